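"""Group statistics and region classification on fitted parameters.

Follows the study's analysis plan: Shapiro-Wilk normality screening,
Wilcoxon-Mann-Whitney rank-sum comparisons of PsA vs HC per ROI and
pooled (exact p for small samples, tie-corrected normal approximation
with a z statistic otherwise), a binary logistic regression of diagnosis
on (LT, a, d, K) per region, a ROC analysis whose operating cutoff
maximises Youden's J, and the resulting row-normalised confusion matrix.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.metrics import roc_auc_score
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "RegionStats",
    "LogisticModel",
    "RocResult",
    "ConfusionMatrix",
    "normality_test",
    "group_compare",
    "fit_region_classifier",
    "roc_cutoff",
    "classify_regions",
    "region_stats",
    "ALPHA",
]

ALPHA = 0.05

PARAM_COLUMNS = ("lt", "a", "d", "k")

#: Largest combination count for which the exact rank-sum distribution is
#: enumerated; beyond it the normal approximation is used regardless of n.
_EXACT_COMB_CAP = 5_000_000


def normality_test(values) -> tuple[float, float]:
    """Shapiro-Wilk W statistic and p value (3 <= n <= 5000)."""
    values = np.asarray(values, dtype=float)
    if not 3 <= values.size <= 5000:
        raise ValueError(f"Shapiro-Wilk needs 3 <= n <= 5000, got {values.size}")
    if np.ptp(values) == 0:
        raise ValueError("normality test undefined for constant input")
    w, p = sps.shapiro(values)
    return float(w), float(p)


def _exact_ranksum_p(ranks2: np.ndarray, n1: int, observed2: int) -> float:
    """Two-sided exact p of the group-1 rank sum under the null.

    Dynamic programming over the multiset of doubled midranks (integers);
    the two-sided p is P(|S - mu| >= |observed - mu|).
    """
    total2 = int(ranks2.sum())
    max_sum = int(np.sort(ranks2)[-n1:].sum())
    # counts[k][s]: number of k-subsets with doubled-rank sum s
    counts = [np.zeros(max_sum + 1, dtype=float) for _ in range(n1 + 1)]
    counts[0][0] = 1.0
    for rv in ranks2:
        for k in range(n1, 0, -1):
            src = counts[k - 1]
            counts[k][rv:] += src[: max_sum + 1 - rv]
    dist = counts[n1]
    n_total = dist.sum()
    mu2 = n1 * (total2 / ranks2.size)
    dev = abs(observed2 - mu2)
    sums = np.arange(max_sum + 1)
    hit = np.abs(sums - mu2) >= dev - 1e-9
    return float(dist[hit].sum() / n_total)


def group_compare(psa_values, hc_values) -> tuple[float, float | None, float]:
    """Wilcoxon-Mann-Whitney comparison of two groups.

    Returns ``(ranksum, z, p)`` where ``ranksum`` is the rank sum of the
    first group with midrank ties.  For min(n1, n2) < 10 the exact null
    distribution is enumerated and no z is reported; otherwise the
    tie-corrected normal approximation supplies z and p.
    """
    x = np.asarray(psa_values, dtype=float)
    y = np.asarray(hc_values, dtype=float)
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    if np.ptp(pooled) == 0:
        warnings.warn("all observations tied; no location shift detectable",
                      stacklevel=2)
        return r1, None, 1.0
    small = min(n1, n2)
    use_exact = small < 10 and math.comb(n1 + n2, small) <= _EXACT_COMB_CAP
    if use_exact:
        ranks2 = np.round(2 * ranks).astype(int)
        # Enumerate over the smaller group; the two-sided p is identical
        # because the two rank sums are complementary.
        if n1 <= n2:
            m, obs2 = n1, int(round(2 * r1))
        else:
            m, obs2 = n2, int(ranks2.sum()) - int(round(2 * r1))
        p = _exact_ranksum_p(ranks2, m, obs2)
        return r1, None, min(p, 1.0)
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    z = (r1 - mu) / math.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return r1, float(z), float(min(p, 1.0))


@dataclass(frozen=True)
class RegionStats:
    """Per-ROI group comparison for one model parameter."""

    roi_label: str
    parameter: str
    psa_mean: float
    psa_sd: float
    hc_mean: float
    hc_sd: float
    ranksum: float
    z: float | None
    p_value: float
    significant: bool


def region_stats(df: pd.DataFrame, roi_label: str = "all") -> list[RegionStats]:
    """Compare PsA vs HC per parameter on a tidy fitted-parameter table.

    ``df`` needs columns ``group`` (PsA/HC) and the four parameter
    columns ``lt, a, d, k``; rows should already have poor fits excluded.
    """
    out = []
    psa = df[df["group"] == "PsA"]
    hc = df[df["group"] == "HC"]
    for p in PARAM_COLUMNS:
        ranksum, z, pval = group_compare(psa[p].to_numpy(), hc[p].to_numpy())
        out.append(
            RegionStats(
                roi_label=roi_label,
                parameter=p,
                psa_mean=float(psa[p].mean()),
                psa_sd=float(psa[p].std(ddof=1)),
                hc_mean=float(hc[p].mean()),
                hc_sd=float(hc[p].std(ddof=1)),
                ranksum=ranksum,
                z=z,
                p_value=pval,
                significant=pval < ALPHA,
            )
        )
    return out


@dataclass
class LogisticModel:
    """Binary logistic regression of diagnosis on (LT, a, d, K)."""

    coef: dict[str, float]
    se: dict[str, float]
    wald: dict[str, float]
    p_values: dict[str, float]
    odds_ratios: dict[str, float]
    fitted_probs: np.ndarray
    labels: np.ndarray  # 1 = PsA, 0 = HC
    separated: bool
    log_likelihood: float


def fit_region_classifier(df: pd.DataFrame) -> LogisticModel:
    """Fit PsA-vs-HC logistic regression with intercept on one ROI's fits.

    Perfect separation is flagged (not silently diverged): coefficients
    from a capped-iteration fit are still reported with the flag set.
    """
    y = (df["group"] == "PsA").to_numpy(dtype=float)
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValueError("need at least 2 records per class")
    X = sm.add_constant(df[list(PARAM_COLUMNS)].to_numpy(dtype=float))
    names = ("intercept",) + PARAM_COLUMNS
    separated = False
    model = sm.Logit(y, X)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = model.fit(disp=0, maxiter=100)
        except (PerfectSeparationError, np.linalg.LinAlgError):
            separated = True
            res = model.fit(method="bfgs", disp=0, maxiter=200, skip_hessian=False)
        for w in caught:
            if "separat" in str(w.message).lower() or "Maximum Likelihood" in str(
                w.message
            ):
                separated = True
    probs = np.asarray(res.predict(X))
    # Post-hoc separation check: a class-wise probability gap of ~1 means
    # the likelihood is unbounded and coefficients are not identified.
    if probs[y == 1].min() > probs[y == 0].max() and (
        probs[y == 1].min() > 0.999 or probs[y == 0].max() < 0.001
    ):
        separated = True
    if separated:
        warnings.warn("perfect separation detected; coefficients unstable",
                      stacklevel=2)
    params = np.asarray(res.params, dtype=float)
    try:
        bse = np.asarray(res.bse, dtype=float)
    except Exception:
        bse = np.full_like(params, np.nan)
    wald = params / bse
    pvals = 2.0 * sps.norm.sf(np.abs(wald))
    return LogisticModel(
        coef=dict(zip(names, params)),
        se=dict(zip(names, bse)),
        wald=dict(zip(names, wald)),
        p_values=dict(zip(names, pvals)),
        odds_ratios={n: float(np.exp(b)) for n, b in zip(names, params)},
        fitted_probs=probs,
        labels=y.astype(int),
        separated=separated,
        log_likelihood=float(res.llf),
    )


@dataclass(frozen=True)
class RocResult:
    """ROC curve over the model's fitted probabilities."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    one_minus_specificity: np.ndarray
    cutoff: float
    auc: float


def roc_cutoff(probs, labels) -> RocResult:
    """ROC analysis; the cutoff maximises Youden's J = sens + spec - 1.

    Ties in J are broken toward higher sensitivity, then toward the
    higher threshold, so a perfectly separated sample returns the lowest
    positive-class probability as its cutoff.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if labels.min() == labels.max():
        raise ValueError("ROC undefined with a single class")
    if probs.min() < 0 or probs.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    thresholds = np.unique(probs)[::-1]
    n_pos = int((labels == 1).sum())
    n_neg = labels.size - n_pos
    sens = np.empty(thresholds.size)
    fpr = np.empty(thresholds.size)
    for i, thr in enumerate(thresholds):
        pred = probs >= thr
        sens[i] = (pred & (labels == 1)).sum() / n_pos
        fpr[i] = (pred & (labels == 0)).sum() / n_neg
    j = sens - fpr
    best = np.flatnonzero(j >= j.max() - 1e-12)
    best = best[sens[best] >= sens[best].max() - 1e-12]
    cutoff = float(thresholds[best].max())
    if np.ptp(probs) == 0:
        auc = 0.5
    else:
        auc = float(roc_auc_score(labels, probs))
    return RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        one_minus_specificity=fpr,
        cutoff=cutoff,
        auc=auc,
    )


@dataclass(frozen=True)
class ConfusionMatrix:
    """Row-normalised percentages: original group x predicted group."""

    matrix: np.ndarray  # rows (PsA, HC) x cols (PsA, HC), percent
    correct_pct: dict[str, float]

    def __post_init__(self) -> None:
        if not np.allclose(self.matrix.sum(axis=1), 100.0):
            raise ValueError("confusion-matrix rows must sum to 100%")


def classify_regions(probs, labels, cutoff: float) -> ConfusionMatrix:
    """Predict PsA iff probability >= cutoff; tabulate per-group accuracy."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = (probs >= cutoff).astype(int)
    matrix = np.empty((2, 2))
    for row, cls in enumerate((1, 0)):  # rows: PsA, HC
        sel = labels == cls
        n = sel.sum()
        matrix[row, 0] = 100.0 * (pred[sel] == 1).sum() / n
        matrix[row, 1] = 100.0 * (pred[sel] == 0).sum() / n
    correct = {"PsA": float(matrix[0, 0]), "HC": float(matrix[1, 1])}
    return ConfusionMatrix(matrix=matrix, correct_pct=correct)
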