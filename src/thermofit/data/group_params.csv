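roi_index,roi_label,group,lt_mean,lt_sd,a_mean,a_sd,d_mean,d_sd,k_mean,k_sd
1,I MCP,PsA,4,6,0.9,3,0.04,0.1,0.9,1.7
1,I MCP,HC,6,7,0.1,0.2,-0.07,0.09,0.3,0.6
2,thumb IP,PsA,0.5,0.8,0.1,0.1,-0.02,0.1,0.3,0.4
2,thumb IP,HC,2,3,0.1,0.17,-0.02,0.2,-0.5,1.6
3,II MCP,PsA,3,4,1,3,-0.01,0.2,0.48,1
3,II MCP,HC,4,4,0.08,0.08,-0.03,0.1,0.4,0.8
4,II IPP,PsA,5,6,0.9,2,-0.06,0.1,0.1,0.1
4,II IPP,HC,3,3,2,3,-0.06,0.08,0.02,0.04
5,II IPD,PsA,4,5,0.5,1,0.03,0.19,0.7,1.5
5,II IPD,HC,8,7,0.4,0.6,0.007,0.2,0.4,0.9
6,III MCP,PsA,3,5,0.12,0.17,-0.01,0.17,0.3,0.9
6,III MCP,HC,2,2,1,1.5,-0.04,0.04,0.03,0.07
7,III IPP,PsA,3,3,0.8,2,-0.1,0.3,0.2,0.16
7,III IPP,HC,7,9,0.2,0.2,-0.04,0.07,0.12,0.16
8,III IPD,PsA,5,7,1,3,-0.1,0.4,0.3,0.4
8,III IPD,HC,4,4,0.2,0.3,-0.01,0.2,0.2,0.3
9,IV MCP,PsA,4,4,0.1,0.09,-0.007,0.06,0.14,0.15
9,IV MCP,HC,4,5,0.6,1.7,-0.06,0.15,-0.2,0.4
10,IV IPP,PsA,3,4,0.6,0.9,-0.06,0.2,0.5,1.3
10,IV IPP,HC,4,7,0.2,0.3,-0.2,0.2,0.4,1.9
11,IV IPD,PsA,3,6,2,2,-0.05,0.1,0.07,0.05
11,IV IPD,HC,3,3,0.1,0.18,-0.08,0.1,0.15,0.1
12,V MCP,PsA,7,8,0.8,1,0.03,0.1,1.5,3
12,V MCP,HC,3,4,0.6,1.5,0.01,0.3,0.9,1.7
13,V IPP,PsA,3,7,1,2,0.04,0.2,0.1,0.1
13,V IPP,HC,4,4,0.9,2,0.02,0.1,0.02,0.05
14,V IPD,PsA,6,7,0.3,0.4,-0.01,0.3,0.1,0.2
14,V IPD,HC,1,2,0.15,0.17,-0.02,0.5,-0.1,0.9
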