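peak,rt_min,adduct,mz,uv_lambda_max
1,6.74,[M-H]-,153.0193,280
1,6.74,[M+H]+,155.0394,280
2,14.76,[M-H]-,353.0877,285;325
2,14.76,[2M-H]-,707.1832,285;325
2,14.76,[M+H]+,355.1027,285;325
3,19.45,[M-H]-,675.1931,283;313
4,21.50,[M-H]-,335.0772,230;280
5,25.04,[M-H]-,369.1555,230;285
6,25.87,[M-H]-,463.0882,283
6,25.87,[M+H]+,465.1026,283
6,25.87,[2M-H]-,927.1837,283
7,29.58,[M-H]-,609.1461,265;285;350
7,29.58,[M+H]+,611.1621,265;285;350
8,31.17,[M-H]-,699.2870,230;280
9,31.70,[M-H]-,463.0882,270;280;355
9,31.70,[2M-H]-,827.1829,270;280;355
9,31.70,[M+H]+,465.1041,270;280;355
10,32.35,[M-H]-,609.1461,270;285;335
10,32.35,[M+H]+,611.1613,270;285;335
11,35.28,[M-H]-,447.0933,270;280;340
11,35.28,[M+H]+,449.1095,270;280;340
11,35.28,[2M-H]-,895.1918,270;280;340
12,37.44,[M-H]-,447.0933,240;265;350
12,37.44,[2M-H]-,895.1927,240;265;350
12,37.44,[M+H]+,449.1094,240;265;350
13,45.69,[M-H]-,575.1770,235;285
13,45.69,[M+H]+,577.1912,235;285
14,46.16,[M-H]-,609.1250,235;280;335
14,46.16,[M+H]+,611.1388,235;280;335
15,46.59,[M-H]-,467.2134,235;280
16,47.84,[M-H]-,493.2291,238;280
17,49.04,[M-H]-,509.3120,245;280
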