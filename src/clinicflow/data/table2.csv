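session,before_hms,after_hms,printed_improvement_pct,discussion_improvement_pct
1,2:00:59,1:21:42,32.47,32.47
2,2:04:21,1:20:38,35.16,35.16
3,1:18:46,0:56:48,27.89,27.89
4,1:03:34,0:46:49,26.35,26.35
5,1:20:34,0:58:18,27.64,27.64
6,1:56:54,1:21:14,30.51,30.51
7,1:23:24,0:59:33,28.60,28.60
8,2:26:24,1:30:26,38.23,38.23
9,1:17:42,0:54:54,29.34,29.34
10,1:58:55,1:21:08,31.83,31.78
11,2:30:23,1:33:46,37.65,37.65
12,1:24:27,1:01:57,26.64,26.64
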