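sample	TRA	TRB	TRA_AND_TRB
C0-P0_pre_don	0.92	0.87	0.99
C0-P0_post_don	0.90	0.92	0.98
C1-P1_pre_don	0.99	0.99	1.00
C1-P1_post_don	0.98	0.98	0.99
C2-P2_pre_don	0.78	0.79	0.94
C2-P2_post_don	0.94	0.69	0.93
C0-P0_pre_thirdP	0.87	0.92	0.97
C0-P0_post_thirdP	0.67	0.83	0.81
C2-P2_pre_thirdP	0.90	0.67	0.94
C2-P2_post_thirdP	0.78	0.61	0.79
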