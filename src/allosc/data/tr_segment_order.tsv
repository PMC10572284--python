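segment	locus
TRAV1-1	TRA
TRAV1-2	TRA
TRAV2	TRA
TRAV3	TRA
TRAV4	TRA
TRAV5	TRA
TRAV6	TRA
TRAV7	TRA
TRAV8-1	TRA
TRAV8-2	TRA
TRAV8-3	TRA
TRAV8-4	TRA
TRAV8-6	TRA
TRAV9-1	TRA
TRAV9-2	TRA
TRAV10	TRA
TRAV12-1	TRA
TRAV12-2	TRA
TRAV12-3	TRA
TRAV13-1	TRA
TRAV13-2	TRA
TRAV14DV4	TRA
TRAV16	TRA
TRAV17	TRA
TRAV18	TRA
TRAV19	TRA
TRAV20	TRA
TRAV21	TRA
TRAV22	TRA
TRAV23DV6	TRA
TRAV24	TRA
TRAV25	TRA
TRAV26-1	TRA
TRAV26-2	TRA
TRAV27	TRA
TRAV29DV5	TRA
TRAV30	TRA
TRAV34	TRA
TRAV35	TRA
TRAV36DV7	TRA
TRAV38-1	TRA
TRAV38-2DV8	TRA
TRAV39	TRA
TRAV40	TRA
TRAV41	TRA
TRAJ58	TRA
TRAJ57	TRA
TRAJ56	TRA
TRAJ54	TRA
TRAJ53	TRA
TRAJ52	TRA
TRAJ50	TRA
TRAJ49	TRA
TRAJ48	TRA
TRAJ47	TRA
TRAJ46	TRA
TRAJ45	TRA
TRAJ44	TRA
TRAJ43	TRA
TRAJ42	TRA
TRAJ41	TRA
TRAJ40	TRA
TRAJ39	TRA
TRAJ38	TRA
TRAJ37	TRA
TRAJ36	TRA
TRAJ35	TRA
TRAJ34	TRA
TRAJ33	TRA
TRAJ32	TRA
TRAJ31	TRA
TRAJ30	TRA
TRAJ29	TRA
TRAJ28	TRA
TRAJ27	TRA
TRAJ26	TRA
TRAJ25	TRA
TRAJ24	TRA
TRAJ23	TRA
TRAJ22	TRA
TRAJ21	TRA
TRAJ20	TRA
TRAJ19	TRA
TRAJ18	TRA
TRAJ17	TRA
TRAJ16	TRA
TRAJ15	TRA
TRAJ14	TRA
TRAJ13	TRA
TRAJ12	TRA
TRAJ11	TRA
TRAJ10	TRA
TRAJ9	TRA
TRAJ8	TRA
TRAJ7	TRA
TRAJ6	TRA
TRAJ5	TRA
TRAJ4	TRA
TRAJ3	TRA
TRDV1	TRD
TRDV2	TRD
TRDV3	TRD
TRDD1	TRD
TRDD2	TRD
TRDD3	TRD
TRDJ1	TRD
TRDJ2	TRD
TRDJ3	TRD
TRDJ4	TRD
TRBV2	TRB
TRBV3-1	TRB
TRBV4-1	TRB
TRBV4-2	TRB
TRBV4-3	TRB
TRBV5-1	TRB
TRBV5-4	TRB
TRBV5-5	TRB
TRBV5-6	TRB
TRBV5-8	TRB
TRBV6-1	TRB
TRBV6-2	TRB
TRBV6-4	TRB
TRBV6-5	TRB
TRBV6-6	TRB
TRBV6-8	TRB
TRBV6-9	TRB
TRBV7-2	TRB
TRBV7-3	TRB
TRBV7-4	TRB
TRBV7-6	TRB
TRBV7-7	TRB
TRBV7-8	TRB
TRBV7-9	TRB
TRBV9	TRB
TRBV10-1	TRB
TRBV10-2	TRB
TRBV10-3	TRB
TRBV11-1	TRB
TRBV11-2	TRB
TRBV11-3	TRB
TRBV12-3	TRB
TRBV12-4	TRB
TRBV12-5	TRB
TRBV13	TRB
TRBV14	TRB
TRBV15	TRB
TRBV16	TRB
TRBV18	TRB
TRBV19	TRB
TRBV20-1	TRB
TRBV24-1	TRB
TRBV25-1	TRB
TRBV27	TRB
TRBV28	TRB
TRBV29-1	TRB
TRBV30	TRB
TRBD1	TRB
TRBJ1-1	TRB
TRBJ1-2	TRB
TRBJ1-3	TRB
TRBJ1-4	TRB
TRBJ1-5	TRB
TRBJ1-6	TRB
TRBD2	TRB
TRBJ2-1	TRB
TRBJ2-2	TRB
TRBJ2-3	TRB
TRBJ2-4	TRB
TRBJ2-5	TRB
TRBJ2-6	TRB
TRBJ2-7	TRB
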