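# nn37: nearest-neighbor RNA folding parameters (kcal/mol, 37C)
name nn37
rt 0.616
min_hairpin 3
max_loop 30
loop_log_coef 1.0780
multiloop_offset 3.4
multiloop_branch 0.4
multiloop_unpaired 0.0
terminal_au 0.5
internal_asym 0.6
stack AU AU -0.93
stack AU CG -2.24
stack AU GC -2.08
stack AU GU -0.55
stack AU UA -1.10
stack AU UG -1.36
stack CG AU -2.11
stack CG CG -3.26
stack CG GC -2.36
stack CG GU -1.41
stack CG UA -2.08
stack CG UG -2.11
stack GC AU -2.35
stack GC CG -3.42
stack GC GC -3.26
stack GC GU -1.53
stack GC UA -2.24
stack GC UG -2.51
stack GU AU -1.00
stack GU CG -2.51
stack GU GC -2.11
stack GU GU -0.50
stack GU UA -1.36
stack GU UG 0.47
stack UA AU -1.33
stack UA CG -2.35
stack UA GC -2.11
stack UA GU -1.27
stack UA UA -0.93
stack UA UG -1.00
stack UG AU -1.27
stack UG CG -1.53
stack UG GC -1.41
stack UG GU -0.30
stack UG UA -0.55
stack UG UG -0.50
hairpin 3 5.400
hairpin 4 5.600
hairpin 5 5.700
hairpin 6 5.400
hairpin 7 6.000
hairpin 8 5.500
hairpin 9 6.400
hairpin 10 6.514
hairpin 11 6.616
hairpin 12 6.710
hairpin 13 6.796
hairpin 14 6.876
hairpin 15 6.951
hairpin 16 7.020
hairpin 17 7.086
hairpin 18 7.147
hairpin 19 7.205
hairpin 20 7.261
hairpin 21 7.313
hairpin 22 7.364
hairpin 23 7.411
hairpin 24 7.457
hairpin 25 7.501
hairpin 26 7.544
hairpin 27 7.584
hairpin 28 7.624
hairpin 29 7.661
hairpin 30 7.698
bulge 1 3.800
bulge 2 2.800
bulge 3 3.200
bulge 4 3.600
bulge 5 4.000
bulge 6 4.400
bulge 7 4.566
bulge 8 4.710
bulge 9 4.837
bulge 10 4.951
bulge 11 5.053
bulge 12 5.147
bulge 13 5.233
bulge 14 5.313
bulge 15 5.388
bulge 16 5.457
bulge 17 5.523
bulge 18 5.584
bulge 19 5.643
bulge 20 5.698
bulge 21 5.750
bulge 22 5.801
bulge 23 5.849
bulge 24 5.894
bulge 25 5.938
bulge 26 5.981
bulge 27 6.021
bulge 28 6.061
bulge 29 6.098
bulge 30 6.135
internal 2 1.000
internal 3 1.800
internal 4 1.100
internal 5 2.000
internal 6 2.300
internal 7 2.466
internal 8 2.610
internal 9 2.737
internal 10 2.851
internal 11 2.953
internal 12 3.047
internal 13 3.133
internal 14 3.213
internal 15 3.288
internal 16 3.357
internal 17 3.423
internal 18 3.484
internal 19 3.543
internal 20 3.598
internal 21 3.650
internal 22 3.701
internal 23 3.749
internal 24 3.794
internal 25 3.838
internal 26 3.881
internal 27 3.921
internal 28 3.961
internal 29 3.998
internal 30 4.035
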