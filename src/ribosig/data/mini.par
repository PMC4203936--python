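# mini: nearest-neighbor RNA folding parameters (kcal/mol, 37C)
name mini
rt 0.616
min_hairpin 3
max_loop 30
loop_log_coef 1.0780
multiloop_offset 3.4
multiloop_branch 0.4
multiloop_unpaired 0.0
terminal_au 0.5
internal_asym 0.6
stack AU AU -1.00
stack AU CG -2.00
stack AU GC -2.00
stack AU GU -1.50
stack AU UA -1.00
stack AU UG -1.50
stack CG AU -2.00
stack CG CG -3.00
stack CG GC -3.00
stack CG GU -2.50
stack CG UA -2.00
stack CG UG -2.50
stack GC AU -2.00
stack GC CG -3.00
stack GC GC -3.00
stack GC GU -2.50
stack GC UA -2.00
stack GC UG -2.50
stack GU AU -1.50
stack GU CG -2.50
stack GU GC -2.50
stack GU GU -2.00
stack GU UA -1.50
stack GU UG -2.00
stack UA AU -1.00
stack UA CG -2.00
stack UA GC -2.00
stack UA GU -1.50
stack UA UA -1.00
stack UA UG -1.50
stack UG AU -1.50
stack UG CG -2.50
stack UG GC -2.50
stack UG GU -2.00
stack UG UA -1.50
stack UG UG -2.00
hairpin 3 4.000
hairpin 4 4.500
hairpin 5 5.000
hairpin 6 5.197
hairpin 7 5.363
hairpin 8 5.507
hairpin 9 5.634
hairpin 10 5.747
hairpin 11 5.850
hairpin 12 5.944
hairpin 13 6.030
hairpin 14 6.110
hairpin 15 6.184
hairpin 16 6.254
hairpin 17 6.319
hairpin 18 6.381
hairpin 19 6.439
hairpin 20 6.494
hairpin 21 6.547
hairpin 22 6.597
hairpin 23 6.645
hairpin 24 6.691
hairpin 25 6.735
hairpin 26 6.777
hairpin 27 6.818
hairpin 28 6.857
hairpin 29 6.895
hairpin 30 6.932
bulge 1 3.500
bulge 2 3.000
bulge 3 3.437
bulge 4 3.747
bulge 5 3.988
bulge 6 4.184
bulge 7 4.350
bulge 8 4.494
bulge 9 4.621
bulge 10 4.735
bulge 11 4.838
bulge 12 4.932
bulge 13 5.018
bulge 14 5.098
bulge 15 5.172
bulge 16 5.242
bulge 17 5.307
bulge 18 5.369
bulge 19 5.427
bulge 20 5.482
bulge 21 5.535
bulge 22 5.585
bulge 23 5.633
bulge 24 5.679
bulge 25 5.723
bulge 26 5.765
bulge 27 5.806
bulge 28 5.845
bulge 29 5.883
bulge 30 5.919
internal 2 1.500
internal 3 2.000
internal 4 2.000
internal 5 2.241
internal 6 2.437
internal 7 2.603
internal 8 2.747
internal 9 2.874
internal 10 2.988
internal 11 3.091
internal 12 3.184
internal 13 3.271
internal 14 3.350
internal 15 3.425
internal 16 3.494
internal 17 3.560
internal 18 3.621
internal 19 3.680
internal 20 3.735
internal 21 3.788
internal 22 3.838
internal 23 3.886
internal 24 3.932
internal 25 3.976
internal 26 4.018
internal 27 4.058
internal 28 4.098
internal 29 4.136
internal 30 4.172
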