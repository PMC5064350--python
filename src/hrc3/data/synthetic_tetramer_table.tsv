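# SYNTHETIC tetramer cleavage table (Normal(1, 0.15), seed 0).
# Placeholder for development and examples only; supply an
# experimentally derived table for real analyses.
AAAA	1.01545
AAAC	0.852921
AAAG	0.877378
AAAT	0.845818
AACA	0.913831
AACC	1.29567
AACG	1.059
AACT	0.999654
AAGA	0.59869
AAGC	1.29139
AAGG	1.00292
AAGT	0.660669
AATA	1.01101
AATC	1.03227
AATG	1.18321
AATT	1.00461
ACAA	0.808769
ACAC	1.03396
ACAG	0.942187
ACAT	0.788623
ACCA	1.04549
ACCC	1.20607
ACCG	1.14732
ACCT	0.914823
ACGA	0.702508
ACGC	0.876676
ACGG	0.754789
ACGT	0.99033
ACTA	1.13969
ACTC	1.4556
ACTG	1.04512
ACTT	0.819618
AGAA	0.967285
AGAC	1.06847
AGAG	0.998629
AGAT	0.980704
AGCA	1.01167
AGCC	1.17418
AGCG	0.932595
AGCT	0.9564
AGGA	0.898613
AGGC	1.01942
AGGG	1.23223
AGGT	1.04663
AGTA	1.25609
AGTC	1.09234
AGTG	1.18649
AGTT	1.15732
ATAA	1.0633
ATAC	1.0553
ATAG	0.694849
ATAT	1.06764
ATCA	1.0529
ATCC	0.905167
ATCG	0.890628
ATCT	1.09603
ATGA	1.11242
ATGC	0.832555
ATGG	0.988396
ATGT	0.982461
ATTA	1.10547
ATTC	0.788855
ATTG	0.807381
ATTT	0.923593
CAAA	0.954356
CAAC	0.925251
CAAG	1.23049
CAAT	0.522589
CACA	1.09041
CACC	0.975163
CACG	1.02831
CACT	0.905601
CAGA	1.03106
CAGC	0.975666
CAGG	1.17291
CAGT	0.948912
CATA	1.366
CATC	0.912382
CATG	0.787129
CATT	1.13818
CCAA	1.05857
CCAC	1.18137
CCAG	1.1577
CCAT	0.800839
CCCA	1.01151
CCCC	1.08537
CCCG	0.80493
CCCT	0.636736
CCGA	1.11885
CCGC	0.960715
CCGG	1.09134
CCGT	1.1576
CCTA	0.856059
CCTC	0.892657
CCTG	1.1636
CCTT	0.964782
CGAA	1.0659
CGAC	0.566652
CGAG	0.902656
CGAT	1.12044
CGCA	0.918068
CGCC	0.920527
CGCG	1.13741
CGCT	0.98995
CGGA	1.02249
CGGC	0.92663
CGGG	1.25394
CGGT	0.866205
CGTA	0.942442
CGTC	1.10677
CGTG	1.04635
CGTT	1.08754
CTAA	1.18961
CTAC	1.0969
CTAG	0.666696
CTAT	0.953063
CTCA	1.0083
CTCC	1.34668
CTCG	0.989173
CTCT	0.99526
CTGA	0.809769
CTGC	0.925755
CTGG	1.08922
CTGT	0.905398
CTTA	1.12938
CTTC	0.84505
CTTG	1.02036
CTTT	0.890974
GAAA	0.990384
GAAC	0.972102
GAAG	0.972361
GAAT	1.05122
GACA	0.897642
GACC	1.05807
GACG	0.911773
GACT	0.960417
GAGA	1.07416
GAGC	0.800933
GAGG	1.02464
GAGT	0.951701
GATA	1.02834
GATC	1.29881
GATG	1.15311
GATT	0.809287
GCAA	0.903867
GCAC	1.31328
GCAG	0.964165
GCAT	1.05671
GCCA	0.943656
GCCC	1.2229
GCCG	1.14887
GCCT	1.07224
GCGA	0.939496
GCGC	0.873082
GCGG	0.999953
GCGT	0.934392
GCTA	0.912673
GCTC	1.16111
GCTG	1.03485
GCTT	1.03725
GGAA	0.938881
GGAC	0.9128
GGAG	1.30374
GGAT	0.779949
GGCA	0.999304
GGCC	0.925466
GGCG	1.08879
GGCT	1.18632
GGGA	0.754095
GGGC	0.89831
GGGG	0.886527
GGGT	0.859166
GGTA	0.971431
GGTC	0.981083
GGTG	0.739475
GGTT	0.869583
GTAA	0.643712
GTAC	1.05984
GTAG	1.0546
GTAT	0.875354
GTCA	1.1552
GTCC	1.04154
GTCG	0.91185
GTCT	0.901042
GTGA	1.03673
GTGC	1.1351
GTGG	1.1766
GTGT	0.857978
GTTA	0.7609
GTTC	1.10765
GTTG	1.15887
GTTT	0.887953
TAAA	1.22208
TAAC	0.825574
TAAG	0.7655
TAAT	0.726415
TACA	0.967405
TACC	1.18391
TACG	1.20653
TACT	1.14005
TAGA	1.23008
TAGC	1.13854
TAGG	1.31419
TAGT	1.19258
TATA	1.24385
TATC	1.03172
TATG	0.96969
TATT	0.884956
TCAA	0.707765
TCAC	0.882128
TCAG	1.00951
TCAT	1.02214
TCCA	0.885831
TCCC	0.776137
TCCG	0.962657
TCCT	0.974352
TCGA	1.28235
TCGC	0.862246
TCGG	0.962093
TCGT	1.15122
TCTA	1.03529
TCTC	0.976873
TCTG	1.09781
TCTT	0.936402
TGAA	0.904271
TGAC	1.03377
TGAG	1.25811
TGAT	0.985535
TGCA	0.991017
TGCC	0.935904
TGCG	1.19494
TGCT	1.12965
TGGA	0.96882
TGGC	1.04385
TGGG	1.09349
TGGT	1.32149
TGTA	1.05174
TGTC	1.09845
TGTG	0.79548
TGTT	0.921739
TTAA	0.888931
TTAC	1.05224
TTAG	1.00905
TTAT	1.06948
TTCA	1.16508
TTCC	0.976028
TTCG	1.04324
TTCT	1.12569
TTGA	0.900914
TTGC	1.00352
TTGG	0.854111
TTGT	1.07405
TTTA	1.33257
TTTC	0.988154
TTTG	1.2287
TTTT	1.07424
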