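# Protein-level orthogroup snapshot covering the shortlisted Arabidopsis
# biomarker candidates and their human counterparts (ath = RefSeq protein,
# hsa = Ensembl protein). Candidates MC6 and MC7 belong to no group.
OG5_127098: ath|NP_188552 hsa|ENSP00000336606 hsa|ENSP00000396113
OG5_132711: ath|NP_193233 hsa|ENSP00000287647
OG5_127539: ath|NP_973433 ath|NP_196419 ath|NP_200908 hsa|ENSP00000254719
OG5_129379: ath|NP_188683 hsa|ENSP00000364894 hsa|ENSP00000387668 hsa|ENSP00000394619 hsa|ENSP00000394649 hsa|ENSP00000406868 hsa|ENSP00000407047 hsa|ENSP00000409207
OG5_132909: ath|NP_172254 hsa|ENSP00000378090
OG5_130132: ath|NP_568851 hsa|ENSP00000402030
OG5_127751: ath|NP_200954 ath|NP_196383 hsa|ENSP00000370672
OG5_178242: ath|NP_565524
OG5_128675: ath|NP_566830 hsa|ENSP00000347978
OG5_127208: ath|NP_568591 ath|NP_568592 hsa|ENSP00000285398
OG5_174560: ath|NP_001118795
OG5_140322: ath|NP_001118392 ath|NP_176126 ath|NP_177130
OG5_147205: ath|NP_178052 ath|NP_178051
OG5_134790: ath|NP_173092
OG5_129286: ath|NP_178318 hsa|ENSP00000351947
OG5_144902: ath|NP_566702
OG5_190312: ath|NP_190811
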