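# Toy orthogroup instance illustrating the annotation-transfer algorithm.
# Groups A, B, C contain both human (hsa) and Arabidopsis (ath) genes;
# D and E contain only plant genes; F contains only human genes.
# Annotated inputs (characterized genes): hsa a, b, d, e; ath ii, iii.
# Only the following relations are exact expectations: a and ii are paired
# through group B; ath gene i (group A) and hsa gene c (group A) are new;
# ath gene iv is reached from annotated ii through the second-hop group D;
# group F yields nothing because it has no plant member, excluding gene e.
# The remaining composition (d and b in C, iii in E) is one consistent
# completion chosen for this fixture.
A: hsa|a hsa|c ath|i
B: hsa|a ath|ii
C: hsa|b hsa|d ath|iii
D: ath|ii ath|iv
E: ath|iii
F: hsa|e
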