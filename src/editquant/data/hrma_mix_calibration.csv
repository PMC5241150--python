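# HRMA dose-response calibration series: PCR products mixed in known proportions.
# Two mix series against the F8-S2 wild-type product: the S3 wild-type product
# (a Tm-matched surrogate mutant, "s3wt") and the authentic 100%-mutant S2
# product ("s2mt"). One row per nominal mutant percentage. DCA columns are the
# measured difference-curve areas (normalized-RFU * degC); the pct_* columns are
# the percentages originally re-estimated from each fitted standard curve
# (self-application and cross-application), kept for comparison.
nominal_pct,dca_s3wt,pct_s3wt_self,dca_s2mt,pct_s2mt_self,pct_s3wt_curve_on_s2mt,pct_s2mt_curve_on_s3wt
100,1.32,97.7,1.33,97.6,98.7,96.2
90,1.19,87.9,1.23,87.7,90.8,84.0
80,1.13,83.1,1.17,82.1,86.3,78.2
70,0.99,72.7,1.08,73.5,79.1,66.0
60,0.84,61.8,0.95,62.2,69.3,53.9
50,0.69,50.6,0.81,51.5,59.5,42.1
40,0.51,37.6,0.60,35.8,44.4,29.3
30,0.35,26.9,0.48,27.6,35.7,19.5
20,0.25,19.9,0.34,18.9,26.1,13.6
10,0.09,9.1,0.24,12.7,18.8,5.0
0,0.00,2.8,0.00,0.5,2.8,0.5
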