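analysis	method	quantity	value
pd_ad	ivw	or	0.918
pd_ad	ivw	ci_low	0.782
pd_ad	ivw	ci_high	1.076
pd_ad	ivw	pval	0.291
pd_ad	weighted-median	or	1.069
pd_ad	weighted-median	ci_low	0.769
pd_ad	weighted-median	ci_high	1.140
pd_ad	weighted-median	pval	0.509
pd_ad	egger-slope	or	0.863
pd_ad	egger-slope	ci_low	0.593
pd_ad	egger-slope	ci_high	1.253
pd_ad	egger-slope	pval	0.437
pd_ad	egger-intercept	beta	0.003
pd_ad	egger-intercept	pval	0.717
pd_ad	max-likelihood	or	0.916
pd_ad	max-likelihood	ci_low	0.780
pd_ad	max-likelihood	ci_high	1.076
pd_ad	max-likelihood	pval	0.292
snca_ad	ivw	or	0.638
snca_ad	ivw	ci_low	0.485
snca_ad	ivw	ci_high	0.838
snca_ad	ivw	pval	1.20E-03
snca_ad	max-likelihood	or	0.60
snca_ad	max-likelihood	ci_low	0.34
snca_ad	max-likelihood	ci_high	1.06
snca_ad	max-likelihood	pval	0.08
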