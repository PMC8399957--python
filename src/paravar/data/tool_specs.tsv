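# Default panel of 16 pathogenicity predictors with score orientation and
# published family-optimized thresholds (raw scale). direction "higher"
# means larger score = more pathogenic; "lower" the opposite (SIFT-style).
# Predictions are positive when the score is strictly beyond the threshold.
name	direction	threshold
ClinPred	higher	0.66
REVEL	higher	0.73
MetaLR	higher	0.91
Eigen	higher	0.55
MCap	higher	0.59
PrimateAI	higher	0.69
MetaSVM	higher	0.92
FATHMM_XF	higher	0.85
SIFT	lower	0.0025
PROVEAN	lower	-3.42
CADD	higher	24
MutationAssessor	higher	2.51
Polyphen_HVAR	higher	0.6
FATHMM	lower	-4.305
Polyphen_HDIV	higher	0.96
MutationTaster	higher	0.99
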