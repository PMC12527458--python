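# Default MCS score table.
# Derived by IBDQ-anchored calibration (each point ~ 17.5 IBDQ-32 points)
# on the packaged synthetic reference cohort (generator seed 20259, n=500,
# baseline records, no missingness). Replace with the published item table
# when available; the loader validates all structural invariants.

[mean_loose]
thresholds = 1.6666, 3.493, 5.3194
points = 0, 1, 2, 3

[mean_nocturnal]
thresholds = 0.4955, 1.2578, 2.0202
points = 0, 1, 2, 3

[urgency_days]
thresholds = 1.6279, 3.3879, 5.1478
points = 0, 1, 2, 3

[leakage_days]
thresholds = 0.8099, 2.1884, 3.5669
points = 0, 1, 2, 3

[mean_pain]
thresholds = 0.4984, 1.0681, 1.6377
points = 0, 1, 2, 3
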