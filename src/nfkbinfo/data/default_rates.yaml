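# Default rate constants of the TNF -> NF-kB stochastic network.
# Units: 1/min for first-order constants; second-order constants are per
# molecule (or per molecule pair) per minute; transcription in mRNA/min.
#
# These values are a repository calibration fitted to behavioral constraints
# of the measured dose response (resting nuclear NF-kB fraction < 0.03, peak
# translocation at 10 ng/ml within 15-30 min and <= 2/3 of total NF-kB,
# dose-response saturation at >= 1 ng/ml, responses below 1 ng/ml weaker at
# 15 min than at 30 min, all-or-nothing single-cell commitment at
# intermediate doses); see scripts/calibrate.py for the fitting metrics.

# receptor layer: activation per ng/ml TNF per free receptor; ~5-min active
# lifetime makes receptor activity bursty at sub-ng/ml doses
k_r_act: 5.0e-4
k_r_deact: 0.2

# IKKK layer: activation per active receptor per inactive IKKK
k_kkk_act: 7.0e-4
k_kkk_deact: 0.2
theta_a20_kkk: 2.0e4     # A20 level halving IKKK activation

# IKK three-state cycle: neutral -> active (per active IKKK), active ->
# inactive (A20-enhanced), inactive -> neutral
k_ikk_act: 1.6e-2
k_ikk_inact: 0.2
theta_a20_ikk: 1.5e3     # A20 level doubling IKK inactivation
k_ikk_recover: 2.0

# IkBa degradation (per active IKK per IkBa molecule) and turnover
k_ikba_deg: 1.9e-4
k_ikba_deg_complex: 1.9e-4
k_ikba_basal: 0.15       # constitutive free/nuclear IkBa turnover
k_complex_basal: 6.0e-4  # constitutive turnover of complexed IkBa

# NF-kB shuttling
k_nfkb_import: 1.0
k_bind_export: 1.0e-4    # nuclear NF-kB:IkBa association + export, per pair

# IkBa feedback expression: few transcripts with high per-transcript
# translation, so feedback onset is burst-timed and varies between cells
k_tx_ikba_basal: 0.3
k_tx_ikba: 2.0e-6        # per nuclear NF-kB molecule
k_mrna_deg_ikba: 0.08
k_tl_ikba: 2400.0
k_ikba_import: 0.05

# A20 feedback expression (same burst-limited design)
k_tx_a20_basal: 5.0e-5
k_tx_a20: 1.2e-6
k_mrna_deg_a20: 0.03
k_tl_a20: 4000.0
k_a20_deg: 0.02

# fixed totals per cell
ikkk_total: 3000
ikk_total: 2000
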