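"""Shared measurement defaults, collected in one place.

These are the standard analysis settings the rest of the package imports;
each is a measurement convention of the AIS morphometry / patch-clamp
literature, not a tuning knob.
"""

# -- morphometry -----------------------------------------------------------
# relative fluorescence threshold for AIS start/end detection, as a
# fraction of (max - background); accepted range 10-30% depending on
# staining quality, default at the midpoint
THETA_DEFAULT = 0.20
THETA_BOUNDS = (0.10, 0.30)
# moving-average smoothing window (um) applied before threshold detection
SMOOTH_WINDOW_UM = 1.0
# sustained-crossing requirement resolving multi-crossing ambiguity (um)
MIN_RUN_UM = 0.5
# confocal sampling: 0.21 um/px (60x) or 0.12 um/px (100x)
PIXEL_SIZES_UM = (0.21, 0.12)

# -- electrophysiology -----------------------------------------------------
# dV/dt criterion defining AP voltage threshold (V/s)
DVDT_THRESHOLD_VPS = 50.0
# series-resistance exclusion cutoff (MOhm)
RS_EXCLUSION_MOHM = 30.0
# acquisition rate (Hz)
SAMPLE_RATE_HZ = 50_000.0
# step protocols: 20 ms pulses in 10 pA increments (threshold APs),
# 500 ms pulses in 50 pA increments (firing patterns / I-f curves)
SHORT_STEP = dict(kind="short", duration_ms=20.0, step_pA=10.0)
LONG_STEP = dict(kind="long", duration_ms=500.0, step_pA=50.0)
# PSC recordings: 2 min of voltage clamp at -90 mV
PSC_DURATION_S = 120.0

# -- statistics ------------------------------------------------------------
# significance level, two-sided throughout
ALPHA = 0.05
# per-animal sampling rule for cohort statistics
MIN_AIS_PER_ANIMAL = 100
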