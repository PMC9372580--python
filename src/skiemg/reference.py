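"""Published effect-size anchors from the on-snow repeated-runs study of
elite alpine skiers that this pipeline re-implements.

These printed summary values (marginal/conditional R^2, adjusted/conditional
ICC, and three in-text effect classifications) are inputs for consistency
checks: the identity R2m + ICC_cond = R2c must recover every printed
conditional ICC, and :func:`skiemg.mixedfx.classify_effect` must reproduce
the printed labels. They are not fitted by this package.
"""

from __future__ import annotations

#: (variable, discipline, muscle, factor level, r2m, r2c, icc_adj, icc_cond)
EFFECT_SIZE_TABLE = [
    ("rms_pct_mvc", "SL", "VL", "IL", 0.000, 0.999, 0.999, 0.999),
    ("rms_pct_mvc", "SL", "VL", "OL", 0.013, 0.999, 0.999, 0.986),
    ("rms_pct_mvc", "SL", "VL", "First", 0.239, 0.999, 0.999, 0.761),
    ("rms_pct_mvc", "SL", "VL", "Last", 0.177, 1.000, 1.000, 0.823),
    ("rms_pct_mvc", "GS", "VM", "OL", 0.043, 1.000, 1.000, 0.957),
    ("rms_pct_mvc", "GS", "VM", "First", 0.521, 1.000, 1.000, 0.479),
    ("rms_pct_mvc", "GS", "VM", "Last", 0.524, 1.000, 1.000, 0.476),
    ("rms_pct_mvc", "GS", "SMST", "IL", 0.002, 0.992, 0.992, 0.990),
    ("rms_pct_mvc", "GS", "SMST", "OL", 0.023, 0.998, 0.998, 0.975),
    ("rms_pct_mvc", "GS", "SMST", "First", 0.854, 0.999, 0.993, 0.145),
    ("rms_pct_mvc", "GS", "SMST", "Last", 0.895, 0.999, 0.990, 0.104),
    ("burst_ms", "GS", "SMST", "OL", 0.036, 1.000, 1.000, 0.964),
    ("burst_ms", "GS", "SMST", "First", 0.681, 1.000, 1.000, 0.319),
    ("burst_ms", "GS", "SMST", "Last", 0.782, 1.000, 1.000, 0.218),
    ("burst_ms", "SG+DH", "VM", "IL", 0.069, 1.000, 1.000, 0.931),
    ("burst_ms", "SG+DH", "VM", "OL", 0.009, 1.000, 1.000, 0.991),
    ("burst_ms", "SG+DH", "VM", "First", 0.400, 1.000, 1.000, 0.600),
    ("burst_ms", "SG+DH", "VM", "Last", 0.131, 1.000, 1.000, 0.869),
    ("burst_ms", "SL", "RF", "IL", 0.001, 0.472, 0.471, 0.471),
    ("burst_ms", "SL", "RF", "OL", 0.021, 0.491, 0.481, 0.471),
    ("burst_pct", "SL", "RF", "First", 0.206, 0.527, 0.404, 0.321),
    ("burst_pct", "SL", "RF", "Last", 0.135, 0.574, 0.508, 0.439),
    ("burst_pct", "GS", "SMST", "IL", 0.001, 0.530, 0.530, 0.530),
    ("burst_pct", "GS", "SMST", "OL", 0.006, 0.531, 0.528, 0.525),
    ("burst_pct", "GS", "SMST", "First", 0.276, 0.564, 0.398, 0.288),
    ("burst_pct", "GS", "SMST", "Last", 0.339, 0.569, 0.348, 0.230),
]

#: (p, icc_adj, icc_cond, printed classification)
CLASSIFICATION_ANCHORS = [
    (0.0005, 1.000, 0.465, "very strong"),  # GS vastus medialis RMS, run effect
    (0.035, 1.000, 0.859, "moderate"),  # SL vastus medialis RMS, run effect
    (0.011, 0.528, 0.525, "negligible"),  # GS medial hamstring burst %, OL: ICC_adj ~ ICC_cond
]
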