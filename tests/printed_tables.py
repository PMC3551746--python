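"""Published interstudy reproducibility rows used as arithmetic inputs.

Each row carries the printed pooled mean, mean difference, SD of the
difference, 95% limits of agreement and (for FA/MD) the CoV, all at the
precision of the source tables (3 decimals for FA/MD, 1 for HA and CoV%).

Recomputing CoV = 100·SD/mean and LoA = diff ± 1.96·SD from printed inputs
can disagree with the printed outputs in the last digit whenever the
source computed from unrounded per-subject data; the ``*_CONSISTENT`` sets
list the rows whose printed values are exactly self-consistent, frozen
after checking every row once.
"""

# (region, mean_value, mean_difference, sd_difference, loa_low, loa_high, cov%)
FA_REPRO_ROWS = [
    ("global", 0.617, -0.008, 0.045, -0.096, 0.079, 7.2),
    ("apical", 0.614, -0.013, 0.054, -0.119, 0.093, 8.8),
    ("mid", 0.622, 0.001, 0.051, -0.099, 0.102, 8.2),
    ("basal", 0.614, -0.013, 0.043, -0.098, 0.072, 7.1),
    ("anterior", 0.620, -0.009, 0.042, -0.091, 0.073, 6.8),
    ("lateral", 0.608, 0.012, 0.059, -0.104, 0.128, 9.7),
    ("inferior", 0.620, -0.018, 0.053, -0.123, 0.087, 8.6),
    ("septal", 0.619, -0.017, 0.053, -0.121, 0.086, 8.5),
]

# units: 1e-3 mm^2/s
MD_REPRO_ROWS = [
    ("global", 0.728, 0.045, 0.135, -0.220, 0.310, 18.6),
    ("apical", 0.764, 0.041, 0.176, -0.304, 0.385, 23.0),
    ("mid", 0.720, 0.045, 0.160, -0.268, 0.358, 22.2),
    ("basal", 0.704, 0.045, 0.115, -0.181, 0.271, 16.4),
    ("anterior", 0.727, 0.061, 0.112, -0.158, 0.281, 15.4),
    ("lateral", 0.713, 0.003, 0.164, -0.317, 0.324, 22.9),
    ("inferior", 0.716, 0.053, 0.140, -0.221, 0.327, 19.5),
    ("septal", 0.751, 0.067, 0.232, -0.388, 0.521, 30.9),
]

# degrees; no CoV printed (angle-origin dependent, unstable near zero mean)
HA_REPRO_ROWS = [
    ("global_endo", 38.4, 1.2, 4.8, -8.3, 10.6),
    ("global_meso", 3.9, -0.6, 3.4, -7.3, 6.0),
    ("global_epi", -33.1, -2.7, 2.9, -8.4, 3.0),
    ("apical_endo", 39.5, 3.0, 10.6, -17.8, 23.9),
    ("apical_meso", 4.3, 0.0, 6.1, -12.0, 12.0),
    ("apical_epi", -32.0, -3.6, 6.4, -16.2, 8.9),
    ("mid_endo", 39.1, 1.9, 6.2, -10.3, 14.1),
    ("mid_meso", 3.4, -0.7, 4.7, -9.9, 8.4),
    ("mid_epi", -33.0, -2.9, 6.8, -16.2, 10.4),
    ("basal_endo", 36.6, -0.8, 4.4, -9.3, 7.8),
    ("basal_meso", 4.1, -1.1, 3.2, -7.3, 5.2),
    ("basal_epi", -33.9, -1.8, 4.7, -11.0, 7.4),
    ("anterior_endo", 43.2, 3.7, 8.6, -13.2, 20.5),
    ("anterior_meso", 6.0, 2.6, 5.5, -8.1, 13.3),
    ("anterior_epi", -36.5, -0.9, 7.3, -15.2, 13.5),
    ("lateral_endo", 42.6, 0.0, 4.9, -9.7, 9.7),
    ("lateral_meso", 8.7, -2.2, 6.9, -15.8, 11.4),
    ("lateral_epi", -27.7, -2.0, 7.8, -17.4, 13.3),
    ("inferior_endo", 34.2, -0.6, 6.7, -13.6, 12.5),
    ("inferior_meso", 0.7, -1.7, 7.2, -15.9, 12.4),
    ("inferior_epi", -30.8, -3.2, 9.4, -21.7, 15.3),
    ("septal_endo", 33.3, 1.6, 8.0, -14.1, 17.4),
    ("septal_meso", 0.2, -1.8, 6.8, -15.1, 11.6),
    ("septal_epi", -36.7, -4.9, 7.3, -19.3, 9.5),
]

# rows whose printed CoV equals round(100·SD/mean, 1) exactly
COV_CONSISTENT = {
    ("FA", "apical"), ("FA", "mid"), ("FA", "anterior"), ("FA", "lateral"),
    ("MD", "apical"), ("MD", "mid"), ("MD", "anterior"), ("MD", "septal"),
}

# rows whose printed limits equal round(diff ± 1.96·SD, printed precision)
LOA_CONSISTENT = {
    ("FA", "apical"), ("FA", "anterior"), ("FA", "lateral"),
    ("MD", "global"), ("MD", "inferior"),
    ("HA", "global_epi"), ("HA", "apical_meso"), ("HA", "mid_endo"),
    ("HA", "mid_epi"), ("HA", "basal_epi"),
}
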