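"""Published PCA spectra of the reference 414-ear models.

EV columns of the upper-auricle (24 displayed components, total variance
14289) and lobule (18 displayed components, total variance 2226) coordinate
PCA models, used as fixed numeric inputs for selection-rule and
contribution-ratio arithmetic checks.
"""

UPPER_AURICLE_EV = (
    1437.6, 1212.3, 1000.8, 900.3, 709.0, 572.0, 483.4, 449.5, 390.3,
    358.2, 347.4, 335.7, 277.1, 269.6, 258.1, 241.0, 221.2, 205.9, 198.8,
    184.0, 170.4, 158.1, 153.1, 144.2,
)
UPPER_AURICLE_TOTAL = 14289.0
UPPER_AURICLE_CCR = 74.7

LOBULE_EV = (
    399.0, 314.0, 254.0, 220.0, 147.0, 110.0, 99.0, 76.0, 72.0, 58.0,
    50.0, 48.0, 38.0, 34.0, 32.0, 29.0, 25.0, 22.0,
)
LOBULE_TOTAL = 2226.0
LOBULE_CCR = 91.0
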