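"""Published reference values from the Xiong'an New Area RSEI study record.

These printed tables are used as validation inputs: the package's accounting
arithmetic (eigenvalue percent shares, level-area totals and between-year
differences) must reproduce the printed summaries when fed the printed cells.
They are *not* used anywhere in the computational pipeline itself.
"""

from __future__ import annotations

# Covariance eigenvalues of the four-indicator PCA, per study year, and the
# printed PC1 percent-of-variance shares (2-decimal rounding).
PCA_COVARIANCE_EIGENVALUES: dict[int, tuple[float, float, float, float]] = {
    2014: (0.075, 0.003, 0.002, 0.001),
    2017: (0.044, 0.005, 0.002, 0.001),
    2019: (0.109, 0.005, 0.002, 0.001),
    2020: (0.050, 0.002, 0.002, 0.000),
    2021: (0.068, 0.003, 0.003, 0.001),
}

PC1_PERCENT_PRINTED: dict[int, float] = {
    2014: 92.59,
    2017: 84.62,
    2019: 93.16,
    2020: 92.59,
    2021: 90.67,
}

# RSEI level statistics: area (km^2) and percent per level, 2014 and 2021,
# plus the printed 2021-minus-2014 percentage-point difference column.
LEVEL_AREAS_2014 = {5: 259.85, 4: 774.13, 3: 194.59, 2: 201.56, 1: 27.85}
LEVEL_PERCENTS_2014 = {5: 17.82, 4: 53.10, 3: 13.35, 2: 13.82, 1: 1.91}
LEVEL_PERCENTS_2021 = {5: 10.25, 4: 50.34, 3: 16.97, 2: 20.21, 1: 2.24}
LEVEL_PERCENT_DIFF_PRINTED = {5: -7.57, 4: -2.76, 3: 3.62, 2: 6.39, 1: 0.33}
LEVEL_AREA_TOTAL_2014_PRINTED = 1457.98
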