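"""Published summary values from the clinical reproducibility study that this
package emulates in simulation.

Two transcribed tables ship with the package so that every *derived* number
the study reports (tracked-time percentages, bin percentages, MDC halvings,
mean MDC reductions, maxima) can be re-derived from its printed inputs by
:mod:`petmbf.verify`:

* ``MOTION_TABLE`` -- cohort-average motion tracking per phase and axis:
  tracked seconds (and % of acquisition time) plus seconds (and % of tracked
  time) in each motion-intensity bin.
* ``BA_TABLE`` -- Bland-Altman bias, limits-of-agreement range and minimal
  detectable change for every quantity x region x software-pair x
  motion-correction mode cell.

Values are study outputs, not simulation inputs; nothing in the pipeline fits
toward them.
"""

from __future__ import annotations

import pandas as pd

TOTAL_SECONDS = {"rest": 600, "stress": 630}

# (phase, axis) -> tracked seconds, tracked %, then per-bin (seconds, %) for
# <3 / 3-6 / 6-9 / >9 mm, percentages relative to tracked seconds.
MOTION_TABLE = {
    ("rest", "X"): {"tracked_sec": 518, "tracked_pct": 86.3,
                    "bins_sec": (472, 46, 1, 0), "bins_pct": (91.3, 8.5, 0.2, 0.0)},
    ("rest", "Y"): {"tracked_sec": 473, "tracked_pct": 78.8,
                    "bins_sec": (453, 19, 0, 0), "bins_pct": (95.9, 4.0, 0.1, 0.0)},
    ("rest", "Z"): {"tracked_sec": 582, "tracked_pct": 97.0,
                    "bins_sec": (468, 64, 28, 22), "bins_pct": (80.4, 10.9, 4.9, 3.8)},
    ("stress", "X"): {"tracked_sec": 602, "tracked_pct": 95.6,
                      "bins_sec": (578, 24, 0, 0), "bins_pct": (96.1, 3.9, 0.0, 0.0)},
    ("stress", "Y"): {"tracked_sec": 580, "tracked_pct": 92.1,
                      "bins_sec": (549, 30, 1, 0), "bins_pct": (94.7, 5.2, 0.2, 0.0)},
    ("stress", "Z"): {"tracked_sec": 624, "tracked_pct": 99.0,
                      "bins_sec": (453, 84, 50, 37), "bins_pct": (72.6, 13.5, 8.0, 5.9)},
}

COMPARISONS = ("QPET vs 4DM", "QPET vs Syngo", "4DM vs Syngo")
MC_MODES = ("NMC", "ISMC", "DDMC")

# rows: (quantity, region); cells: comparison -> mode -> (bias, loa_range, mdc)
_BA_ROWS = [
    ("rest_mbf", "LAD",
     ((0.09, 0.50, 0.25), (0.06, 0.42, 0.21), (0.10, 0.42, 0.21)),
     ((-0.06, 0.47, 0.23), (-0.04, 0.45, 0.23), (-0.03, 0.49, 0.24)),
     ((-0.16, 0.39, 0.20), (-0.11, 0.33, 0.17), (-0.13, 0.37, 0.18))),
    ("rest_mbf", "Cx",
     ((0.10, 0.51, 0.26), (0.10, 0.37, 0.18), (0.11, 0.59, 0.29)),
     ((-0.01, 0.49, 0.24), (0.03, 0.43, 0.21), (0.03, 0.56, 0.28)),
     ((-0.11, 0.34, 0.17), (-0.08, 0.34, 0.17), (-0.09, 0.34, 0.17))),
    ("rest_mbf", "RCA",
     ((0.04, 0.68, 0.34), (0.08, 0.42, 0.21), (0.09, 0.66, 0.33)),
     ((-0.04, 0.63, 0.32), (-0.04, 0.59, 0.29), (0.05, 0.67, 0.34)),
     ((-0.08, 0.40, 0.20), (-0.12, 0.54, 0.27), (-0.04, 0.29, 0.14))),
    ("rest_mbf", "Global",
     ((0.10, 0.48, 0.24), (0.09, 0.38, 0.19), (0.11, 0.45, 0.23)),
     ((-0.04, 0.47, 0.23), (-0.02, 0.42, 0.21), (0.01, 0.48, 0.24)),
     ((-0.13, 0.37, 0.18), (-0.11, 0.35, 0.17), (-0.11, 0.32, 0.16))),
    ("stress_mbf", "LAD",
     ((0.12, 1.41, 0.70), (0.32, 1.37, 0.69), (0.42, 1.30, 0.65)),
     ((-0.37, 1.78, 0.89), (0.03, 1.55, 0.78), (0.04, 1.16, 0.58)),
     ((-0.49, 1.35, 0.68), (-0.30, 1.15, 0.57), (-0.38, 1.24, 0.62))),
    ("stress_mbf", "Cx",
     ((0.12, 1.93, 0.96), (0.52, 1.53, 0.77), (0.59, 1.19, 0.59)),
     ((-0.28, 2.09, 1.04), (0.25, 1.61, 0.81), (0.14, 1.49, 0.74)),
     ((-0.40, 1.26, 0.63), (-0.27, 1.20, 0.60), (-0.44, 1.25, 0.62))),
    ("stress_mbf", "RCA",
     ((-0.46, 2.07, 1.03), (0.34, 1.55, 0.78), (0.32, 1.20, 0.60)),
     ((-0.79, 2.30, 1.15), (-0.08, 1.78, 0.89), (-0.04, 1.99, 0.99)),
     ((-0.33, 1.23, 0.61), (-0.42, 1.72, 0.86), (-0.36, 1.54, 0.77))),
    ("stress_mbf", "Global",
     ((-0.04, 1.68, 0.84), (0.36, 1.33, 0.67), (0.43, 1.02, 0.51)),
     ((-0.42, 1.91, 0.95), (0.07, 1.53, 0.77), (0.06, 1.30, 0.65)),
     ((-0.38, 1.19, 0.59), (-0.28, 1.15, 0.57), (-0.37, 1.19, 0.59))),
    ("cfr", "LAD",
     ((-0.13, 1.62, 0.81), (0.19, 1.57, 0.79), (0.17, 1.68, 0.84)),
     ((-0.17, 1.86, 0.93), (0.20, 1.86, 0.93), (0.20, 1.69, 0.84)),
     ((-0.04, 1.63, 0.81), (0.00, 1.47, 0.73), (0.03, 1.71, 0.85))),
    ("cfr", "Cx",
     ((-0.18, 1.93, 0.96), (0.22, 1.26, 0.63), (0.30, 1.59, 0.80)),
     ((-0.25, 2.05, 1.02), (0.20, 1.72, 0.86), (0.11, 1.71, 0.85)),
     ((-0.07, 1.47, 0.73), (-0.02, 1.53, 0.77), (-0.18, 1.37, 0.69))),
    ("cfr", "RCA",
     ((-0.67, 2.72, 1.36), (0.16, 2.10, 1.05), (0.15, 2.57, 1.28)),
     ((-0.75, 2.99, 1.50), (0.10, 2.29, 1.15), (-0.09, 3.22, 1.61)),
     ((-0.08, 1.83, 0.92), (-0.06, 1.93, 0.96), (-0.25, 1.63, 0.81))),
    ("cfr", "Global",
     ((-0.33, 1.83, 0.92), (0.13, 1.50, 0.75), (0.15, 1.36, 0.68)),
     ((-0.32, 2.01, 1.00), (0.17, 1.76, 0.88), (0.10, 1.76, 0.88)),
     ((0.02, 1.63, 0.81), (0.04, 1.41, 0.70), (-0.05, 1.47, 0.73))),
]


def ba_table() -> pd.DataFrame:
    """Long-format Bland-Altman summary table."""
    rows = []
    for quantity, region, *cells in _BA_ROWS:
        for comparison, modes in zip(COMPARISONS, cells):
            for mode, (bias, loa_range, mdc) in zip(MC_MODES, modes):
                rows.append({"quantity": quantity, "region": region,
                             "comparison": comparison, "mode": mode,
                             "bias": bias, "loa_range": loa_range, "mdc": mdc})
    return pd.DataFrame(rows)
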