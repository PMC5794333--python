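"""Published study values used as inputs and generating conditions.

These are printed summary numbers from the S. salinarum osmoadaptation
study: per-salinity mean (+/- sd) intracellular osmolyte concentrations,
end-point growth counts under exogenous-osmolyte treatments, and CRF
group summaries from sodium/potassium ion imaging. They serve as worked
-example inputs for the derived metrics and as realistic generating means
for the synthetic-data demonstrations; they are not re-derived by this
package (the underlying replicate-level data were never printed).
"""

from __future__ import annotations

AVERAGE_CELL_VOLUME_PL = 8.01

# intracellular osmolyte concentration, mol/l, by % w/v salinity: (mean, sd)
# (values at 9% and 15% were measured in the study but not printed)
GB_INTRACELLULAR: dict[int, tuple[float, float]] = {
    5: (0.35, 0.2),
    7: (0.72, 0.3),
    11: (0.85, 0.3),
    13: (1.23, 0.3),
    17: (1.21, 0.5),
    19: (1.94, 0.4),
    21: (6.35, 1.04),
}
ECT_INTRACELLULAR: dict[int, tuple[float, float]] = {
    5: (0.09, 0.1),
    11: (0.23, 0.1),
    13: (0.45, 0.1),
    19: (0.64, 0.2),
    21: (2.0, 0.6),
}

N_REPLICATES_PER_SALINITY = 6
SALINITY_GRADIENT_PCT = (5, 7, 9, 11, 13, 15, 17, 19, 21)

# nine-day growth experiment, cells per ml: (mean, sd), triplicate counts,
# 500 cells/ml at inoculation
GROWTH_CELLS_PER_ML: dict[str, tuple[float, float]] = {
    "control": (280.0, 181.0),
    "GB": (983.0, 32.0),
    "Ect": (1380.0, 28.0),
    "Ch": (3247.0, 1557.0),
}
GROWTH_START_CELLS_PER_ML = 500.0

# normalised corrected relative fluorescence, (mean, sd), n = 10 cells/group
CRF_SODIUM: dict[str, tuple[float, float]] = {
    "4%": (46.70, 12.0),
    "9%": (52.03, 14.0),
    "13%": (49.70, 10.0),
    "17%": (47.30, 15.0),
    "21%": (88.70, 15.0),
}
CRF_POTASSIUM: dict[str, tuple[float, float]] = {
    "4%": (17.17, 3.0),
    "10%": (17.04, 4.0),
    "21%": (18.40, 4.0),
}
CRF_N_CELLS = 10


def interpolated_osmolyte_means(salinities=SALINITY_GRADIENT_PCT):
    """Per-salinity (GB, Ect) generating means with gaps filled linearly.

    The printed tables omit some salinities; linear interpolation between
    neighbouring printed values fills them so simulations can cover the
    full gradient. Returns {salinity_pct: (gb_mol_l, ect_mol_l)}.
    """
    import numpy as np

    out = {}
    gb_x = sorted(GB_INTRACELLULAR)
    ect_x = sorted(ECT_INTRACELLULAR)
    for s in salinities:
        gb = float(np.interp(s, gb_x, [GB_INTRACELLULAR[k][0] for k in gb_x]))
        ect = float(np.interp(s, ect_x, [ECT_INTRACELLULAR[k][0] for k in ect_x]))
        out[s] = (gb, ect)
    return out
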