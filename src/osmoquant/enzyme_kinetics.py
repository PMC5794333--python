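"""Michaelis-Menten characterisation of enzymes under salt/osmolyte stress.

Specific activities (U mg^-1, 1 U = 1 umol min^-1) measured across a
substrate series are fitted to v = Vmax * S / (Km + S) by nonlinear least
squares (Hanes-Woolf linearisation supplies starting values). Derived
comparison metrics follow the conventions of salt-stress enzymology:

* specificity constant  Vmax / Km           (U mg^-1 mM^-1)
* residual activity     100 * Vmax / Vmax,ref        (percent)
* osmolyte performance  100 * (Vmax/Km) / (Vmax/Km),ref   (percent)

where the reference condition is typically the low-salt assay buffer
(0.05 M NaCl). ``REFERENCE_KINETICS`` ships published parameter pairs for
malate dehydrogenase (MDH, substrate oxaloacetate) and NADP-dependent
isocitrate dehydrogenase (ICDH, substrate DL-isocitrate) of E. coli and
the halophilic ciliate S. salinarum under four buffer conditions; they
serve as realistic generating values for simulations and as worked-example
inputs for the derived metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

NADH_EPSILON_340 = 6220.0  # M^-1 cm^-1, molar absorptivity of NAD(P)H at 340 nm

LOW_SALT = "0.05 M NaCl"

# Published (Km mM, Vmax U mg^-1) pairs per enzyme and buffer condition.
REFERENCE_KINETICS: dict[str, dict[str, tuple[float, float]]] = {
    "MDH_Ecoli": {
        "0.05 M NaCl": (0.022, 1486.0),
        "1.2 M NaCl": (0.163, 227.0),
        "2.4 M NaCl": (0.26, 78.0),
        "2.5 M GB": (0.018, 273.0),
    },
    "MDH_Ssalinarum": {
        "0.05 M NaCl": (0.038, 2062.0),
        "1.2 M NaCl": (0.20, 314.0),
        "2.4 M NaCl": (0.25, 144.0),
        "2.5 M GB": (0.031, 519.0),
    },
    "ICDH_Ecoli": {
        "0.05 M NaCl": (0.021, 46.0),
        "1.2 M NaCl": (1.2, 12.3),
        "2.4 M NaCl": (3.9, 4.7),
        "2.5 M GB": (0.009, 3.2),
    },
    "ICDH_Ssalinarum": {
        "0.05 M NaCl": (0.019, 6.8),
        "1.2 M NaCl": (0.68, 1.6),
        "2.4 M NaCl": (0.82, 0.32),
        "2.5 M GB": (0.014, 2.4),
    },
}


@dataclass(frozen=True)
class RateSeries:
    """Substrate concentrations (mM) vs specific activities (U mg^-1)."""

    substrate: np.ndarray
    rate: np.ndarray
    condition: str = ""
    enzyme: str = ""

    def __post_init__(self) -> None:
        s = np.asarray(self.substrate, dtype=float)
        v = np.asarray(self.rate, dtype=float)
        if s.ndim != 1 or v.ndim != 1 or s.size != v.size:
            raise ValueError("substrate and rate must be equal-length 1-D arrays")
        if s.size < 3:
            raise ValueError("a rate series needs at least 3 measurements")
        if (s <= 0).any():
            raise ValueError("substrate concentrations must be > 0")
        if (v < 0).any():
            raise ValueError("rates must be >= 0")
        object.__setattr__(self, "substrate", s)
        object.__setattr__(self, "rate", v)


@dataclass(frozen=True)
class KineticFit:
    """Fitted Michaelis-Menten parameters with uncertainties."""

    Km: float          # mM
    Vmax: float        # U mg^-1
    Km_se: float
    Vmax_se: float
    rss: float         # residual sum of squares
    condition: str = ""
    enzyme: str = ""

    def __post_init__(self) -> None:
        if self.Km <= 0 or self.Vmax <= 0:
            raise ValueError("Km and Vmax must be > 0")

    @property
    def specificity_constant(self) -> float:
        return self.Vmax / self.Km


def michaelis_menten(s, vmax, km):
    return vmax * s / (km + s)


def rates_from_absorbance(
    a340: np.ndarray,
    epsilon: float = NADH_EPSILON_340,
    path_cm: float = 1.0,
    protein_mg: float = 1.0,
    volume_l: float = 1e-3,
    direction: str = "decrease",
    initial_points: int | None = None,
) -> float:
    """Specific activity (U mg^-1) from an A340 time trace.

    ``a340`` is an (n, 2) array of (time in minutes, absorbance). The
    initial slope |dA/dt| is estimated by least squares over the first
    ``initial_points`` samples (default: the first fifth, at least 3),
    converted to molarity per minute via Beer-Lambert (dc = dA / (eps * l)),
    then to umol min^-1 mg^-1 with the assay volume and protein mass.

    NADH-coupled assays run in a fixed direction ("decrease" for NADH
    consumption, "increase" for NADP+ reduction); an early trace trending
    the wrong way triggers a warning but the magnitude is still reported.
    """
    a = np.asarray(a340, dtype=float)
    if a.ndim != 2 or a.shape[1] != 2 or a.shape[0] < 2:
        raise ValueError("a340 must be an (n>=2, 2) array of (minutes, A)")
    if protein_mg <= 0 or epsilon <= 0 or path_cm <= 0 or volume_l <= 0:
        raise ValueError("epsilon, path, protein and volume must be > 0")
    if direction not in ("decrease", "increase"):
        raise ValueError("direction must be 'decrease' or 'increase'")
    n = initial_points or max(3, a.shape[0] // 5)
    n = min(max(n, 2), a.shape[0])
    t, y = a[:n, 0], a[:n, 1]
    slope = float(np.polyfit(t, y, 1)[0])
    expected_sign = -1.0 if direction == "decrease" else 1.0
    span = float(np.ptp(y))
    if span > 0 and slope * expected_sign < -0.05 * span / max(np.ptp(t), 1e-12):
        warnings.warn(
            f"initial A340 trace trends opposite to the configured "
            f"'{direction}' direction; reporting |slope| anyway",
            stacklevel=2,
        )
    molar_per_min = abs(slope) / (epsilon * path_cm)       # mol/l per min
    umol_per_min = molar_per_min * volume_l * 1e6          # U
    return umol_per_min / protein_mg


def fit_mm(data: RateSeries) -> KineticFit:
    """Nonlinear least-squares fit of the Michaelis-Menten equation.

    Minimises sum (v_i - Vmax S_i/(Km+S_i))^2 with positivity bounds.
    Starting values come from the Hanes-Woolf linearisation (S/v vs S).
    Fails if fewer than 3 distinct substrate levels are present, if the
    optimiser does not converge, or if the fitted Km exceeds 100x the
    largest substrate concentration (the plateau is then unconstrained).
    """
    s, v = data.substrate, data.rate
    if np.unique(s).size < 3:
        raise ValueError("need >= 3 distinct substrate concentrations")

    pos = v > 0
    if pos.sum() >= 2:
        # Hanes-Woolf: S/v = S/Vmax + Km/Vmax
        slope, intercept = np.polyfit(s[pos], s[pos] / v[pos], 1)
        vmax0 = 1.0 / slope if slope > 0 else float(v.max())
        km0 = intercept * vmax0 if intercept > 0 else float(np.median(s))
    else:
        vmax0, km0 = float(max(v.max(), 1e-9)), float(np.median(s))
    vmax0 = max(vmax0, 1e-12)
    km0 = max(km0, 1e-12)

    try:
        popt, pcov = curve_fit(
            michaelis_menten, s, v, p0=[vmax0, km0],
            bounds=([1e-15, 1e-15], [np.inf, np.inf]), maxfev=20000,
        )
    except RuntimeError as err:
        raise ValueError(f"Michaelis-Menten fit did not converge: {err}") from err
    vmax, km = float(popt[0]), float(popt[1])
    if km > 100.0 * float(s.max()):
        raise ValueError(
            f"fitted Km {km:.3g} mM exceeds 100x the largest substrate "
            f"concentration ({s.max():.3g} mM): the data do not constrain "
            "saturation"
        )
    se = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(2, np.nan)
    resid = v - michaelis_menten(s, *popt)
    return KineticFit(
        Km=km, Vmax=vmax, Km_se=float(se[1]), Vmax_se=float(se[0]),
        rss=float(resid @ resid), condition=data.condition, enzyme=data.enzyme,
    )


def specificity_constant(fit: KineticFit) -> float:
    """Vmax / Km in U mg^-1 mM^-1 (catalytic efficiency proxy)."""
    return fit.Vmax / fit.Km


def residual_activity(fit: KineticFit, reference_fit: KineticFit) -> float:
    """Percent of the reference Vmax retained: 100 * Vmax / Vmax_ref."""
    if reference_fit.Vmax <= 0:
        raise ValueError("reference Vmax must be > 0")
    return 100.0 * fit.Vmax / reference_fit.Vmax


def osmolyte_performance(fit: KineticFit, reference_fit: KineticFit) -> float:
    """Percent of the reference specificity constant retained."""
    ref = specificity_constant(reference_fit)
    if ref <= 0:
        raise ValueError("reference specificity constant must be > 0")
    return 100.0 * specificity_constant(fit) / ref


def published_fit(enzyme: str, condition: str) -> KineticFit:
    """A :class:`KineticFit` carrying published Km/Vmax (no uncertainties)."""
    km, vmax = REFERENCE_KINETICS[enzyme][condition]
    return KineticFit(Km=km, Vmax=vmax, Km_se=float("nan"),
                      Vmax_se=float("nan"), rss=float("nan"),
                      condition=condition, enzyme=enzyme)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_rates_csv(path) -> list[RateSeries]:
    """Read (substrate_mM, rate_U_per_mg, condition[, enzyme]) CSV into series."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"substrate_mM", "rate_U_per_mg"}
    if not required <= set(df.columns):
        raise ValueError(f"rates CSV must contain columns {sorted(required)}")
    if "condition" not in df.columns:
        df["condition"] = ""
    if "enzyme" not in df.columns:
        df["enzyme"] = ""
    out = []
    for (enzyme, condition), grp in df.groupby(["enzyme", "condition"], sort=True):
        out.append(
            RateSeries(grp["substrate_mM"].to_numpy(),
                       grp["rate_U_per_mg"].to_numpy(),
                       condition=str(condition), enzyme=str(enzyme))
        )
    return out


def fits_to_csv(fits: list[KineticFit], path,
                reference_condition: str = LOW_SALT) -> None:
    """Summary table mirroring the usual reporting columns.

    One row per fit: Km, Vmax, specificity constant, and — when a fit for
    ``reference_condition`` of the same enzyme is present — residual
    activity and osmolyte performance relative to it.
    """
    import pandas as pd

    refs = {f.enzyme: f for f in fits if f.condition == reference_condition}
    rows = []
    for f in fits:
        ref = refs.get(f.enzyme)
        rows.append(
            {
                "enzyme": f.enzyme,
                "condition": f.condition,
                "Km_mM": f.Km,
                "Vmax_U_per_mg": f.Vmax,
                "specificity_constant": specificity_constant(f),
                "residual_activity_pct": residual_activity(f, ref) if ref else float("nan"),
                "osmolyte_performance_pct": osmolyte_performance(f, ref) if ref else float("nan"),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
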