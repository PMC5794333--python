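"""Synthetic data generators with known ground truth.

Every downstream stage of the package (NMR quantification, ion-image CRF,
Michaelis-Menten fitting, growth statistics) is exercised against data from
these generators, so the whole pipeline is testable without any external
download. Generators are deterministic given their seed.

Simulated spectra use Lorentzian lines (1.5 Hz FWHM default, a typical
solution-state proton linewidth); multiplets are first-order with binomial
intensity patterns; a peak's integrated area is ``concentration x proton
count`` in (mol/l)·ppm units. 13C-labelled species produce symmetric
doublets split by the one-bond 1J(13C-H) coupling (144 Hz default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import comb

from .references import (
    InternalStandardSpec,
    MULTIPLICITIES,
    SolutePeak,
    SoluteReference,
    default_library,
)
from .spectra import Spectrum1D

DEFAULT_J_CH_HZ = 144.0  # one-bond 13C-1H coupling


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpectrumSimConfig:
    """Axis, lineshape and noise settings for simulated 1H spectra."""

    ppm_min: float = -0.5
    ppm_max: float = 10.5
    n_points: int = 65536
    spectrometer_freq: float = 400.0  # MHz
    linewidth: float = 1.5            # Hz, full width at half maximum
    noise_sd: float = 0.0             # additive Gaussian, intensity units
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ppm_min >= self.ppm_max:
            raise ValueError("ppm_min must be < ppm_max")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if self.linewidth <= 0:
            raise ValueError("linewidth must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.spectrometer_freq <= 0:
            raise ValueError("spectrometer_freq must be > 0")


@dataclass(frozen=True)
class ImageSimConfig:
    """Three-stratum fluorescence micrograph: background < cytoplasm < vacuole.

    The cell is an axis-aligned ellipse, the vacuole a disk strictly inside
    it. Intensities are arbitrary camera units; noise is additive Gaussian
    clipped at zero.
    """

    height: int = 128
    width: int = 128
    background_level: float = 10.0
    cytoplasm_level: float = 50.0
    vacuole_level: float = 120.0
    cell_center: tuple[float, float] = (64.0, 64.0)   # (row, col)
    cell_axes: tuple[float, float] = (40.0, 28.0)     # (semi-row, semi-col)
    vacuole_center: tuple[float, float] = (70.0, 64.0)
    vacuole_radius: float = 10.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.background_level < self.cytoplasm_level < self.vacuole_level):
            raise ValueError(
                "levels must satisfy 0 <= background < cytoplasm < vacuole"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if min(self.height, self.width) < 8:
            raise ValueError("image too small")


@dataclass(frozen=True)
class KineticsSimConfig:
    """Michaelis-Menten rate series with multiplicative Gaussian noise."""

    true_Km: float                     # mM
    true_Vmax: float                   # U mg^-1
    substrate_concs: tuple[float, ...] # mM
    noise_cv: float = 0.0              # coefficient of variation
    replicates: int = 1
    seed: int = 0
    condition: str = "simulated"
    enzyme: str = "simulated"

    def __post_init__(self) -> None:
        if self.true_Km <= 0 or self.true_Vmax <= 0:
            raise ValueError("true_Km and true_Vmax must be > 0")
        if len(self.substrate_concs) == 0 or min(self.substrate_concs) <= 0:
            raise ValueError("substrate_concs must be strictly positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass(frozen=True)
class GrowthSimConfig:
    """Replicated end-point cell counts for a control and named treatments."""

    control_mean: float = 280.0  # cells per ml
    treatment_means: dict[str, float] = field(
        default_factory=lambda: {"GB": 983.0, "Ect": 1380.0, "Ch": 3247.0}
    )
    sd_fraction: float = 0.1
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.control_mean < 0 or any(m < 0 for m in self.treatment_means.values()):
            raise ValueError("means must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.sd_fraction < 0:
            raise ValueError("sd_fraction must be >= 0")


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

def _lorentzian(ppm: np.ndarray, center: float, fwhm_ppm: float, area: float) -> np.ndarray:
    hwhm = fwhm_ppm / 2.0
    return area * hwhm / (np.pi * ((ppm - center) ** 2 + hwhm**2))


def _add_peak(
    out: np.ndarray,
    ppm: np.ndarray,
    peak: SolutePeak,
    area: float,
    fwhm_ppm: float,
    freq: float,
) -> None:
    """Add one (possibly multiplet) resonance with total integrated ``area``."""
    n_lines = MULTIPLICITIES[peak.multiplicity]
    if n_lines == 1:
        out += _lorentzian(ppm, peak.shift, fwhm_ppm, area)
        return
    # first-order multiplet: binomial weights, lines spaced by J
    j_ppm = peak.j_hz / freq
    weights = np.array([comb(n_lines - 1, k) for k in range(n_lines)], dtype=float)
    weights /= weights.sum()
    offsets = (np.arange(n_lines) - (n_lines - 1) / 2.0) * j_ppm
    for w, off in zip(weights, offsets):
        out += _lorentzian(ppm, peak.shift + off, fwhm_ppm, area * w)


def _axis(cfg: SpectrumSimConfig) -> np.ndarray:
    return np.linspace(cfg.ppm_max, cfg.ppm_min, cfg.n_points)  # descending


def simulate_spectrum(
    concentrations: dict[str, float],
    standard_conc: float,
    library: dict[str, SoluteReference] | None = None,
    cfg: SpectrumSimConfig | None = None,
    standard: InternalStandardSpec | None = None,
) -> Spectrum1D:
    """Simulate a 1H spectrum of a solute mixture plus internal standard.

    Each reference peak of each named solute appears with integrated area
    ``concentration x n_protons``; the internal standard (TMSP by default)
    appears at its shift with area ``standard_conc x 9``. Additive Gaussian
    noise with sd ``cfg.noise_sd`` is applied to the whole trace.
    """
    cfg = cfg or SpectrumSimConfig()
    library = library if library is not None else default_library()
    standard = standard or InternalStandardSpec(concentration=max(standard_conc, 1e-12))
    ppm = _axis(cfg)
    fwhm_ppm = cfg.linewidth / cfg.spectrometer_freq
    out = np.zeros_like(ppm)

    for name in sorted(concentrations):  # order-independent float accumulation
        conc = concentrations[name]
        if name not in library:
            raise KeyError(
                f"unknown solute {name!r}; library has {sorted(library)}"
            )
        if conc < 0:
            raise ValueError(f"negative concentration for {name}")
        for peak in library[name].peaks:
            _add_peak(out, ppm, peak, conc * peak.n_protons, fwhm_ppm,
                      cfg.spectrometer_freq)

    if standard_conc < 0:
        raise ValueError("standard_conc must be >= 0")
    if standard_conc > 0:
        std_peak = standard.as_reference().quantification_peak
        _add_peak(out, ppm, std_peak, standard_conc * std_peak.n_protons,
                  fwhm_ppm, cfg.spectrometer_freq)

    if cfg.noise_sd > 0:
        rng = np.random.default_rng(cfg.seed)
        out = out + rng.normal(0.0, cfg.noise_sd, size=out.shape)
    return Spectrum1D(ppm, out, cfg.spectrometer_freq)


def simulate_labeled_spectrum(
    unlabeled_GB: float,
    labeled_GB: float,
    other: dict[str, float] | None = None,
    cfg: SpectrumSimConfig | None = None,
    standard_conc: float = 0.05,
    library: dict[str, SoluteReference] | None = None,
    j_ch_hz: float = DEFAULT_J_CH_HZ,
) -> Spectrum1D:
    """Simulate a mixture of unlabelled and 1,2-13C2-labelled glycine betaine.

    Unlabelled GB contributes its normal singlets. The doubly 13C-labelled
    species contributes, for each GB resonance, a symmetric satellite doublet
    centred at the same shift and split by ``j_ch_hz`` (so each satellite
    sits at shift +/- J/(2 x spectrometer frequency) ppm), with total area
    equal to the corresponding singlet area at equal concentration.
    ``other`` maps additional solute names (e.g. "Ect") to concentrations.
    """
    if unlabeled_GB < 0 or labeled_GB < 0:
        raise ValueError("concentrations must be >= 0")
    cfg = cfg or SpectrumSimConfig()
    library = library if library is not None else default_library()
    base = dict(other or {})
    base["GB"] = base.get("GB", 0.0) + unlabeled_GB
    spec = simulate_spectrum(base, standard_conc, library, cfg)
    if labeled_GB == 0:
        return spec

    ppm = spec.ppm
    out = spec.intensity.copy()
    fwhm_ppm = cfg.linewidth / cfg.spectrometer_freq
    half_split = j_ch_hz / (2.0 * cfg.spectrometer_freq)
    for peak in library["GB"].peaks:
        area = labeled_GB * peak.n_protons
        for sign in (-1.0, 1.0):
            out += _lorentzian(ppm, peak.shift + sign * half_split, fwhm_ppm,
                               area / 2.0)
    return Spectrum1D(ppm, out, cfg.spectrometer_freq)


# ---------------------------------------------------------------------------
# micrographs
# ---------------------------------------------------------------------------

def simulate_ion_image(cfg: ImageSimConfig):
    """Simulate a three-stratum fluorescence micrograph and its true masks.

    Returns ``(image, truth)`` where ``truth`` is a
    :class:`~osmoquant.ion_imaging.SegmentationResult` holding the exact
    generating masks, the midpoint thresholds that reproduce them on the
    noise-free image, and the default four corner background regions.
    """
    from .ion_imaging import SegmentationResult, corner_regions

    rows, cols = np.mgrid[0 : cfg.height, 0 : cfg.width]
    cr, cc = cfg.cell_center
    ar, ac = cfg.cell_axes
    cell = ((rows - cr) / ar) ** 2 + ((cols - cc) / ac) ** 2 <= 1.0
    vr, vc = cfg.vacuole_center
    vac = (rows - vr) ** 2 + (cols - vc) ** 2 <= cfg.vacuole_radius**2
    if not cell.any():
        raise ValueError("cell geometry does not fit inside the frame")
    if vac.any() and not cell[vac].all():
        raise ValueError("vacuole must lie inside the cell")

    cyt = cell & ~vac
    img = np.full((cfg.height, cfg.width), cfg.background_level, dtype=float)
    img[cyt] = cfg.cytoplasm_level
    img[vac] = cfg.vacuole_level
    if cfg.noise_sd > 0:
        rng = np.random.default_rng(cfg.seed)
        img = np.clip(img + rng.normal(0.0, cfg.noise_sd, img.shape), 0.0, None)

    t_low = (cfg.background_level + cfg.cytoplasm_level) / 2.0
    t_high = (cfg.cytoplasm_level + cfg.vacuole_level) / 2.0
    truth = SegmentationResult(
        background=~cell,
        cytoplasm=cyt,
        vacuole=vac,
        thresholds=(t_low, t_high),
        background_regions=corner_regions(cfg.height, cfg.width),
    )
    return img, truth


# ---------------------------------------------------------------------------
# kinetics and growth
# ---------------------------------------------------------------------------

def simulate_rate_data(cfg: KineticsSimConfig):
    """Simulate substrate-vs-specific-activity data.

    ``v_i = Vmax * S_i / (Km + S_i) * (1 + eps_i)`` with
    ``eps_i ~ Normal(0, noise_cv)``; rates floored at 0.
    """
    from .enzyme_kinetics import RateSeries

    rng = np.random.default_rng(cfg.seed)
    s = np.repeat(np.asarray(cfg.substrate_concs, dtype=float), cfg.replicates)
    v_true = cfg.true_Vmax * s / (cfg.true_Km + s)
    if cfg.noise_cv > 0:
        v = v_true * (1.0 + rng.normal(0.0, cfg.noise_cv, size=s.shape))
    else:
        v = v_true.copy()
    return RateSeries(
        substrate=s, rate=np.clip(v, 0.0, None),
        condition=cfg.condition, enzyme=cfg.enzyme,
    )


def simulate_growth(cfg: GrowthSimConfig) -> pd.DataFrame:
    """Simulate end-point cell counts (cells/ml), truncated at zero.

    Returns a tidy frame with columns ``treatment, replicate, cells_per_ml``;
    the control group is labelled ``"control"``.
    """
    rng = np.random.default_rng(cfg.seed)
    rows = []
    groups = {"control": cfg.control_mean, **cfg.treatment_means}
    for name, mean in groups.items():
        sd = cfg.sd_fraction * mean
        counts = mean + rng.normal(0.0, sd, cfg.n_replicates) if sd > 0 else np.full(
            cfg.n_replicates, float(mean)
        )
        for i, c in enumerate(counts):
            rows.append({"treatment": name, "replicate": i + 1,
                         "cells_per_ml": max(float(c), 0.0)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_rates_csv(series, path) -> None:
    """CSV with columns substrate_mM, rate_U_per_mg, condition, enzyme."""
    pd.DataFrame(
        {
            "substrate_mM": series.substrate,
            "rate_U_per_mg": series.rate,
            "condition": series.condition,
            "enzyme": series.enzyme,
        }
    ).to_csv(path, index=False)


def write_counts_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_image_tiff(img: np.ndarray, path) -> None:
    """Write a 16-bit grayscale TIFF (values clipped to the uint16 range)."""
    import tifffile

    tifffile.imwrite(path, np.clip(np.round(img), 0, 65535).astype(np.uint16))


def write_image_pgm(img: np.ndarray, path) -> None:
    """Write plain (ASCII, P2) PGM, 16-bit maxval."""
    arr = np.clip(np.round(img), 0, 65535).astype(int)
    h, w = arr.shape
    lines = [f"P2\n{w} {h}\n65535"]
    for row in arr:
        lines.append(" ".join(str(v) for v in row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
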