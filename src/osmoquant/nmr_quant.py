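"""Internal-standard quantification of compatible solutes from 1H spectra.

Workflow: detect peaks above a noise-scaled threshold, assign them to
library solutes by chemical shift, integrate each solute's designated
quantification peak and the internal standard over identical windows, and
convert the area ratio to a molar tube concentration:

    c_s = (A_s / A_std) * (n_H,std / n_H,s) * c_std

Because every quantification line shares the same Lorentzian width, the
finite integration window truncates all peaks by the same factor and the
ratio is unbiased. Tube concentrations are scaled to intracellular
molarity with the sampled cell count and the geometric cell volume.

A separate routine resolves 13C2-labelled from unlabelled glycine betaine:
the labelled species appears as satellite doublets split by the one-bond
1J(13C-H) coupling, so its concentration is read from the summed satellite
areas while the unlabelled pool keeps the central singlet.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .references import (
    InternalStandardSpec,
    SolutePeak,
    SoluteReference,
    default_library,
)
from .spectra import Spectrum1D

HOD_WINDOW = (4.6, 4.9)  # residual semi-heavy water, excluded from peak picking


@dataclass(frozen=True)
class PeakAssignment:
    """A reference peak matched to a detected peak."""

    solute: str
    reference: SolutePeak
    detected_shift: float
    shift_error: float
    area: float = np.nan  # filled by quantification when integrated

    def __post_init__(self) -> None:
        if not np.isnan(self.area) and self.area < 0:
            raise ValueError("area must be >= 0")


@dataclass(frozen=True)
class QuantResult:
    """Tube and intracellular concentrations with the scaling inputs echoed."""

    tube_molarity: dict[str, float]          # mol/l in the NMR tube
    intracellular_molarity: dict[str, float] # mol/l in the cell
    n_cells: float
    sample_volume_l: float
    cell_volume_pl: float


# ---------------------------------------------------------------------------
# peak detection and assignment
# ---------------------------------------------------------------------------

def _noise_sigma(spec: Spectrum1D, trace: np.ndarray,
                 noise_region: tuple[float, float]) -> float:
    """Robust noise sd: 1.4826 x MAD of a signal-free region of ``trace``."""
    lo, hi = min(noise_region), max(noise_region)
    mask = (spec.ppm >= lo) & (spec.ppm <= hi)
    region = trace[mask] if mask.sum() >= 16 else trace
    mad = np.median(np.abs(region - np.median(region)))
    return 1.4826 * float(mad)


def detect_peaks(
    spec: Spectrum1D,
    min_snr: float = 3.0,
    exclusion_windows: tuple[tuple[float, float], ...] = (HOD_WINDOW,),
    noise_region: tuple[float, float] = (9.0, 10.0),
    smooth_points: int = 11,
) -> list[tuple[float, float]]:
    """Detect peaks as local maxima exceeding ``min_snr`` x the noise level.

    The trace is lightly Savitzky-Golay smoothed before maximum-finding
    (set ``smooth_points=0`` to disable); the noise level is the MAD-based
    sd of a signal-free region of the same trace, so threshold and noise
    estimate are consistent. Peaks inside exclusion windows (default: the
    HOD region 4.6-4.9 ppm) are discarded. Returns ``(shift, height)``
    pairs sorted by shift descending; an all-flat spectrum yields ``[]``.
    """
    if min_snr <= 0:
        raise ValueError("min_snr must be > 0")
    y = spec.intensity
    if smooth_points and smooth_points >= 5 and len(spec) > smooth_points:
        y = savgol_filter(y, smooth_points, polyorder=2)
    sigma = _noise_sigma(spec, y, noise_region)
    floor = 1e-12 * max(1.0, float(np.max(np.abs(y))))
    height = max(min_snr * sigma, floor)
    idx, props = find_peaks(y, height=height)
    shifts = spec.ppm[idx]
    heights = props["peak_heights"]
    keep = np.ones(len(idx), dtype=bool)
    for lo, hi in exclusion_windows:
        lo, hi = min(lo, hi), max(lo, hi)
        keep &= ~((shifts >= lo) & (shifts <= hi))
    order = np.argsort(-shifts[keep])
    return [(float(s), float(h)) for s, h in
            zip(shifts[keep][order], heights[keep][order])]


def assign_solutes(
    peaks: list[tuple[float, float]],
    library: dict[str, SoluteReference] | None = None,
    tol: float = 0.03,
) -> list[PeakAssignment]:
    """Match reference peaks to detected peaks by nearest shift within ``tol``.

    A solute is identified only if every one of its reference peaks finds a
    match; partially matched solutes contribute no assignments. Within one
    solute each detected peak is used at most once (greedy nearest; ties
    resolved toward the lower-ppm detected peak). Input peak order does not
    affect the result.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    library = library if library is not None else default_library()
    detected = sorted((float(s) for s, _ in peaks))
    out: list[PeakAssignment] = []
    for name in sorted(library):
        ref = library[name]
        used: set[int] = set()
        matches: list[PeakAssignment] = []
        # process reference peaks in a deterministic order
        for rp in sorted(ref.peaks, key=lambda p: -p.shift):
            best_i, best_d = -1, np.inf
            for i, ds in enumerate(detected):
                if i in used:
                    continue
                d = abs(ds - rp.shift)
                if d > tol:
                    continue
                # strictly nearer, or equidistant but lower ppm
                if d < best_d or (d == best_d and ds < detected[best_i]):
                    best_i, best_d = i, d
            if best_i < 0:
                matches = []
                break
            used.add(best_i)
            matches.append(
                PeakAssignment(name, rp, detected[best_i],
                               detected[best_i] - rp.shift)
            )
        out.extend(matches)
    return out


def identified_solutes(assignments: list[PeakAssignment]) -> set[str]:
    return {a.solute for a in assignments}


# ---------------------------------------------------------------------------
# integration and quantification
# ---------------------------------------------------------------------------

def integrate_peak(
    spec: Spectrum1D,
    center: float,
    window: float,
    baseline_margin_frac: float = 0.25,
) -> float:
    """Trapezoidal peak area over ``center +/- window`` minus a linear baseline.

    The baseline is a straight line through the two window endpoints; each
    endpoint value is the mean intensity over a small flanking margin
    (``baseline_margin_frac`` of the window to each side) so a few noisy
    samples cannot dominate the correction. The area is floored at zero.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    lo, hi = center - window, center + window
    if lo < spec.ppm_min or hi > spec.ppm_max:
        raise ValueError(
            f"window [{lo:.4g}, {hi:.4g}] ppm outside axis "
            f"[{spec.ppm_min:.4g}, {spec.ppm_max:.4g}]"
        )
    ppm, y = spec.ppm, spec.intensity
    sel = (ppm >= lo) & (ppm <= hi)
    if sel.sum() < 3:
        raise ValueError("window contains fewer than 3 points")
    x_w = ppm[sel][::-1]  # ascending for integration
    y_w = y[sel][::-1]

    m = window * baseline_margin_frac
    def _edge_mean(edge: float) -> float:
        em = (ppm >= edge - m) & (ppm <= edge + m)
        return float(np.mean(y[em])) if em.any() else float(
            y[np.argmin(np.abs(ppm - edge))]
        )

    y_lo, y_hi = _edge_mean(lo), _edge_mean(hi)
    baseline = y_lo + (y_hi - y_lo) * (x_w - lo) / (hi - lo)
    area = float(np.trapezoid(y_w - baseline, x_w))
    return max(area, 0.0)


def quantify(
    spec: Spectrum1D,
    library: dict[str, SoluteReference] | None = None,
    standard: InternalStandardSpec | None = None,
    tol: float = 0.03,
    window: float = 0.05,
    min_snr: float = 3.0,
) -> dict[str, float]:
    """Quantify every library solute against the internal standard.

    Returns a map ``solute -> mol/l in the tube``; solutes not identified in
    the spectrum map to 0.0. Raises ``ValueError`` if the standard peak is
    not detectable (the spectrum is then unusable for quantification).
    """
    library = library if library is not None else default_library()
    standard = standard or InternalStandardSpec()
    peaks = detect_peaks(spec, min_snr=min_snr)

    std_candidates = [s for s, _ in peaks if abs(s - standard.shift) <= tol]
    if not std_candidates:
        raise ValueError(
            f"internal standard {standard.name} not detected near "
            f"{standard.shift} ppm; spectrum unusable for quantification"
        )
    std_shift = min(std_candidates, key=lambda s: abs(s - standard.shift))
    a_std = integrate_peak(spec, std_shift, window)
    if a_std <= 0:
        raise ValueError("internal standard peak has zero integrated area")

    assignments = assign_solutes(peaks, library, tol)
    by_solute = {}
    for a in assignments:
        by_solute.setdefault(a.solute, []).append(a)

    out: dict[str, float] = {}
    for name, ref in library.items():
        if name == standard.name:
            continue
        if name not in by_solute:
            out[name] = 0.0
            continue
        qp = ref.quantification_peak
        match = next(a for a in by_solute[name] if a.reference == qp)
        a_s = integrate_peak(spec, match.detected_shift, window)
        out[name] = (a_s / a_std) * (standard.n_protons / qp.n_protons) * \
            standard.concentration
    return out


def intracellular_concentration(
    tube_conc: float,
    sample_volume_l: float,
    n_cells: float,
    cell_volume_pl: float,
) -> float:
    """Scale a tube concentration to intracellular molarity.

    The solute amount in the tube (``tube_conc x sample_volume``) came from
    ``n_cells`` cells of volume ``cell_volume_pl`` picolitres, so the
    intracellular concentration is

        c_cell = tube_conc * sample_volume / (n_cells * cell_volume)

    with the cell volume converted from pl to litres (1 pl = 1e-12 l).
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be > 0")
    if cell_volume_pl <= 0:
        raise ValueError("cell_volume_pl must be > 0")
    if sample_volume_l < 0 or tube_conc < 0:
        raise ValueError("tube_conc and sample_volume must be >= 0")
    return tube_conc * sample_volume_l / (n_cells * cell_volume_pl * 1e-12)


def quantify_intracellular(
    spec: Spectrum1D,
    n_cells: float,
    sample_volume_l: float = 600e-6,
    cell_volume_pl: float = 8.01,
    library: dict[str, SoluteReference] | None = None,
    standard: InternalStandardSpec | None = None,
    tol: float = 0.03,
    window: float = 0.05,
) -> QuantResult:
    """Full quantification: tube molarities plus intracellular scaling."""
    tube = quantify(spec, library, standard, tol=tol, window=window)
    intra = {
        k: intracellular_concentration(v, sample_volume_l, n_cells, cell_volume_pl)
        for k, v in tube.items()
    }
    return QuantResult(tube, intra, n_cells, sample_volume_l, cell_volume_pl)


# ---------------------------------------------------------------------------
# labelled / unlabelled glycine betaine
# ---------------------------------------------------------------------------

def label_ratio(
    spec: Spectrum1D,
    library: dict[str, SoluteReference] | None = None,
    standard: InternalStandardSpec | None = None,
    j_ch_hz: float = 144.0,
    tol: float = 0.03,
    window: float = 0.015,
) -> tuple[float, float, float]:
    """Resolve (unlabelled GB, 13C2-labelled GB, Ect) as a normalised ratio.

    Unlabelled glycine betaine is integrated at the central trimethyl
    singlet; the labelled pool from the two 13C satellites at
    ``shift +/- J/(2 x spectrometer frequency)``; ectoine at its
    quantification peak. All areas are proton-count corrected and the
    ratio is normalised so the smallest nonzero component equals 1.
    """
    library = library if library is not None else default_library()
    gb_peak = library["GB"].quantification_peak
    ect_peak = library["Ect"].quantification_peak
    half_split = j_ch_hz / (2.0 * spec.spectrometer_freq)
    if half_split <= 2.0 * window:
        raise ValueError(
            f"satellite offset {half_split:.4f} ppm <= 2 x window {window} ppm: "
            "satellites overlap the central peak; decrease the window or "
            "increase J / spectrometer frequency"
        )
    a_central = integrate_peak(spec, gb_peak.shift, window)
    # the doublet is symmetric, so twice the upfield satellite equals the
    # summed satellite area; the downfield satellite (shift + J/2, ~3.45 ppm
    # at 144 Hz / 400 MHz) collides with ectoine's 3.44 ppm methylene line
    # and is therefore not integrated
    a_sat = 2.0 * integrate_peak(spec, gb_peak.shift - half_split, window)
    a_ect = integrate_peak(spec, ect_peak.shift, window)

    comps = np.array([
        a_central / gb_peak.n_protons,
        a_sat / gb_peak.n_protons,
        a_ect / ect_peak.n_protons,
    ])
    if comps.max() <= 0:
        return (0.0, 0.0, 0.0)
    # neighbouring-line tails and baseline ripple leave a small residue
    # where a species is absent; below 2% of the largest component it is
    # indistinguishable from interference and counts as zero
    comps[comps < 0.02 * comps.max()] = 0.0
    comps = comps / comps[comps > 0].min()
    return (float(comps[0]), float(comps[1]), float(comps[2]))


# ---------------------------------------------------------------------------
# output helpers
# ---------------------------------------------------------------------------

def quant_result_to_csv(result: QuantResult, path) -> None:
    """CSV with columns solute, tube_molarity, intracellular_molarity."""
    import pandas as pd

    rows = [
        {
            "solute": name,
            "tube_molarity": result.tube_molarity[name],
            "intracellular_molarity": result.intracellular_molarity[name],
        }
        for name in sorted(result.tube_molarity)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_run_record(path, **params) -> None:
    """JSON record of every parameter that affected a quantification run."""
    import json

    with open(path, "w") as fh:
        json.dump(params, fh, indent=2, sort_keys=True, default=str)
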