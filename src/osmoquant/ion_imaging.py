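"""Corrected relative fluorescence (CRF) from ion-imaging micrographs.

A grayscale micrograph of a dye-loaded cell is segmented into three
intensity strata — background, cytoplasm, and bright vacuole-like
inclusions — either by explicit thresholds or by two-threshold
between-class-variance maximisation (3-class Otsu). The background level
I_B is the mean of four rectangular background regions (image corners by
default). The cytoplasm signal is then background-corrected:

    CRF_C    = I_C,total - A_C * I_B      (summed cytoplasm intensity
                                           minus the matching background mass)
    CRF_norm = CRF_C / A_C                (per-pixel corrected intensity)

Vacuole pixels are excluded from the cytoplasm integral; vacuole
statistics are reported separately. CRF values are relative (arbitrary
camera units), not calibrated ion molarities.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

Rect = tuple[int, int, int, int]  # (row0, col0, height, width)


@dataclass(frozen=True)
class SegmentationResult:
    """Disjoint stratum masks, the thresholds used, and background ROIs."""

    background: np.ndarray
    cytoplasm: np.ndarray
    vacuole: np.ndarray
    thresholds: tuple[float, float]
    background_regions: tuple[Rect, Rect, Rect, Rect]

    def __post_init__(self) -> None:
        t_low, t_high = self.thresholds
        if t_low >= t_high:
            raise ValueError("thresholds must satisfy t_low < t_high")
        if len(self.background_regions) != 4:
            raise ValueError("exactly 4 background regions required")
        if (self.background & self.cytoplasm).any() or \
           (self.background & self.vacuole).any() or \
           (self.cytoplasm & self.vacuole).any():
            raise ValueError("stratum masks must be pairwise disjoint")


@dataclass(frozen=True)
class CRFResult:
    """Corrected relative fluorescence statistics for one cell image."""

    I_B: float        # mean background intensity per pixel
    A_C: int          # cytoplasm area, pixels
    I_C_total: float  # summed cytoplasm intensity
    CRF_C: float      # I_C_total - A_C * I_B (may be negative)
    CRF_norm: float   # CRF_C / A_C
    I_V_mean: float   # mean vacuole intensity (nan if no vacuole pixels)
    A_V: int          # vacuole area, pixels


def _validate_image(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("image must be a non-empty 2-D array")
    if not np.all(np.isfinite(img)) or (img < 0).any():
        raise ValueError("image intensities must be finite and >= 0")
    return img


def corner_regions(height: int, width: int,
                   frac: float = 1 / 16) -> tuple[Rect, Rect, Rect, Rect]:
    """Four square ROIs in the image corners, side = ``frac`` x image width."""
    side = max(2, int(round(width * frac)))
    side = min(side, height, width)
    return (
        (0, 0, side, side),
        (0, width - side, side, side),
        (height - side, 0, side, side),
        (height - side, width - side, side, side),
    )


def segment(
    img: np.ndarray,
    thresholds: tuple[float, float] | None = None,
    background_regions: tuple[Rect, Rect, Rect, Rect] | None = None,
) -> SegmentationResult:
    """Split an image into background / cytoplasm / vacuole strata.

    A pixel with intensity I goes to background if ``I <= t_low``, to
    cytoplasm if ``t_low < I <= t_high``, and to vacuole if ``I > t_high``.
    When ``thresholds`` is omitted they are chosen by 3-class Otsu
    (between-class variance maximisation). Fails if the cytoplasm stratum
    comes out empty — there is then nothing to quantify.
    """
    img = _validate_image(img)
    if thresholds is None:
        from skimage.filters import threshold_multiotsu

        if np.ptp(img) == 0:
            raise ValueError("uniform image: no separable intensity strata")
        try:
            t_low, t_high = threshold_multiotsu(img, classes=3)
        except ValueError as err:
            raise ValueError(f"automatic thresholding failed: {err}") from err
    else:
        t_low, t_high = thresholds
        if t_low >= t_high:
            raise ValueError("thresholds must satisfy t_low < t_high")

    background = img <= t_low
    cytoplasm = (img > t_low) & (img <= t_high)
    vacuole = img > t_high
    if not cytoplasm.any():
        raise ValueError(
            f"empty cytoplasm stratum with thresholds ({t_low}, {t_high})"
        )
    regions = background_regions or corner_regions(*img.shape)
    return SegmentationResult(background, cytoplasm, vacuole,
                              (float(t_low), float(t_high)), tuple(regions))


def background_mean(img: np.ndarray, regions: tuple[Rect, ...]) -> float:
    """I_B: equal-weight mean of the per-region mean intensities."""
    img = _validate_image(img)
    h, w = img.shape
    means = []
    for r0, c0, rh, rw in regions:
        if rh <= 0 or rw <= 0 or r0 < 0 or c0 < 0 or r0 + rh > h or c0 + rw > w:
            raise ValueError(f"ROI {(r0, c0, rh, rw)} outside {h}x{w} image")
        means.append(float(img[r0 : r0 + rh, c0 : c0 + rw].mean()))
    return float(np.mean(means))


def crf(img: np.ndarray, seg: SegmentationResult) -> CRFResult:
    """Corrected relative fluorescence of the cytoplasm stratum.

    Vacuole pixels are excluded from the integral. CRF_C may be negative
    (cytoplasm dimmer than background); it is reported as computed.
    """
    img = _validate_image(img)
    a_c = int(seg.cytoplasm.sum())
    if a_c == 0:
        raise ValueError("cytoplasm mask is empty")
    i_b = background_mean(img, seg.background_regions)
    i_c_total = float(img[seg.cytoplasm].sum())
    crf_c = i_c_total - a_c * i_b
    a_v = int(seg.vacuole.sum())
    i_v = float(img[seg.vacuole].mean()) if a_v else float("nan")
    return CRFResult(i_b, a_c, i_c_total, crf_c, crf_c / a_c, i_v, a_v)


def summarize_cells(results: dict[str, list[CRFResult]]):
    """Per-group mean and sample sd of CRF_norm.

    ``results`` maps group label -> list of per-cell CRF results. Groups
    with a single cell get sd = NaN (undefined). Returns a DataFrame with
    columns group, n, mean_crf_norm, sd_crf_norm — ready for ANOVA.
    """
    import pandas as pd

    rows = []
    for group, cells in results.items():
        if not cells:
            raise ValueError(f"group {group!r} is empty")
        vals = np.array([c.CRF_norm for c in cells], dtype=float)
        rows.append(
            {
                "group": group,
                "n": vals.size,
                "mean_crf_norm": float(vals.mean()),
                "sd_crf_norm": float(vals.std(ddof=1)) if vals.size > 1 else float("nan"),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale TIFF/PNG/PGM micrograph as a float array."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:  # collapse an accidental RGB read of a gray image
        arr = arr.mean(axis=2)
    return _validate_image(arr)


def read_roi_file(path: str | Path) -> tuple[Rect, ...]:
    """JSON list of [row0, col0, height, width] rectangles."""
    import json

    data = json.loads(Path(path).read_text())
    return tuple(tuple(int(v) for v in rect) for rect in data)
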