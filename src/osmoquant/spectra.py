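"""1-D NMR spectrum container and plain-text spectrum I/O.

A spectrum is a chemical-shift axis (ppm, stored descending by NMR
convention) with one intensity per point. Two on-disk dialects are
supported: two-column whitespace text ``ppm intensity`` and a minimal
JCAMP-DX subset (``##XYDATA=(XY..XY)`` with AFFN numbers), which is
enough to round-trip spectra produced by this package and to ingest
simple exports from processing software.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass(frozen=True)
class Spectrum1D:
    """A 1-D spectrum: chemical-shift axis plus intensities.

    Parameters
    ----------
    ppm : ndarray
        Chemical-shift axis in parts per million, strictly monotonic.
        Stored descending (left edge of a plotted spectrum = highest ppm).
    intensity : ndarray
        Intensity in arbitrary units, same length as ``ppm``, all finite.
    spectrometer_freq : float
        Proton Larmor frequency in MHz; converts Hz quantities (couplings,
        linewidths) to ppm: ``delta_ppm = delta_Hz / spectrometer_freq``.
    """

    ppm: np.ndarray
    intensity: np.ndarray
    spectrometer_freq: float = 400.0

    def __post_init__(self) -> None:
        ppm = np.asarray(self.ppm, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        if ppm.ndim != 1 or intensity.ndim != 1:
            raise ValueError("ppm and intensity must be 1-D arrays")
        if ppm.size != intensity.size:
            raise ValueError(
                f"axis length {ppm.size} != intensity length {intensity.size}"
            )
        if ppm.size < 2:
            raise ValueError("spectrum needs at least 2 points")
        d = np.diff(ppm)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("ppm axis must be strictly monotonic")
        if not np.all(np.isfinite(intensity)):
            raise ValueError("intensities must be finite")
        if self.spectrometer_freq <= 0:
            raise ValueError("spectrometer_freq must be positive (MHz)")
        if d[0] > 0:  # normalise to descending axis
            ppm = ppm[::-1].copy()
            intensity = intensity[::-1].copy()
        object.__setattr__(self, "ppm", ppm)
        object.__setattr__(self, "intensity", intensity)

    def __len__(self) -> int:
        return self.ppm.size

    @property
    def ppm_min(self) -> float:
        return float(self.ppm[-1])

    @property
    def ppm_max(self) -> float:
        return float(self.ppm[0])

    def scaled(self, k: float) -> "Spectrum1D":
        """Return a copy with intensities multiplied by ``k``."""
        return Spectrum1D(self.ppm, self.intensity * k, self.spectrometer_freq)


# ---------------------------------------------------------------------------
# two-column text
# ---------------------------------------------------------------------------

def write_two_column(spec: Spectrum1D, path: str | Path) -> None:
    """Write ``ppm intensity`` whitespace text, one point per line."""
    arr = np.column_stack([spec.ppm, spec.intensity])
    header = f"spectrometer_freq_MHz {spec.spectrometer_freq}"
    np.savetxt(path, arr, fmt="%.8g", header=header)


def read_two_column(path: str | Path, spectrometer_freq: float | None = None) -> Spectrum1D:
    """Read two-column whitespace text (``#`` comments allowed).

    The spectrometer frequency is taken from a header comment written by
    :func:`write_two_column` when present, else from the argument, else 400.
    """
    path = Path(path)
    freq = spectrometer_freq
    if freq is None:
        with open(path) as fh:
            for line in fh:
                if line.lstrip().startswith("#") and "spectrometer_freq_MHz" in line:
                    freq = float(line.split()[-1])
                    break
                if not line.lstrip().startswith("#"):
                    break
    arr = np.loadtxt(path)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (ppm, intensity)")
    return Spectrum1D(arr[:, 0], arr[:, 1], freq or 400.0)


# ---------------------------------------------------------------------------
# minimal JCAMP-DX (XYDATA, AFFN, (XY..XY) pairs)
# ---------------------------------------------------------------------------

def write_jcamp(spec: Spectrum1D, path: str | Path, title: str = "osmoquant spectrum") -> None:
    """Write a minimal JCAMP-DX file with explicit (XY..XY) AFFN pairs."""
    lines = [
        f"##TITLE={title}",
        "##JCAMP-DX=4.24",
        "##DATA TYPE=NMR SPECTRUM",
        "##XUNITS=PPM",
        "##YUNITS=ARBITRARY UNITS",
        f"##.OBSERVE FREQUENCY={spec.spectrometer_freq}",
        f"##FIRSTX={spec.ppm[0]:.8g}",
        f"##LASTX={spec.ppm[-1]:.8g}",
        f"##NPOINTS={len(spec)}",
        "##XYDATA=(XY..XY)",
    ]
    for x, y in zip(spec.ppm, spec.intensity):
        lines.append(f"{x:.8g}, {y:.8g}")
    lines.append("##END=")
    Path(path).write_text("\n".join(lines) + "\n")


def read_jcamp(path: str | Path) -> Spectrum1D:
    """Read the JCAMP-DX subset written by :func:`write_jcamp`.

    Accepts ``##XYDATA=(XY..XY)`` blocks with AFFN numbers separated by
    commas and/or whitespace. Raises ``ValueError`` on anything else.
    """
    freq = 400.0
    xs: list[float] = []
    ys: list[float] = []
    in_data = False
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = key.strip().upper()
            if key == ".OBSERVE FREQUENCY":
                try:
                    freq = float(value.strip().split()[0])
                except ValueError:
                    pass
            elif key == "XYDATA":
                if "XY..XY" not in value:
                    raise ValueError(
                        f"unsupported XYDATA form {value!r}; only (XY..XY) is handled"
                    )
                in_data = True
            elif key == "END":
                in_data = False
            continue
        if in_data:
            parts = line.replace(",", " ").split()
            if len(parts) % 2 != 0:
                raise ValueError(f"odd number of values in XYDATA line: {raw!r}")
            vals = [float(p) for p in parts]
            xs.extend(vals[0::2])
            ys.extend(vals[1::2])
    if not xs:
        raise ValueError(f"{path}: no XYDATA found")
    return Spectrum1D(np.asarray(xs), np.asarray(ys), freq)
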