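"""Reference peak tables for compatible solutes and the internal standard.

Quantitative 1H-NMR identifies a solute by matching all of its reference
resonances and quantifies it from a single designated quantification peak,
scaled to the internal standard (TMSP) by proton count. The shipped
library covers the osmolytes relevant to halophile osmoadaptation work —
glycine betaine (GB), ectoine (Ect), choline (Ch) — plus TMSP.

Ectoine's methyl resonance is reported at 2.25 ppm in some sources and
2.44 ppm in others; both entries are shipped, with 2.25 ppm as the default
quantification peak (select the alternative via ``ectoine_quant_shift``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

MULTIPLICITIES = {"singlet": 1, "doublet": 2, "triplet": 3, "quartet": 4}


@dataclass(frozen=True)
class SolutePeak:
    """One reference resonance of a solute.

    shift : chemical shift in ppm (-1..12 on the usual 1H axis)
    multiplicity : first-order pattern name ("singlet", "doublet", ...)
    n_protons : number of equivalent protons producing the resonance
    is_quantification_peak : whether quantification integrates this peak
    label : moiety annotation, e.g. "-N+(CH3)3"
    j_hz : scalar coupling for multiplets (ignored for singlets)
    """

    shift: float
    multiplicity: str = "singlet"
    n_protons: int = 1
    is_quantification_peak: bool = False
    label: str = ""
    j_hz: float = 7.0

    def __post_init__(self) -> None:
        if self.n_protons < 1:
            raise ValueError("n_protons must be >= 1")
        if not -1.0 <= self.shift <= 12.0:
            raise ValueError(f"shift {self.shift} ppm outside the 1H axis (-1..12)")
        if self.multiplicity not in MULTIPLICITIES:
            raise ValueError(
                f"unknown multiplicity {self.multiplicity!r}; "
                f"one of {sorted(MULTIPLICITIES)}"
            )


@dataclass(frozen=True)
class SoluteReference:
    """A named solute with its reference peak table."""

    name: str
    peaks: tuple[SolutePeak, ...]

    def __post_init__(self) -> None:
        peaks = tuple(self.peaks)
        object.__setattr__(self, "peaks", peaks)
        n_quant = sum(p.is_quantification_peak for p in peaks)
        if n_quant != 1:
            raise ValueError(
                f"{self.name}: exactly one quantification peak required, got {n_quant}"
            )

    @property
    def quantification_peak(self) -> SolutePeak:
        return next(p for p in self.peaks if p.is_quantification_peak)


@dataclass(frozen=True)
class InternalStandardSpec:
    """The internal quantification standard (default: TMSP at 0.0 ppm).

    ``concentration`` is the molar concentration in the NMR tube (mol/l).
    """

    name: str = "TMSP"
    shift: float = 0.0
    n_protons: int = 9
    concentration: float = 0.5

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValueError("standard concentration must be > 0")
        if self.n_protons < 1:
            raise ValueError("n_protons must be >= 1")

    def as_reference(self) -> SoluteReference:
        return SoluteReference(
            self.name,
            (
                SolutePeak(
                    self.shift,
                    "singlet",
                    self.n_protons,
                    is_quantification_peak=True,
                    label="Si(CH3)3",
                ),
            ),
        )


def default_library(ectoine_quant_shift: float = 2.25) -> dict[str, SoluteReference]:
    """The shipped solute library keyed by name.

    Parameters
    ----------
    ectoine_quant_shift : 2.25 (default) or 2.44 — which reported value of
        the ectoine methyl resonance carries the quantification flag.
    """
    if ectoine_quant_shift not in (2.25, 2.44):
        raise ValueError("ectoine_quant_shift must be 2.25 or 2.44")
    gb = SoluteReference(
        "GB",
        (
            SolutePeak(3.91, "singlet", 2, label="-CH2"),
            SolutePeak(3.27, "singlet", 9, is_quantification_peak=True,
                       label="-N+(CH3)3"),
        ),
    )
    ect = SoluteReference(
        "Ect",
        (
            SolutePeak(4.01, "singlet", 1, label="-CH"),
            SolutePeak(3.44, "singlet", 1, label="-CH2-ND"),
            SolutePeak(3.29, "singlet", 1, label="-CH2-ND"),
            SolutePeak(ectoine_quant_shift, "singlet", 3,
                       is_quantification_peak=True, label="-CH3"),
            SolutePeak(2.12, "singlet", 2, label="-CH2-CH"),
        ),
    )
    ch = SoluteReference(
        "Ch",
        (
            SolutePeak(4.05, "singlet", 2, label="-CH2-OH"),
            SolutePeak(3.50, "singlet", 2, label="-CH2-N"),
            SolutePeak(3.19, "singlet", 9, is_quantification_peak=True,
                       label="-N+(CH3)3"),
        ),
    )
    tmsp = InternalStandardSpec().as_reference()
    return {s.name: s for s in (gb, ect, ch, tmsp)}


# ---------------------------------------------------------------------------
# YAML serialisation
# ---------------------------------------------------------------------------

def library_to_yaml(library: dict[str, SoluteReference], path: str | Path) -> None:
    doc = {
        name: [
            {
                "shift": p.shift,
                "multiplicity": p.multiplicity,
                "n_protons": p.n_protons,
                "is_quantification_peak": p.is_quantification_peak,
                "label": p.label,
                "j_hz": p.j_hz,
            }
            for p in ref.peaks
        ]
        for name, ref in library.items()
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def library_from_yaml(path: str | Path) -> dict[str, SoluteReference]:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: expected a mapping solute -> peak list")
    out: dict[str, SoluteReference] = {}
    for name, peaks in doc.items():
        out[name] = SoluteReference(
            name, tuple(SolutePeak(**{k: v for k, v in p.items()}) for p in peaks)
        )
    return out
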