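# osmoquant

Quantification toolkit for studying **osmoadaptation in halophilic
microorganisms** — built around the three measurement procedures such
studies combine: quantitative ¹H-NMR of compatible solutes, corrected
relative fluorescence (CRF) ion imaging, and salt/osmolyte-dependent
Michaelis–Menten enzyme characterisation. It is aimed at microbial
physiologists who need these quantifications to be reproducible, testable,
and runnable end-to-end on synthetic data with known ground truth.

## What it computes

**Internal-standard qNMR.** Compatible solutes (glycine betaine GB,
ectoine Ect, choline Ch) are identified by matching all of their reference
resonances and quantified from a designated peak against the TMSP internal
standard:

```
c_s = (A_s / A_std) · (n_H,std / n_H,s) · c_std
```

Tube concentrations are scaled to intracellular molarity with the sampled
cell count and a geometric cell volume, `V = π(w/2)²L + 2·(π(w/2)²L/3)`
(cylinder plus two cones, reported in picolitres). ¹³C₂-labelled GB is
resolved from the unlabelled pool via its one-bond ¹J(¹³C–H) satellite
doublets.

**CRF ion imaging.** Micrographs are segmented into background, cytoplasm
and vacuole strata (3-class Otsu or explicit thresholds); the cytoplasm
signal is background-corrected as `CRF_C = I_C,total − A_C·I_B` and
normalised per pixel, `CRF_norm = CRF_C / A_C`.

**Enzyme kinetics.** Rate series are fitted to `v = V_max·S/(K_m+S)` by
nonlinear least squares, with the derived comparison metrics: specificity
constant `V_max/K_m`, residual activity (percent of reference `V_max`) and
osmolyte performance (percent of reference `V_max/K_m`).

**Statistics.** Welch's t test (from raw samples or summary tables),
Pearson/OLS regression with R² and slope p, one-way ANOVA with Tukey HSD,
and fold changes.

A first-class synthetic-data module generates spectra (Lorentzian lines,
multiplets, ¹³C satellites, additive noise), three-stratum micrographs,
noisy Michaelis–Menten rate series and growth counts — all seeded and with
exact ground truth — so every pipeline stage is testable offline.

## Worked example

```python
from osmoquant import InternalStandardSpec, default_library, quantify_intracellular
from osmoquant.synthetic_data import SpectrumSimConfig, simulate_spectrum

library = default_library()
standard = InternalStandardSpec(concentration=0.05)   # 50 mM TMSP
spec = simulate_spectrum({"GB": 0.05, "Ect": 0.02}, standard.concentration,
                         library, SpectrumSimConfig(noise_sd=0.0), standard)
result = quantify_intracellular(spec, n_cells=1e5, sample_volume_l=600e-6,
                                cell_volume_pl=8.01, library=library,
                                standard=standard, window=0.008)
for name in ("GB", "Ect"):
    print(name, round(result.tube_molarity[name], 4),
          round(result.intracellular_molarity[name], 3))
```

prints

```
GB 0.05 37.425
Ect 0.02 14.981
```

i.e. the 50 mM GB / 20 mM Ect put into the simulated tube are recovered to
within 0.2%, and — had that tube content come from 10⁵ cells of 8.01 pl in
600 µl — would correspond to ~37.4 and ~15.0 mol/l intracellular (the
intracellular scaling is `c_tube · V_sample / (n_cells · V_cell)`).

The same operations are available from the shell:

```sh
osmoquant simulate spectrum --solute GB=0.05 --standard-conc 0.05 --out mix.txt
osmoquant quantify-nmr --spectrum mix.txt --standard-mm 50 --cells 1e5 --out quant.csv
osmoquant cell-volume --width-um 10 --length-um 50
osmoquant fit-kinetics --rates rates.csv --out fits.csv
osmoquant run --config run.yaml
```

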