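# inta — interferometric nanoparticle tracking analysis

Blood plasma contains far more lipoproteins than extracellular vesicles
(EVs), and the two overlap in size, so sizing alone (conventional
nanoparticle tracking analysis) cannot tell them apart. Interferometric
NTA (iNTA) measures, for every tracked particle, both its hydrodynamic
diameter *and* its scattering cross-section, from which an *effective
refractive index* follows — and EVs (lipid bilayer + lumen, n ≈ 1.37) sit
well below large lipoproteins (lipid-rich core, n ≈ 1.45–1.57) on the
size–RI plane.

`inta` is a Python toolkit for this analysis, aimed at EV researchers and
single-particle-tracking method developers. It covers the full chain:

* **Forward optics** (`inta.mie`): Lorenz–Mie scattering cross-section of
  a homogeneous nanosphere, and its inversion σ → n at known diameter.
* **Synthetic measurements** (`inta.simulate`): ground-truth-labelled 3D
  Brownian trajectories at 5 kHz inside a bounded observation volume with
  noisy per-frame iSCAT contrasts `C = A√σ + ε`; presets for EV, ULDL
  (chylomicron) and VLDL populations (median (IQR) sizes 97 (79–120),
  57 (48–71), 46 (41–52) nm; RIs 1.37, 1.52, 1.49).
* **Image stage** (`inta.frames`, optional): render interferometric
  movies, then recover localizations via rolling-median background
  correction, a radial variance transform, and nearest-neighbour linking.
* **Per-particle estimation** (`inta.estimate`): covariance-based (CVE)
  diffusion estimate → Stokes–Einstein diameter; median contrast →
  cross-section → effective RI; and `IQR_S`, a per-particle Monte-Carlo
  measure of how much RI spread contrast noise alone would cause —
  particles with `IQR_S < 0.05` pass the precision gate.
* **Discrimination** (`inta.classify`): a random forest over
  (diameter, log σ, RI) returning P(EV), with an 80% confidence threshold
  (EV / LP / unclassified) and mixture quantification
  `C_EV/(C_EV + C_LP)`.
* **Quantification** (`inta.quantify`): trajectory counts → particles/mL
  via a bead-series calibration, dilution factors, and back-calculation
  of the original plasma EV concentration from enrichment recovery rates
  (SEC 80%, DMC 33%, DG 25%) and volume factors.

The model assumptions, defaults and known limitations are documented in
[`docs/methods.md`](docs/methods.md).

## Worked example

Simulate a pure EV sample, estimate per-particle quantities, and
summarize the population:

```python
import numpy as np
from inta import (
    OpticalConfig, InstrumentSpec, ContrastCalibration,
    POPULATION_PRESETS, simulate_sample,
)
from inta.estimate import build_records, population_summary

optics, instr, calib = OpticalConfig(), InstrumentSpec(), ContrastCalibration()
trajset = simulate_sample([POPULATION_PRESETS["EV"]], instr, optics, calib,
                          seed=111, n_expected=2400)
records = build_records(trajset, seed=112)
summary = population_summary(records, optics, instr)
print(f"{summary['n_records']} records, "
      f"median diameter {summary['median_diameter_nm']:.1f} nm, "
      f"median RI {summary['median_ri']:.3f} "
      f"(gate passed by {summary['gate_fraction']:.0%})")
```

```
1252 records, median diameter 95.9 nm, median RI 1.369 (gate passed by 100%)
```

The summary recovers the generator's population (median 97 nm, RI 1.37)
because `population_summary` reweights records by the inverse survival
probability of the >100-localization filter and corrects the 1/D
convexity of the size estimate; the plain median of the kept records sits
several percent high (see `docs/methods.md`).

Back-calculate a plasma EV concentration from an enriched-sample
measurement:

```python
from inta.quantify import RECOVERY_PRESETS, back_calculate_plasma_concentration, round_sig
c = back_calculate_plasma_concentration(9.8e10, RECOVERY_PRESETS["DMC"])
print(f"{round_sig(c, 2):.1e}")   # 5.9e+10 particles/mL
```

A measured 9.8×10¹⁰ /mL after dual-mode chromatography (33% recovery,
0.5 mL plasma concentrated to 0.1 mL) implies 5.9×10¹⁰ /mL in the
original plasma.

The same workflows are available from the shell:

```bash
inta simulate --population EV --n-expected 500 --seed 1 --out traj.csv
inta analyze  --input traj.csv --seed 1 --out records.csv
inta train    --ev-records ev.csv --lp-records lp.csv --out model.joblib
inta classify --records records.csv --model model.joblib --plot size_ri.png --out labelled.csv
inta quantify --records labelled.csv --factor 1e8 --recovery-preset DMC --out report.json
```

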