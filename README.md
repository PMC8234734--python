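# noncanon-pk

Pharmacokinetic analysis of **non-canonical bolus concentration–time
curves** — i.v. bolus blood curves that *rise* to a maximum (~4 min) before
decaying bi-exponentially, and i.p. tissue curves with bimodal peaks near 4
and 10–15 min.  Curves of this shape arise for the tetrapeptide
Ac-His-Ala-Glu-Glu-NH₂ (HAEE), a blood–brain-barrier-crossing anti-amyloid
candidate, where rapid binding to the vascular endothelium and plasma
proteins hides part of the dose from early blood draws.

The package is organised as an analysis project: a library under
`src/noncanon_pk/`, numbered drivers under `analysis/`, and a fully
synthetic data path so the whole pipeline runs and is tested without animal
data.

## What it computes

The canonical decay segment (t ≥ Tmax) follows the two-compartment
macro-constant form

    C(t) = A·e^(−α·t) + B·e^(−β·t),   α > β > 0,

fitted by curve stripping + weighted nonlinear least squares, with mono- vs
bi-exponential selection by AICc.  Because the pre-peak segment is not
described by this model, exposure is *hybrid*:

    AUC(0–∞) = trapezoid(first sample → Tmax)  +  (A/α)e^(−α·Tmax) + (B/β)e^(−β·Tmax)

From dose D, the fit and the hybrid moments come the standard parameters
ClT = D/AUC, Kel = β, T1/2 = ln2/β, MRT (1/β and AUMC/AUC), Vd(c) = D/(A+B),
Vd(β) = ClT/β, Vd(extrap) = D/B — plus dose-linearity Pearson analysis,
chronic-vs-single-dose equivalence ratios, tissue bioavailability
f_T = AUC(0–20)_tissue / AUC(0–20)_blood, and peak (mode) detection for the
bimodal tissue curves.

A mechanistic simulator (`noncanon_pk.simulate`) embodies the three-pool
binding picture — free / endothelium-bound / protein-bound drug plus
peripheral and per-tissue fast/deep pools — and reproduces the signature
curve shapes; it is the data source for all end-to-end tests.  See
`docs/methods.md` for the model, its assumptions and its limits.

## Worked example

```python
import numpy as np
from noncanon_pk.compartmental import Model, fit_decay, hybrid_auc_inf, hybrid_aumc_inf
from noncanon_pk.io import DoseRecord, Route
from noncanon_pk.nca import cmax_tmax
from noncanon_pk.pkparams import derive_parameters
from noncanon_pk.simulate import add_noise, default_iv_config, simulate_iv

profile, _ = simulate_iv(default_iv_config(dose=105_000))   # 300 µg/kg rat-scale
profile = add_noise(profile, cv=0.10, n_animals=6, seed=1)
cmax, tmax = cmax_tmax(profile)
fit = fit_decay(profile, Model.BI, t_start=tmax)
pk = derive_parameters(
    DoseRecord(Route.IV_BOLUS, 300, 0.35, group_id="rat300"),
    fit.macro,
    auc0_inf=hybrid_auc_inf(profile, fit),
    aumc0_inf=hybrid_aumc_inf(profile, fit),
    cmax=cmax, tmax=tmax,
)
print(f"Tmax {pk.Tmax:.0f} min, Cmax {pk.Cmax:.0f} ng/mL")
print(f"beta {pk.Kel:.4f} /min  ->  T1/2 {pk.T12_el:.1f} min")
print(f"AUC(0-inf) {pk.AUC0_inf:.0f} (ng/mL)·min,  ClT {pk.ClT:.1f} mL/min")
```

prints

```
Tmax 4 min, Cmax 253 ng/mL
beta 0.0280 /min  ->  T1/2 24.7 min
AUC(0-inf) 7168 (ng/mL)·min,  ClT 14.6 mL/min
```

i.e. the simulated rat-scale bolus peaks at 4 minutes, is eliminated with a
~23-minute half-life, and its clearance follows from dose over hybrid
exposure.  (The clearance differs from the published rat value because the
simulator's central volume and elimination rate are calibrated to curve
*shape*, not to a particular animal's absolute exposure.)

The numbered drivers run the full pipeline and write tables under
`results/`:

```sh
python analysis/01_desk_checks.py        # re-derivations from the published tables
python analysis/02_simulate_study.py     # synthetic 3-dose + chronic i.v. study
python analysis/03_fit_decay.py          # mono/bi fits, model choice, hybrid AUC
python analysis/04_derive_parameters.py  # full parameter table
python analysis/05_dose_linearity.py     # Pearson linearity + chronic comparison
python analysis/06_biodistribution.py    # i.p. tissue f_T table + modes
```

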