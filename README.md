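# deerflex

Analysis of protein conformational flexibility from pulsed dipolar ESR
(DEER/PELDOR) distance distributions, built around the BCL-2 regulatory
problem: how phosphorylation-mimicking mutations in a flexible loop rigidify
the protein and change its ligand binding.  The package simulates and
inverts four-pulse DEER time traces, quantifies flexibility by the width of
the recovered inter-spin distance distribution P(r), cross-checks distances
against coordinate-based in-silico spin labeling, and computes the
companion biochemical readouts (FRET efficiency, cytochrome-c release,
FRAP pore activity on model membranes).

## The model

Two nitroxide spin labels at distance *r* couple at the powder-averaged
dipolar frequency ω<sub>dd</sub>(r) = 2π·D/r³ with D = 52.04 MHz·nm³.  A
distance distribution P(r) produces the time-domain form factor

    F(t) = ∫ P(r) ∫₀¹ cos[(1 − 3u²) ω_dd(r) t] du dr ,

and the measured echo is V(t) = [(1 − λ) + λ·F(t)]·B(t) with modulation
depth λ and a stretched-exponential intermolecular background
B(t) = exp(−k·t^(d/3)).  Recovering P(r) from V(t) is a classic ill-posed
inverse problem; the package solves it by

1. background fitting on the trace tail, with one round of
   form-factor-aware refinement of (λ, k) on the full trace;
2. non-negative Tikhonov regularization (active-set NNLS on the stacked
   system, second-difference penalty), with the regularization weight α
   chosen at the maximum-curvature corner of the L-curve;
3. maximum-entropy refinement toward a reduced chi-square of ≈1, using the
   Tikhonov solution as the prior.

Flexibility is reported as the full width at half maximum of P(r), defined
between the outermost half-maximum crossings so that broad multimodal
ensembles report the full extent of the conformational spread.

## Worked example

```python
import numpy as np
from deerflex import (InversionConfig, invert, make_scenario,
                      simulate_trace_from_scenario, mode_distance, fwhm)

narrow = make_scenario("EEE-like", seed=2)      # rigidified: one narrow component
broad = make_scenario("WT-like", seed=2)        # flexible: broad shouldered hump
cfg = InversionConfig(dr=0.05)
for sc in (broad, narrow):
    trace, truth = simulate_trace_from_scenario(sc, seed=40)
    res = invert(trace, cfg)
    print(f"{sc.label}: lambda={res.background.lam:.2f} "
          f"mode={mode_distance(res.p_mem):.2f} nm "
          f"fwhm={fwhm(res.p_mem):.2f} nm (truth {fwhm(truth):.2f} nm)")
```

prints

```
WT-like seed=2: lambda=0.24 mode=4.10 nm fwhm=1.72 nm (truth 1.63 nm)
EEE-like seed=2: lambda=0.22 mode=3.30 nm fwhm=0.41 nm (truth 0.42 nm)
```

The broad (flexible, wild-type-like) ensemble and the narrow
(rigidified, phosphomimetic-like) ensemble are simulated at the same
signal-to-noise ratio; the inversion recovers the most probable distance
of both and preserves the width ordering — the quantity the structural
argument rests on.

The same pipeline is available from the shell:

```bash
deerflex simulate trace --kind EEE-like --seed 4 --out eee.dat
deerflex invert --trace eee.dat --dr 0.05 --out eee
deerflex stats --dist eee_mem.csv --out report.csv
deerflex label --pdb structure.pdb --site A:12 --site A:92 --seed 7 --out pred.csv
deerflex assay frap --curve recovery.csv --radius-um 10 --dextran 70k
```

`invert` writes the Tikhonov and maximum-entropy distributions, the full
regularization path, and a report with the chosen α, λ, k and χ²/N.

## Scope notes

Bruker instrument binaries (DTA/DSC) are not read; convert to two-column
text first.  Orientation selection, multi-spin effects and exchange
coupling are not modeled.  The in-silico labeler is a simplified
accessible-volume surrogate (uniform shell sampling with clash rejection),
not a rotamer-library method; see `docs/methods.md` for what that implies.
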