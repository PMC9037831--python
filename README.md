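# flexsaxs

Solution small-angle X-ray scattering (SAXS) analysis and restrained
modelling for flexible multi-domain proteins — built around the antibody
problem: an IgG is three rigid domains (two antigen-binding Fab arms and
one Fc stem) on flexible hinges, too mobile to crystallize or class-average
in cryo-EM, yet fully characterizable in solution by combining SAXS
invariants with computational modelling.

The package covers that combined workflow end to end:

* **Reduction** — frame averaging with correlation-based outlier rejection,
  buffer subtraction, concentration-series merging with fitted scales.
* **Invariants** — Guinier fit (self-consistent q·Rg ≤ 1.3 window),
  normalized Kratky curves, and a regularized indirect Fourier transform to
  the pair distance distribution: P(r) = r·Σₙ aₙ sin(nπr/Dmax) with an
  L1 second-derivative smoothness penalty and a constant-background option,
  plus Dmax scanning and P(r) peak analysis.
* **Forward scattering** — the Debye equation
  I(q) = Σᵢⱼ fᵢfⱼ sin(qrᵢⱼ)/(qrᵢⱼ), histogram-accelerated to < 1e−6 of the
  exact double sum, and closed-form χ² fitting.
* **Envelopes** — ab initio bead-model reconstruction by simulated
  annealing on an HCP lattice, normalized-spatial-discrepancy (NSD)
  clustering and averaging, voxelization, CCP4/MRC I/O.
* **Flexible fitting** — the density-restraint potential
  V(r) = k·[1 − ρ(r)/ρmax] on Cα-level beads with analytic trilinear
  forces, elastic-network (or exactly rigid-domain) overdamped dynamics,
  and best-model selection by reciprocal-space χ² along the trajectory.
* **Ensembles** — genetic-algorithm sub-ensemble selection against a
  profile and entropy-based flexibility metrics
  (Rflex = 100·H(p)/log₂ n_bins of the size distribution;
  Rsigma = sd(selected)/sd(pool)).
* **Geometry & statistics** — inter-domain distances/angles, inertia
  planes, Shrake–Rupley SASA, the Fab elbow angle (angle between the
  pseudo-two-fold axes of the variable and constant modules), Kabsch RMSD,
  and PCA / hierarchical clustering over profile and feature matrices.
* **Synthetic data** — an antibody surrogate (three ellipsoidal bead
  domains on two hinges, Rg ≈ 58 Å, Dmax ≈ 168 Å) with conformational
  pools, realistic q-dependent noise, and temperature / concentration
  series with known ground truth, so the whole pipeline is testable
  offline.

## Worked example

```python
import numpy as np
from flexsaxs.synthetic_data import NoiseSpec, build_antibody_surrogate, simulate_profile
from flexsaxs.profile_analysis import guinier_fit, ift_pr, pr_peaks

model, domains = build_antibody_surrogate()          # ~320-bead IgG surrogate
q = np.linspace(0.002, 0.25, 180)                    # 1/Angstrom
profile = simulate_profile(model, q, NoiseSpec(seed=1))

g = guinier_fit(profile)
pr = ift_pr(profile, Dmax=model.dmax())
peaks = pr_peaks(pr, min_prominence=0.03)

print(f"ground truth   Rg = {model.rg():5.1f} A   Dmax = {model.dmax():5.1f} A")
print(f"Guinier        Rg = {g.Rg:5.1f} A   (q*Rg <= {g.qmax_Rg:.2f})")
print(f"P(r)           Rg = {pr.Rg:5.1f} A   I(0) = {pr.I0:.3g}")
print(f"P(r) maxima at r = {', '.join(f'{p:.0f} A' for p in peaks)}")
```

prints

```
ground truth   Rg =  57.9 A   Dmax = 168.3 A
Guinier        Rg =  58.1 A   (q*Rg <= 1.24)
P(r)           Rg =  58.1 A   I(0) = 1.03e+05
P(r) maxima at r = 29 A, 96 A
```

Both size estimators agree with the ground-truth radius of gyration to
well under 1 %, and the two P(r) maxima are the intra-domain (~29 Å) and
inter-domain (~96 Å) distance modes of the three-domain architecture — the
bimodal fingerprint of well-separated rigid domains.

Bundled end-to-end workflows (static characterization: invariants →
envelopes → restrained fit; flexibility: pool → ensemble → Rflex/Rsigma;
condition comparison: series → trends → PCA) run from one YAML config:

```bash
flexsaxs run static --seed 1 --out-dir out/
flexsaxs invariants profile.dat --out invariants.json
flexsaxs fitenv --pdb model.pdb --map envelope.mrc --profile profile.dat
```

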