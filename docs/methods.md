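# Methods

`flexsaxs` implements the full solution-SAXS workflow for a flexible
multi-domain protein — an antibody-like particle of two Fab arms and one Fc
stem joined by flexible hinges — from raw-curve reduction to
envelope-restrained atomistic refinement and ensemble-based flexibility
quantification. This note records the models, the parameters that matter,
the numerical choices, and what the synthetic-data validation does and does
not demonstrate.

## The synthetic antibody surrogate

All end-to-end validation runs on a coarse surrogate with known ground
truth. Three rigid ellipsoidal domains are filled with uniform dummy
scatterers on a jittered cubic lattice: two Fab-like arms with semi-axes
(40, 25, 20) Å and an Fc with (33, 25, 21) Å, about 110 beads each
(~320 beads total, one bead per ~3–4 residues of a 150 kDa IgG). Arms
attach to pivots at the top of the Fc through 18 Å hinges; each hinge
carries a bend angle (interior angle at the pivot between the stem axis and
the arm; 180° = collinear) and a twist about the arm axis. The resting
conformation is asymmetric (bends 118° and 142°), giving Rg ≈ 58 Å and
Dmax ≈ 168 Å — antibody-sized. Conformers are drawn by uniform rigid arm
rotations (default ±35° bend, ±60° twist), so intra-domain distances are
preserved to machine precision; a clash filter rejects conformations in
which any two domains approach within one bead diameter.

Measurement noise follows a photon-statistics-like model
σ(q) = I(q)·(floor + growth·q)/√counts with floor 1 %, growth 0.15 Å, and
counts scale 1 — relative errors grow from ~1 % at low q to ~5 % at
q = 0.25 Å⁻¹, as on modern beamlines. Gaussian noise of that σ is added to
the Debye intensity.

Two condition series emulate comparative experiments. The temperature
series mixes the folded state with an isotropically expanded one
(coordinates scaled ×1.6 about the centre of mass) with a logistic unfolded
fraction (midpoint 75 °C, width 4 °C): apparent size is flat at low
temperature and rises through the transition. The concentration series
mixes monomer with a side-by-side dimer, I = (1−f)·I₁ + f·I₂, where the
dimer fraction is 0 below 4 mg/ml and rises linearly (slope 0.12 per mg/ml,
capped at 0.72); the dimer is a geometric stand-in for aggregation, not a
mechanistic claim. What the surrogate does **not** emulate: side-chain
chemistry, hydration-shell contrast, inter-particle structure factors
beyond the dimer mixture, glycans, or a self-avoiding unfolded chain (only
Rg-level behaviour of the expanded state is asserted). Passing tests
therefore demonstrate the correctness of the analysis machinery at SAXS
resolution, not detector-level realism.

## Reduction

Frame averaging rejects outlier frames whose Pearson correlation with the
pointwise-median frame falls below 0.995 (radiation-damage screening);
uncertainties propagate as √(Σσ²)/n. Note that a uniformly rescaled frame
is invisible to a correlation criterion by construction — only
shape-changing damage is caught. Buffer subtraction requires exactly
matching q grids; the package never resamples a measured curve, so no
hidden smoothing enters the data. Concentration-series merging fits, on
the overlapping q window, the error-weighted scale of each
higher-concentration profile to the running merged curve, and splices at
the crossover q where the smoothed scaled discrepancy is smallest (override
available); low concentration contributes the low-q side (least
inter-particle interference), high concentration the high-q side (best
statistics).

## Model-free invariants

**Guinier.** Weighted linear fit of ln I vs q² iterated to a
self-consistent window with q·Rg ≤ 1.3. Two guards keep the window honest:
leading points are trimmed (at most 5) while the first standardized
residual exceeds +3 (aggregation upturn), and the window shrinks from high
q while the fit's reduced χ² exceeds 2 — without the second guard,
systematic curvature biases the sphere Rg by ~2 % whenever statistical
errors are small. At least 10 points are always kept, so the input grid
must resolve the Guinier region (the bundled pipelines use
q from 0.002 Å⁻¹, 180 points, for this reason).

**Kratky.** The normalized curve (qRg)²·I/I₀ vs qRg. The textbook
compact-particle fingerprint — peak at √3 of height 3/e — is exact for the
Guinier curve itself; the exact homogeneous sphere peaks at qRg ≈ 1.61,
height ≈ 1.02, about 6 % away. Tests assert the identity on the curve for
which it holds.

**Indirect Fourier transform.** P(r) is expanded as
r·Σₙ aₙ sin(nπr/Dmax) — a sine expansion of P(r)/r, the form whose Debye
transform is elementary:

    I(q) = 4π Σₙ aₙ (−1)ⁿ⁺¹ sin(qD) (nπ/D) / (q((nπ/D)² − q²)).

Coefficients (plus an optional constant background) minimize
χ² + α·Σ|Δ²P|, an L1 (sparsity-of-curvature) smoothness penalty minimized
by iteratively reweighted least squares (40 iterations, weight floor 1e−8)
— deterministic, no stochastic solver. The basis size defaults to the
Shannon-channel count ⌈qmax·Dmax/π⌉ + 2; the margin removes a truncation
bias exactly at the true Dmax. α defaults to the corner (maximum curvature
point) of the log–log L-curve over α ∈ [1e−4, 1e3]. Intensities are
normalized internally so the result is equivariant under global rescaling.
P(0) = P(Dmax) = 0 hold by construction; positivity is encouraged by the
Dmax-scan score, not enforced. Derived invariants: Rg² = ∫r²P/(2∫P),
I₀ = 4π∫P.

**Dmax scan.** Each candidate Dmax is scored
exp(−χ²_red/2)·exp(−20·f_neg)·exp(−0.25·n_basis), where f_neg is the
negative fraction of |P| area and the last factor is an evidence-like
parsimony term: without it every Dmax above the true one fits equally well
and the score plateaus. Scores are rescaled to max 1. The scan is exact on
spheres (sharp P(r) cutoff); for particles whose P(r) decays smoothly into
the tail it clips 5–15 % of Dmax — the bundled pipeline therefore sets the
envelope search sphere 15 % beyond the scanned value. The suggested qmax is
the largest q where the smoothed q·I/(q·σ) signal-to-noise stays above 2.

## Forward scattering and χ²

The Debye double sum uses q-independent form factors (uniform for beads, an
atomic-number table for element mode); no excluded-volume or hydration
term, so absolute comparisons with experiment on real data would carry a
systematic contrast offset — all comparisons here are internal. Above 200
scatterers the sum is histogram-accelerated: pair distances are binned at
0.1 Å keeping per-bin weighted mean and variance, and a second-order Taylor
correction in the bin moments reproduces the direct sum to better than
1e−7. χ² fitting solves the scale (and optional offset) in closed form and
normalizes by N − n_params.

## Envelope reconstruction

Dummy-atom models live on a hexagonal close-packed lattice inside a sphere
of diameter Dmax (bead radius Dmax/24 by default; the bundled pipelines use
Dmax/16 to keep multi-model ensembles fast). Simulated annealing over
occupancy flips minimizes χ² against the IFT-smoothed intensity (40 q
channels) plus λ_c·(components − 1) + λ_p·⟨empty-neighbour fraction⟩ with
λ_c = 1e5 — effectively a hard connectivity constraint, so elongated shapes
grow necks instead of splitting — and λ_p = 2. Schedule: T₀ = 2, cooling
0.88 per sweep, 60 sweeps of one proposal per site, early stop after 12
sweeps without improvement (best-so-far returned with a flag). Intensity
updates are incremental (O(N_occ) per flip) and connectivity is recounted
by BFS only for moves that can change it. The final model is pruned to its
largest component if needed.

Reconstructions are compared by the normalized spatial discrepancy (NSD)
after rigid alignment (principal-axes initialization over the four proper
flips and the enantiomer branch, then ICP refinement), clustered by
average linkage on the pairwise aligned-NSD matrix (cut 0.7; singletons
reported as isolated), and averaged site-wise: members snap to the
reference lattice and sites with ≥ 50 % occupancy survive. Voxelization
deposits point masses on a regular grid (nearest voxel) and blurs with an
isotropic Gaussian, padded by 3σ so mass is conserved to < 1 %.

## Envelope-restrained refinement

The restraint is the density potential V(r) = k·[1 − ρ(r)/ρmax] summed over
the selected atoms (all points at the bead/Cα resolution used here;
k = 0.1 by default), with ρ trilinearly interpolated and the force
(k/ρmax)∇ρ taken from the analytic gradient of the interpolant — verified
against central finite differences to 1e−8. Positions outside the grid
clamp to ρ = 0 (zero force), which is why refinement targets use a generous
blur (8–12 Å): the Gaussian tail is what reaches a displaced domain.

Internal structure is maintained by a harmonic network over intra-domain
atom pairs within 12 Å (rest lengths = starting distances; no inter-domain
pairs, so hinge motion is free), integrated by overdamped Euler–Maruyama
(pure gradient descent at T = 0, the default — best-model selection is a
deterministic argmin anyway). A sustained energy rise aborts with a
step-size diagnostic. Because an explicit integrator over a stiff network
forces a step size far below what domain-scale motion needs, the refiner
also offers (and the pipelines use) a constrained mode: after every step
each domain is projected back onto its rigid-body manifold by a Kabsch fit
of its starting geometry — the stiff-spring limit, analogous to holonomic
constraint (SHAKE-type) dynamics. Domains then move with the net force and
torque of their atoms, intra-domain distances are exact, and step sizes of
0.3 (reduced units) are stable. The standard validation experiment — one
arm rotated 30° about its hinge, refined into the truth envelope through a
two-stage blur schedule (12 Å then 6 Å) — recovers ~94 % of the initial
Cα RMSD with envelope correlation > 0.99.

Best-model selection is the argmin of reciprocal-space χ² along the
trajectory (ties → earliest frame); envelope agreement is tracked as the
Pearson correlation between the target grid and the model voxelized onto
it with matching blur.

## Ensemble optimization and flexibility

A conformer pool (default 150–200 models for tests; arbitrary for
production) carries precomputed profiles, Rg and Dmax. A genetic algorithm
searches multisets of fixed size (default population 100, 200 generations,
tournament 5, one-point crossover, mutation 0.1, elitism 1, patience 60):
fitness is the χ² of the scale-fitted uniform mean of member profiles.
Weights are member multiplicities / ensemble size. Flexibility metrics on
the size distributions: Rflex = 100·H(p)/log₂(n_bins) (Shannon entropy of
the histogram over 20 bins spanning the pool range) for the pool and the
weighted selection, and Rsigma = sd(selected)/sd(pool). Recovery is
identifiable only for genuinely distinct states: the planted two-state
test uses the pool's extreme-Rg pair, because χ²-equivalent look-alike
conformers otherwise absorb weight.

## Geometry metrics

Mass-weighted COMs, pairwise COM distances, angles at the whole-molecule
COM, inertia-plane angles (acute angle between the normals of each domain's
two-largest-variance principal planes; mass-weighted tensors by default),
per-domain Rg, and per-domain SASA by an own Shrake–Rupley implementation
(960 golden-spiral points, probe 1.4 Å, per-domain atom sets in isolation)
— validated against the analytic sphere area to 2 %. The Fab elbow angle is
the angle between the pseudo-two-fold axes obtained from the Kabsch
rotations VL→VH and CL→CH1. Pseudo-dyads are sign-ambiguous, so both are
canonically oriented (variable dyad toward the constant module; constant
dyad into the same hemisphere), the inter-dyad angle θ ∈ [0°, 90°] is
formed, and the elbow is 180° ∓ θ with the reflex branch set by
sign((u_V×u_C)·(COM_C−COM_V)) — results lie in (90°, 270°), 180° for
parallel dyads. Superpositions with rotations under 5° raise (dyad
ill-defined).

## Comparative statistics

Profile matrices are rows of log I(q) on a common grid (non-positive rows
excluded with a log message); feature matrices are z-scored before PCA
because features mix Å, degrees and Å². PCA is a full SVD with a fixed
sign convention (largest-|loading| element of each component positive) so
score plots reproduce run to run. Hierarchical clustering is average
linkage on a supplied distance matrix. Size-vs-concentration trends are
plain Pearson correlations; a zero-variance metric is reported as
undefined rather than 0. For the synthetic comparison the non-aggregating
null is reported as the mean correlation over three noise replicates of a
nine-point series — a single five-point draw of a null correlation is
nearly uniform on [−1, 1] and meaningless.

## Problem sizes and determinism

The default validation sizes — 320-bead surrogate, 150-conformer pools,
sphere envelopes at bead radius Dmax/16 with 4–8 annealing seeds, 3 000
refinement steps in two blur stages, five GA seeds for the mixture — were
chosen so that each experiment answers its question with margin (recovery
ratios and correlations sit far from their thresholds) while the whole
suite stays desk-scale. Every stochastic component takes an explicit seed
(NumPy `default_rng`); bundled pipelines derive per-stage seeds from one
config seed, and reruns reproduce every number bitwise.

## Known limitations

No hydration-shell/excluded-volume contrast (fits to real, absolute-scale
data need an external CRYSOL-type forward model); the Dmax scan clips
smooth P(r) tails; the annealer's χ² surface is coarse at bead resolution,
so envelope detail below ~1.5 bead diameters is noise; the rigid-domain
projection forbids intra-domain relaxation by design — soft-network mode
exists but needs small steps; EOM-style binning conventions differ between
tools, so Rflex percentages are comparable within this package, not across
programs.
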