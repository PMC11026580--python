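# absaxs

Coarse-grained solution-scattering analysis of antibody flexibility.

Monomeric IgA2 carries two Fab arms tethered to a glycosylated Fc by a short
hinge. Small-angle X-ray scattering (SAXS) sees the whole conformational
ensemble at once: how far the Fabs swing away from the Fc, and how removing
N-glycans changes that mobility. `absaxs` implements the complete analysis
chain needed to ask such questions quantitatively — on synthetic data with
known ground truth, so every stage can be validated end to end:

- **Synthetic glycoprotein models** — a parameterized builder for an
  IgA2-like monomer (two Fab + Fc ellipsoidal bead clusters, flexible hinge
  `228–235`, tailpiece `449–466`, N-glycan bead chains with per-site
  occupancy and excess scattering weight), with calibrated *closed*
  (R_g ≈ 44 Å), *open* (≈ 53 Å) and *extended* (≈ 65 Å) conformers, noisy
  two-state mixture profiles, SEC-SAXS frame stacks, SPR sensorgrams and
  thermal melt curves.
- **Theoretical profiles** — the Debye formula
  `I(q) = Σᵢⱼ fᵢfⱼ sin(q·rᵢⱼ)/(q·rᵢⱼ)` with a pair-distance-histogram
  acceleration (validated against the exact double sum and the analytic
  sphere form factor).
- **Model-free reductions** — buffer subtraction and elution-peak merging,
  the Guinier fit `I(q) = I(0)·exp(−q²R_g²/3)` with an iterative
  self-consistent `q·R_g < 1.5` window, P(r) by Tikhonov-regularized
  indirect Fourier transform with non-negativity (L-curve choice of α), a
  D_max scan, and the dimensionless Kratky representation
  `(qR_g)²·I/I(0)` vs `qR_g` with a peak/shoulder feature detector.
- **Rigid-body conformational sampling** — clash-filtered randomized pivot
  moves over hinges, tailpieces and glycans; the two Fab arms move
  independently and the rigid-body internal geometry is preserved exactly.
- **Multistate ensemble fitting** — non-negative least-squares weights for
  k-state models, exhaustive/beam-search ranking over the conformer pool,
  χ²-based selection of the number of states, and state counting from the
  weighted R_g distribution of the top fits.
- **Auxiliary biophysics** — single-cycle SPR 1:1 kinetics
  (`dR/dt = k_a·C·(R_max − R) − k_d·R`, `K_D = k_d/k_a`) and melting
  temperatures from the first derivative of thermal denaturation curves.

Fits follow the model/results idiom: `GuinierModel(profile).fit()`,
`IFTModel(profile, dmax).fit()`, `MultiStateModel(profile, ensemble).fit()`
and `SPRKineticsModel(trace).fit()` each return a results object carrying
the estimates, diagnostics and a `summary()`.

## Worked example

The demo pipeline synthesizes a 45:55 closed/open mixture, simulates a
SEC-SAXS elution, reduces it, samples a conformer pool and recovers the
two-state composition:

```bash
absaxs run --outdir demo --seed 0 -n 150
```

prints (abridged):

```
== synthesize ==
closed: 1459 beads, Rg = 44.21 A
open: 1459 beads, Rg = 53.20 A
extended: 1459 beads, Rg = 65.70 A

== reduce ==
Guinier Rg = 48.56 A, I(0) = 1.581e+06, qRg_max = 1.46, R^2 = 0.9994
Dmax (scan) = 162 A
P(r) features of the closed model: peak@43.2, shoulder@67.3, shoulder@82.9
Kratky maximum at qRg = 1.84 (height 1.14)

== sample ==
153 conformers, Rg 44.2-70.9 A

== multistate fit ==
best k=1: chi2 = 3.960, weights = 1.00
best k=2: chi2 = 1.748, weights = 0.47,0.53
best k=3: chi2 = 1.740, weights = 0.46,0.48,0.06
selected number of states k = 2 (chi2 improvement > 15% rule)
estimated states from Rg distribution: 2
  state at Rg = 44.5 A, weight 0.47
  state at Rg = 53.5 A, weight 0.53
(truth: 0.45 closed at 44.2 A + 0.55 open at 53.2 A)
```

Reading the numbers: the merged elution profile shows the ensemble-average
R_g of 48.6 Å and a maximal dimension of ~160 Å; a single conformer cannot
fit the curve (χ² = 4.0), two states fit it well (χ² = 1.7) and a third adds
nothing, and the pooled R_g distribution of the best two-state models puts
one state at the compact (44 Å) and one at the opened (54 Å) arrangement
with weights matching the simulated truth.

The same stages are available piecemeal (`absaxs synth / profile / reduce
guinier|pr|kratky / sample / multifit / spr / melt`) and as library calls.

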