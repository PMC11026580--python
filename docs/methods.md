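# Methods

This note documents the models, the numerical choices and the limits of what
the synthetic-data experiments can show. Everything stated here is computed
by the test suite or the demo pipeline; nothing is quoted from external
measurements.

## Coarse-grained antibody model

One bead represents one amino-acid residue or one monosaccharide. The
monomer consists of three rigid bodies — two Fabs and one Fc — built as
uniform random fillings of ellipsoids with generous immunoglobulin-fold
dimensions (Fab semi-axes 48 × 29.5 × 24 Å, Fc 29.5 × 25 × 36 Å; per-domain
R_g ≈ 24–27.5 Å, deliberately at the plump end so the assembled particle
reproduces compact-antibody scattering features). Each heavy chain
(sequential 1-based numbering) contributes a hinge (residues 228–235)
anchored on the upper Fc surface, a C-terminal tailpiece (449–466) grown as
a worm-like chain from the lower pole, and five N-glycosylation sequons:
two on the Fab arm (NLT, and the short low-occupancy NVS at 20%), two on
the CH2 region of Fc (NVT, NSS) and one on the tailpiece (NIT). Glycans are
bead chains (default 9 sugars, 3.5 Å steps) drawn present per molecule with
the site's occupancy; each glycan bead scatters 1.3× a protein bead,
reflecting the higher electron density of carbohydrate relative to protein.
Only the ratio being ≥ 1 matters for the qualitative behaviour.

Three reference conformations place the Fab arms rigidly (internal pair
distances preserved to machine precision; the flexible hinge is re-laid
along the new anchor-to-Fab path):

| mode | arm placement | R_g (default build) |
|---|---|---|
| closed | compact Y, arms hugging Fc, slightly out of plane | 44.2 Å |
| open | arms lifted and swung outward | 53.2 Å |
| extended | arms splayed laterally, long axes radial | 65.7 Å |

The placements were calibrated once so that (i) the three conformers land
in the 43–46 / 52–54 / 63–66 Å windows typical of compact and splayed IgA
monomers, (ii) the closed model's P(r) shows its first maximum near 43 Å
with an inter-domain shoulder near 83 Å and its dimensionless Kratky curve
peaks near q·R_g ≈ 1.8, and (iii) the default 45:55 closed/open mixture
shows a Guinier R_g of ≈ 48.6 Å and a maximal dimension of ≈ 160–170 Å.
These are joint constraints: making the closed arrangement more isotropic
pushes the Kratky maximum toward the spherical limit but erases the ≥ 70 Å
inter-domain shoulder, so the chosen geometry is a deliberate compromise
(Kratky maximum 1.794, shoulder 82.9 Å). For orientation: an ideal uniform
sphere peaks at q·R_g = 1.61 and a pure Guinier bell at √3 ≈ 1.73, so a
compact multidomain particle sits a little above both.

## Simulated measurements

**Mixture profiles.** I_exp(q) = Σ_k w_k I_k(q) + ε with Gaussian ε of
σ(q) = rel·I(q)·(1 + c·q), rel = 2% and c = 5 Å by default — relative error
growing toward high q as on real detectors. With zero noise the weighted
sum is returned exactly (the recorded σ column then falls back to a nominal
1% so downstream fits stay weighted). Default truth: closed:open = 45:55,
chosen so the mixture's Guinier R_g lands mid-way in the 48–49 Å window.

**SEC-SAXS stacks.** Buffer-only frames followed by peak frames whose
mixture signal is scaled by a Gaussian elution profile over a flat
background (default background ≈ 0.3 of the mean signal, apex
signal-to-background well above the merge threshold).

**SPR sensorgrams.** The 1:1 interaction integrated exactly per
constant-concentration segment; default single-cycle schedule is a 2-fold
ladder topping at 400 nM with 60 s association/dissociation phases, additive
Gaussian noise in response units.

**Melt curves.** Two-state sigmoid (default width 2.5 °C) between linear
pre/post baselines on a 15–90 °C grid at 0.5 °C steps; default instrument
noise in the generator's acceptance-level experiments is 0.2% of the
transition amplitude, the smoothness of ratiometric fluorimetry data.

## Reductions

**Guinier.** Weighted least squares of ln I vs q² over an iteratively
self-consistent window: starting above any leading non-positive
intensities, the window is grown/shrunk until q_max·R_g ≤ 1.5 (the default
limit; data below q = 0.01 Å⁻¹ are never used) and the estimate is stable
to 0.1%. Ties break toward the widest valid window. For an ideal sphere
the residual curvature of ln I inside a 1.5 window biases R_g upward by
≈ +2.4%; the sphere oracle tests therefore use the tighter globular
convention q·R_g < 1.3 (bias ≈ +1.9%). Real windows are a data-quality
decision; both limits are exposed as a parameter.

**Indirect Fourier transform.** p(r) on a 201-point grid over [0, D_max]
solves min ‖(A·p − I)/σ‖² + α‖D₂·p‖² with p ≥ 0 and p(0) = p(D_max) = 0,
where A encodes I(q) = 4π Σ p(r)·sinc(q r)·Δr and D₂ is the second
difference. α is chosen at the corner of the L-curve over a 15-point log
grid unless given. A reduced misfit χ² > 3 flags an inconsistent D_max.
The D_max scan solves free-endpoint IFTs over a bracket and returns the
smallest support whose solution both fits the data (χ² within 20% of the
bracket best) and decays below 1% of the peak; a scan pinned at the lower
bracket edge is flagged degenerate (point-like scatterer).

**Feature detection.** Peaks are local maxima of a Savitzky–Golay-smoothed
curve; shoulders are downward zero crossings of the smoothed second
derivative on descending flanks. Defaults: window 11 points for Kratky
curves, 21 for 1 Å-binned P(r) histograms (bead-level granularity).
Two reported composites deserve explanation:

- *Inter-domain P(r) shoulder*: the outermost detected feature with
  normalized p ≥ 0.45. Domain–domain distances are the largest strong
  distance population; fainter ripples beyond belong to the single-pair
  tail.
- *Kratky domain feature*: for compact curves, the first feature beyond the
  main maximum; for strongly extended conformers the domain-scale hump is
  itself the global maximum with a broad flat top, where a point argmax is
  ill-conditioned — the position is then the centroid of the region within
  1.5% of the maximum.

**Frame processing.** Buffer frames are averaged and subtracted with
quadrature error propagation. Merging keeps frames whose integral exceeds
30% of the apex frame and whose Guinier R_g lies within 5% of the apex R_g,
then averages them (σ/√n scaling).

## Conformational sampling

High-temperature dynamics over the flexible regions is replaced by a
randomized-move pool generator. Per conformer and per Fab arm: the arm
direction is drawn uniformly on the sphere, the hinge is laid as a
worm-like chain along it (3.8 Å per bead, per-step wobble 2σ), and the Fab
(with its arm glycans) is rigidly re-attached continuing the chain at its
hinge-proximal pole — the coarse-grained CH1 exit — with a random roll;
every hinge bead then applies a Gaussian pivot (σ, default 25°) to
everything downstream. Tailpieces and glycan chains are perturbed by plain
per-bead pivots. The re-aim/re-extend step is what decorrelates the pool:
pivots alone can neither lengthen a linker the seed lays short nor swing
the arms far from the seed arrangement, and the two arms must explore
independently. σ = 0 returns the seed model unchanged; σ controls folding
depth (the compact reach of the R_g distribution is monotone in σ), while
the splayed reach is direction-driven and σ-independent.

Candidates are rejected on steric clash: any bead-centre pair below 1.5 Å
between different rigid bodies, or between a glycan chain and a body it is
not anchored to. The cutoff is a hard-core limit: with one bead per
residue, the surface beads of two domains in genuine contact interleave
well below the 3.8 Å backbone spacing, and a cutoff near 3 Å would veto
every compact conformer (the compact reference state itself contains
inter-body pairs at 1.6 Å). A 500-conformer pool seeded from the open
conformer reaches from the closed window (43–46 Å) through the extended
window (63–66 Å) with contiguous coverage between.

## Multistate fitting and state counting

For a fixed conformer subset, non-negative least squares on the
σ-weighted intensities yields coefficients a_k; the scale c = Σa absorbs
magnitude and w = a/c lives on the simplex. χ² is the σ-weighted residual
sum divided by the number of points M (per-point normalization; M vs M − p
affects absolute values, not rankings). k = 1 is ranked exhaustively;
k ≥ 2 by beam search extending the best (k−1)-subsets with every pool
member (duplicates collapsed), which enumerates exhaustively whenever the
beam width covers all retained (k−1)-subsets — the oracle tests exploit
this on 30-conformer pools. Ties break toward smaller weighted-mean R_g,
then lexicographic ids. The pipeline accepts k+1 over k only for a > 15%
χ² improvement (configurable).

State counting pools the top fits whose χ² lies within 5% of the best
(models of the same goodness-of-fit — a looser tolerance admits fits that
are statistically far worse over ~200 points and smears the state
structure), histograms their conformers' R_g weighted by the
state weights, smooths with a 2 Å Gaussian, and calls every local maximum
above 10% of the global one a state; histogram mass is attributed to the
nearest peak. Pools much sparser than the ten-thousand-model pools of
production rigid-body pipelines fit with a higher χ² floor; the demo
pipeline therefore seeds the pool with the three reference conformers in
addition to sampled ones.

## Auxiliary fits

**SPR.** Global nonlinear least squares of the exact piecewise 1:1
solution over the whole single-cycle trace, with rate constants on a log
scale and a 3 × 3 multistart grid over (k_a, k_d) decades unless guesses
are given. A schedule whose lowest injection exceeds 10 × K_D triggers a
correlation warning (only R_max and the equilibrium constant's order of
magnitude remain well determined). The fit is invariant under uniform
response rescaling.

**Melting temperature.** T_m is the centroid of the contiguous region
above 80% of the peak of the smoothed |dS/dT| (Savitzky–Golay, window 21
points, handling rising and falling transitions alike); a point argmax on
the broad derivative top is noise-dominated. Monotone or flat signals
raise instead of returning a number. At 0.2% amplitude noise this resolves
a 2 °C stability difference to within ±0.2 °C per measurement pair.

## What the synthetic experiments do and do not show

Passing tests demonstrate that each algorithm recovers the known ground
truth of an idealized generator: uniform-density domains, q-independent
bead form factors, Gaussian uncorrelated noise with a correctly recorded σ,
ideal 1:1 binding, two-state thermal unfolding. They do not exercise
inter-frame correlations, radiation damage, concentration effects,
hydration-layer contrast (a single multiplicative factor is provided but
off by default), excluded-volume refinements, mass-transport-limited SPR,
or real glycan chemistry. Quantities tied to the calibrated geometry (the
feature positions reported by `scripts/acceptance.py`) characterise the
builder's default models, not any particular experimental sample.

## Problem sizes and defaults

Default q-grid 220 points on [0.01, 0.45] Å⁻¹; antibody models ~1,460
beads; Debye evaluation via 0.25 Å distance-histogram bins (≤ 0.2%
deviation from the exact double sum, ≤ 0.5% guaranteed by the invariant
test); demo pool 150–300 conformers plus the three reference modes (the
pool-size default of 1,000 in the sampler is scaled down in the demo
configuration); sphere oracles use a lattice filling of ~4,200 beads.
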