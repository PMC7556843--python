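# Methods

This note documents the models and numerical choices behind `ubisax`: what
is computed, with which defaults, and what the synthetic closure tests do
and do not demonstrate.

## Chain representation

A chain of N domains is described by a `DomainTopology`: each domain
contributes `residues_per_domain` residues (default 76) of which the first
`core_span` (default 70) form a rigid core; the remaining residues form the
linker to the next domain, and the last domain ends at its core. With the
defaults this gives cores at residues 1–70, 77–146, 153–222, 229–298, …
and total length 76N − 6. A His-tag or other N-terminal extension can be
represented by enlarging the first domain via the topology parameters
rather than special-casing.

Conformations are `BeadChain`s: one or more beads per residue with a
domain id, a bead class (the form-factor key) and a backbone flag. All
coordinates are nanometres internally; the PDB-style file format stores
Ångström and encodes the domain in the chain id, the bead class in the
atom name and the backbone flag in the B-factor column.

Domain "centers" are unweighted geometric centers of backbone beads.
Coarse-grained bead masses are nearly uniform, so this stands in for the
center of mass without importing a force-field mass table; the same choice
applies to the distance collective variable.

An elastic network (default k = 500 kJ mol⁻¹ nm⁻², cutoff 0.9 nm) may be
built over backbone bead pairs within a single core; pairs never span
domains or touch linker residues, so the network fixes each fold while
leaving the inter-domain geometry free. The cutoff is a package default
chosen from common coarse-grained practice and is configurable.

## Collective variables

For an N-domain chain the biasing/analysis set is:

- one core-center distance per unordered domain pair;
- one inter-domain torsion per pair: the dihedral of the two domain axes,
  each axis running N→C from the center of the first half of the core to
  the center of the second half (the first half takes the extra residue,
  i.e. residues 1–36 vs 37–70 of each ubiquitin core). Point order is
  (i first half, i second half, j second half, j first half) with the
  IUPAC right-handed sign convention; swapping i and j reverses the point
  sequence and leaves the value unchanged. Collinear geometry returns NaN
  rather than an arbitrary angle;
- one backbone radius of gyration;
- one "alphabeta" torsional similarity per linker,
  ½ Σₖ (1 + cos(φₖ − φ_ref,ₖ)) over the linker's backbone dihedrals
  (reference angles default to 0 and are configurable). Aggregating all
  dihedrals of a linker into a single CV is what makes the totals come out
  at 4, 9 and 16 for 2, 3 and 4 domains.

## SAXS forward model

Debye summation over bead pairs with q-independent effective scattering
lengths per bead class. The built-in residue table assigns each amino acid
its electron count minus displaced solvent (0.334 e Å⁻³ times a standard
residue volume); a uniform table (f ≡ 1) serves geometry-only work and
tests. Users with published coarse-grained form-factor parameters can
supply them as a plain mapping.

Supporting analytics:

- `restraint_grid`: equidistant q points including both endpoints (e.g. 21
  points in 0.017–0.24 nm⁻¹);
- `smooth_experimental`: least-squares polynomial (default degree 16,
  fitted on a scaled domain for conditioning) evaluated at the restraint
  points, with experimental σ linearly interpolated there. Interpolating σ
  rather than using polynomial residuals is a choice; the residual-based
  alternative is easy to add but not implemented;
- `initial_scaling`: the calculated-to-experimental ratio at the lowest
  shared q point;
- `guinier_rg`: weighted linear fit of ln I vs q² over the largest prefix
  window with q_max·Rg ≤ 1.0, iterated to a fixed point (≤20 iterations).
  For strongly anisotropic bodies (thin rods) the Guinier approximation
  itself biases the result by a few percent at that window; a tighter
  product (0.8) restores ~2% accuracy and is exposed as a parameter.

## Metainference score

Restraint points are scored with the σ-marginalized long-tailed
likelihood E = −ln[(1 − e^(−λ))/λ], λ = (d − s·f − o)²/2σ², evaluated with
`expm1` and a series branch below λ = 10⁻¹², so the Gaussian limit λ/2
holds to machine precision. A Gaussian alternative sits behind
`noise_model="gaussian"`. The effective σ² is σ_B² + σ_mean², where σ_B is
a sampled or fixed noise level (falling back to the experimental σ of the
restraint set) and σ_mean is the maximum block-wise standard error of the
ensemble-averaged forward model. Whether σ_B is global or per-point is
configurable; the default follows the restraint set per-point. Scaling and
offset are sampled by Metropolis moves with uniform proposals; proposals
outside the prior box ([0.9, 1.1] × [−1, 1]) are rejected outright, which
preserves detailed balance with respect to exp(−E/kT) on the box.

Post-hoc ensemble refinement (`reweight_to_saxs`) is a maximum-entropy
update: minimize χ²/2 − θ·S_rel(w‖w₀) through its convex dual (L-BFGS-B on
one multiplier per restraint point, intensities normalized to the first
data point for conditioning). θ = 1 by default; smaller values fit
tighter. This is the Gaussian-limit counterpart of the metainference
score: a per-frame exp(−E) importance weighting cannot be used here
because the restraint compares the data with the ensemble *average*, which
no single frame needs to match.

## Sampling

`run_sampler` is multiple-walker Metropolis MC with three move kinds:
pivot rotations of everything downstream of a random linker bead,
single-linker-bead displacements, and rigid spins of one domain about its
centroid. None of these deforms a core, so the elastic network acts as a
guard. The surrogate potential is: hard-core exclusion (default diameter
0.4 nm) between core beads of different domains; harmonic linker bonds
(r₀ = 0.35 nm, k = 1000 kJ mol⁻¹ nm⁻²); the elastic network; and an
optional Gaussian attraction between neighboring core centers to emulate
compact-state propensity. Chains without linker residues are outside the
move set's domain. Default walker count is 8 and everything is driven by a
single seeded generator, so runs are bit-reproducible.

Bias: well-tempered parallel-bias metadynamics. Each CV carries a 1-D bias
accumulated on a 512-point grid (hills are also logged individually);
deposition every 200 steps with base height 0.1 kJ/mol, bias factor
γ = 10, and per-CV heights carrying both the well-tempered decay
exp(−V/(kT(γ−1))) and the parallel-bias conditional weight
exp(−Vₖ/kT)/Σⱼexp(−Vⱼ/kT). The combined bias is
V_PB = −kT ln Σₖ exp(−Vₖ/kT). Hill widths are fixed per CV (set from a
short unbiased pre-run as ~0.5× the CV standard deviation, or given
explicitly); an adaptive-width scheme is deliberately not implemented.
Final-bias reweighting w ∝ exp(+V_PB/kT) recovers unbiased averages.

With restraints configured, the metainference energy of the
walker-averaged forward model enters the acceptance only every fifth step
(the restraint stride) and is held constant in between; scaling and offset
are Gibbs-updated at the same cadence.

`run_metad_1d` is a one-dimensional calibration utility used to validate
the bias machinery against analytic Boltzmann integrals: on a ~15 kT
tilted double well, 150 000 steps (40 000 discarded) recover the
free-energy difference to ~0.2 kT, well within the 0.5 kT target.

## Ensemble analysis

- Free-energy surfaces: F = −kT ln(weighted 2-D histogram), minimum
  shifted to zero, empty bins NaN (never zero).
- Compactness: a neighbor core pair is *open* iff its minimum inter-core
  bead distance exceeds 0.6 nm (strictly; 0.6 itself is compact).
- Contact maps: per residue pair of two cores, the weighted probability of
  any bead-pair contact within 0.6 nm — the same length as the
  open/compact threshold, for consistency; configurable.
- End-to-end distance: first backbone bead of residue 1 to the last
  backbone bead of the final residue.
- Power-law fits A·Nᵛ by nonlinear least squares (`curve_fit`), with a
  fixed-exponent mode (linear in A) for extrapolating other linkages from
  a measured prefactor. `min_chain_length_for_two_dimers` scans integer
  N ≥ 3 for the smallest N with A·(N−2)ᵛ ≥ span.
- Bound-likeness: backbone RMSD of a neighbor core pair to a two-domain
  reference after optimal (Kabsch) superposition, threshold 0.6 nm (6 Å).
  The reference "average structure" helper iteratively superposes onto a
  running mean (3 iterations). Clash-excluded mode maps the rigid partner
  surrogate through the superposition transform onto the bound-like pair
  and discards frames where any bead outside the pair comes within the
  clash cutoff (default 0.5 nm) of the surrogate.

## Synthetic generators

The domain surrogate is a rigid icosahedral shell of 12 beads at radius
1.2 nm (the size of a ubiquitin core), 18 residues per domain (12 core +
6 linker, one backbone bead each). Linker beads are interpolated between
consecutive cores with a small fixed zigzag so their dihedrals are well
defined; their spacing is wider than a real backbone bond, which is why
bond-length validation is opt-in.

- `saw`: pivot-algorithm MC over rigid domains with hard-core exclusion
  (0.4 nm) between core beads of different domains; joint spans vary in
  0.5–1.8 nm, a range set so the surrogate reproduces the length-scale
  ratios of SAXS-refined polyubiquitin ensembles (e2e roughly 1.5× per
  doubling at short N, mean neighbor distances ~3–3.5 nm). The resulting
  effective scaling exponent for N = 1–6 is ~0.66 — on the high side of
  the Flory value, as expected for short stiff chains — and is an emergent
  property, not a fitted one.
- `two_state`: each neighbor joint is independently compact (target
  minimum inter-core distance sampled in 0.42–0.58 nm) with probability
  `p_compact` (default 0.45, the diubiquitin range), else open (0.8–2.2
  nm); joint placement iterates the span until the target minimum distance
  is met to 0.02 nm, rejecting hard-core clashes with earlier domains.
  Non-neighbor pairs are uncorrelated by construction.
- `bound_like`: joints adopt a stored deterministic compact reference
  geometry (minimum core distance 0.45 nm) with probability `p_bound`
  (default 0.032), else an open placement. The partner surrogate is a
  rigid two-rod bead model whose axis endpoints are 11.4 nm apart, placed
  1 nm clear of the reference pair.
- `synth_saxs`: ensemble-averaged Debye curve with multiplicative Gaussian
  noise (default 2%) and a σ column equal to the noise scale.

What the closure tests show: that the forward model, the score, the
reweighting and the analyses are mutually consistent and statistically
calibrated on ensembles whose ground truth is known. What they do not
show: anything about force-field accuracy, sequence-specific contacts,
hydration-layer scattering, or experimental systematics — the surrogate
has none of those.

## Numerical details and edge cases

- Debye sums use `np.sinc`, exact at q·r = 0; pair terms are chunked to
  bound memory. Single-bead structures return the flat self-term.
- Guinier windows shorter than 3 points, or non-positive intensities in
  the window, raise; non-decaying curves return Rg = 0 flagged converged.
- `classify_open` rejects negative distances; FES bins with zero weight
  are NaN so that re-adding the minimum reproduces −kT ln(histogram)
  exactly on occupied bins.
- The reweighting dual is convex; failure to improve χ² indicates the
  restraints carry no information against the prior at the given σ (e.g.
  a q window restricted to the Guinier region cannot distinguish mixtures
  whose average size matches within noise — the closure tests therefore
  restrain out to q = 2 nm⁻¹ where inter-domain distances scatter).
- kT defaults to 2.494 kJ/mol (300 K) everywhere.

## Known limitations

Monte-Carlo only (no forces/gradients of CVs); no multi-replica σ_mean
scaling — walker averaging is explicit; rigid domains mean intra-core
observables are trivial; the NEMO surrogate is a geometric stand-in with
the correct span, not a structure; desk-scale sampling cannot and does not
try to reproduce cluster-scale ensemble observables.
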