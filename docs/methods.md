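# Methods

`fapkit` re-implements, as a tested pipeline over synthetic data, the
computational analyses surrounding the FapC functional-amyloid system of
*Pseudomonas*: operon mining from profile-HMM hit tables, imperfect-repeat
motif statistics, helical fibril geometry, small-angle X-ray scattering
(SAXS) models, and AFM twist-periodicity estimation.  This note records the
models, the parameter choices that matter, and the design decisions taken
where the problem was genuinely open.

## Operon mining

Genes are annotated by five profile HMMs (FapA, FapBC_repeat, FapD, FapE,
FapF).  FapB (the nucleator) and FapC (the major fibril subunit) are too
variable for separate profiles, so one FapBC_repeat HMM matches their
shared ~39-residue imperfect repeats and the two genes are separated by
synteny afterwards.

- **Hit filtering.** HMMER3 `domtblout` rows are parsed with an e-value
  cutoff of 1e-5 applied to the full-sequence e-value.  Per-domain
  (i-Evalue) filtering is available (`per_domain=True`) but off by default:
  the per-sequence score sums evidence over all repeats in a gene, which is
  the natural unit for gene-level annotation.
- **Clustering.** Single-linkage chaining of HMM-hit genes along each
  contig.  The intergenic distance is the gap between annotated gene
  boundaries, `start(downstream) − end(upstream) − 1`, strand-agnostic, and
  the threshold is a strict `< 5000` bp.  Chaining tracks the furthest
  right edge reached so far, so nested or overlapping genes cannot split a
  cluster; the result is identical to pairwise single-linkage (property-
  tested against a brute-force union-find oracle).
- **Operon filter.** A cluster is kept when it has at least one
  FapBC_repeat gene and at least three additional HMM-hit genes (total
  size ≥ 4, genes counted as genes regardless of HMM identity).
- **Synteny.** With ≥ 2 FapBC_repeat genes, the first in genomic order is
  fapB, the second fapC (the fapABCDEF gene order).  A single FapBC_repeat
  gene leaves both designations absent and the cluster out of the repeat
  census — synteny cannot tell B from C without a partner.  More than two
  flags the operon for review; the first two are still assigned.
- **Repeat resolution.** Domain hits on a gene are numbered IR1..IRn by
  alignment start.  Pairs overlapping by more than 50% of the shorter
  domain are resolved greedily by bitscore (highest kept).  This rule is a
  package decision to make repeat counts well defined on adversarial
  inputs; non-overlapping real repeats are unaffected.  A gene hit by
  multiple HMMs takes the identity of its best full-sequence bitscore hit.

## Repeat motifs and logos

A position-frequency matrix is built per alignment column over the 20
amino acids; gaps are tracked as a separate per-column fraction and
excluded from the frequency simplex (standard logo convention — the
alignment is assumed to come from HMM match states upstream).  Information
content is `IC = log2 20 − H(column)` bits, in [0, 4.32]; an optional
small-sample correction `(20−1)/(2 n ln 2)` is off by default.

The consensus motif uses the field's notation with configurable
thresholds, applied in priority order per column: top frequency ≥ 0.97 →
capital letter ("complete"); ≥ 0.60 → lowercase ("high"); summed frequency
over the hydrophobic set {A, V, L, I, M, F, W, C} ≥ 0.60 with no single
residue ≥ 0.60 → Ψ; top two residues each ≥ 0.30 and within a factor 2 →
"(x/y)"; otherwise `*`.  The numeric thresholds are package defaults — the
notation itself carries no numbers — and S/T/Y are excluded from the
hydrophobic set because the notation distinguishes small-polar (a/s)
positions from Ψ.  No pseudocounts by default; Laplace smoothing is a flag.

The synthetic repeat generator realizes a FapC-like 27-column consensus
(`gasGNΨGΨNΨaaG*gNqQ*N*Ψ(a/s)Ψ(a/s)*`) as a PFM: complete columns carry
0.98 on one residue, high columns 0.75, Ψ columns spread 0.88 over three
core hydrophobics, pair columns split 0.88 evenly, and unconserved columns
are even over six mixed residues.  Leftover mass goes to a handful of
alternative residues rather than a uniform smear: real repeat columns
substitute among few residues, and narrow support keeps the sampling
variance of rebuilt frequencies small enough that 1000 sampled sequences
reproduce each column within total-variation distance 0.05 (the expected
per-column TV at this design is ≈ 0.02, with the maximum over 27 columns
≈ 0.04).

## Helical geometry

A fibril's screw symmetry is (rise Δz in Å, twist Δφ in degrees); negative
twist is a left-handed helix, and positive twist means right-handed
rotation about +z viewed from +z.  Derived quantities:

- crossover distance (full 360° turn): `rise × 360 / |twist|` — 864 Å for
  both the per-layer symmetry (4.8 Å, −2°) and the per-monomer,
  three-layer symmetry (14.4 Å, −6°), which are related by composition
  (rise ×3, twist ×3);
- half-twist period: crossover / 2 = 43.2 nm — the apparent height-
  modulation period of a twisted fibril adsorbed on a surface, because the
  projected shape repeats every 180°.

Angle composition wraps to [−180, 180), so a composed twist of exactly
±180° is reported as −180° (the two are the same rotation).  Assembly
stacks monomer copies by the screw operator about z; axis alignment is the
caller's job, with `principal_axis_to_z` provided as a helper.  Optimal
superposition RMSD uses the Kabsch construction (SVD of the covariance
matrix, determinant sign corrected to exclude reflections); collinear
point sets are rejected.

## SAXS

**Geometric model.** A fibril is a cylinder with an elliptical
cross-section (semi-axes R and εR, ε ≥ 1), length L, and a Gaussian
grading of the surface of width σ, plus a Gaussian-chain term for
disordered loops and termini:

    I(q) = S_cyl · P_cyl(q; R, ε, L, σ) + S_pol · P_pol(q; Rg) + b

Both form factors are normalized to 1 at q = 0.  The cylinder amplitude at
tilt α and cross-section azimuth φ is `[2J₁(u)/u] · sinc(qL cos α / 2) ·
exp(−(q sin α)² σ²/2)` with `u = q sin α · R√(cos²φ + ε² sin²φ)`; P_cyl is
the orientation average of the squared amplitude over α ∈ [0, π/2]
(weight sin α) and φ ∈ [0, π/2], by Gauss–Legendre quadrature with 128 × 64
nodes (converged: doubling the nodes changes nothing at 6 digits over the
fitted window; node counts are arguments).  Applying the grading as a
Gaussian damping of the cross-section amplitude is the package's reading of
"a grading of the surface given by σ"; it is isolated in one factor so an
alternative functional form is a one-line change.  The polymer term is the
Debye function `P(x) = 2(e⁻ˣ − 1 + x)/x²`, `x = q²Rg²`, with a Taylor
series below x = 0.01 (cancellation) and the 2/x asymptote above 1e8
(overflow).  q is in nm⁻¹ everywhere; a converter handles Å⁻¹ input.

**Fitting.** Weighted least squares on Σ((I_model − I)/σ)².  L (100 nm,
far beyond the resolution of the fitted window — verified by the
length-insensitivity test) and σ (0.5 nm) are fixed by default; R, ε,
S_cyl, S_pol, Rg, b are free.  Positivity (and ε ≥ 1) is enforced by a log
transform.  Because the χ² basin in (R, ε) is narrow, the fit is
multi-start and deterministic: a coarse grid over (R, ε, Rg) — with the
linear parameters (S_cyl, S_pol, b) solved exactly by weighted linear
least squares at each grid point — ranks starting points; Nelder–Mead runs
from the best three (at a reduced 64 × 32 quadrature for speed); a single
Levenberg–Marquardt polish at full quadrature finishes.  Reduced χ² uses
n_points − n_free.  Non-convergence sets a flag instead of raising.

**Identifiability of the recovery suite.**  The recovery test plants the
UK4 cross-section (full axes 2R × 2εR = 3.4 × 11.3 nm — the "a × b nm²"
convention is full axes) with 1% multiplicative noise, σ-column = 1% of
the true intensity, q ∈ [0.03, 4] nm⁻¹, 150 points, and *no* disordered
contribution (S_pol ≈ 0, b = 0, though both remain free in the fit).
Under these conditions both axes are recovered to ~0.2% on every seed
tested.  With a substantial planted polymer term and background the axes
are not statistically identifiable to 5% at this noise level — on many
noise draws the global χ² minimum lies 6–15% from the truth (the fitted χ²
falls *below* the true-parameter χ², so this is estimator variance, not an
optimizer artefact).  Noisy curves with full polymer + background terms
are therefore exercised with χ²-band assertions rather than 5% parameter
recovery.

**Atomic route.** The Debye equation `I(q) = Σᵢⱼ fᵢfⱼ sinc(q rᵢⱼ)` over
explicit scatterers, with per-atom excess scattering lengths
`f = Z − ρ_water · V_displaced` (ρ_water = 0.334 e/Å³; displaced volumes
from the standard solution-scattering tables).  The hydration layer is a
shell of beads on a cubic grid (default spacing 1.5 Å) at distances
[1.8, 4.8] Å from the nearest atom, each carrying 10% of bulk water's
electron density times the voxel volume; thickness, density, probe radius
and spacing are all configurable, since hydration-layer parameterizations
vary between calculators.  The exact double sum is used up to 2000
scatterers; beyond that a pair-distance histogram (bin width 0.05 Å,
maximum allowed 0.1 Å) accumulated in memory-bounded blocks agrees with
the exact sum to well under 0.5% for q ≤ 5 nm⁻¹ (tested on 100-atom random
configurations).  A residue-level coarse-grained mode (one bead per
residue carrying the summed f) is provided for long fibrils.  Affine
comparison of a computed curve against data (`I ≈ scale · I_model +
const`) is closed-form weighted linear least squares with n_free = 2;
a constant model curve is rejected as rank-deficient.

## AFM periodicity

Height profiles (uniform sampling required, ≥ 32 points) are detrended
(mean + linear), Hann-windowed, zero-padded ×4, and the dominant non-DC
peak of the power spectrum is refined by parabolic interpolation on the
three bins around the maximum; the period is 1/f_peak.  A peak is
significant when its power exceeds 5× the median spectral power (the
default k = 5); estimates implying a period longer than half the profile
are discarded.  On a 1 µm trace at 2 nm sampling this resolves a 43 nm
period to well under 1%.  Note that the extreme bin of a pure white-noise
spectrum reaches ≈ 8–10× the median, so when genuinely unmodulated noisy
profiles are possible a stricter ratio (k ≈ 20) should be passed; the
default favors sensitivity on profiles known to contain a fibril.
Aggregation reports the sample mean and sd (n−1) over profiles with a
detected period, counting the rest.

## Synthetic data

All generators are pure functions of (configuration, seed) via
`numpy.random.default_rng`, and each returns a ground-truth manifest the
tests compare against (never hard-coded expectations).  What they emulate,
and what they do not:

- `synth_fap_genome` plants fapABCDEF operons (one per contig) with
  configurable intergenic gaps — including 4999/5000 bp boundary cases —
  per-operon repeat counts, and decoy genes whose hit e-values sit above
  the parsing cutoff.  Gene lengths are realistic for the operon (fapB/C
  lengths derive from the repeat layout: repeats of 39 aa from residue 45
  with 14-aa linkers); sequence composition is random except for the
  planted repeats.  No codon structure, no strand variation, no
  overlapping genes — only the structure the mining stage consumes.
  The emitted HMMER3 `domtblout` dialect round-trips through the parser.
- `synth_repeat_set` samples alignment columns independently from a PFM
  (no phylogenetic correlation between sequences — rebuilt frequencies are
  therefore cleaner than real repeat families at equal n).
- `synth_saxs_curve` is the forward model with multiplicative Gaussian
  noise, σ-column = noise_frac × true intensity.  With noise_frac = 0 the
  σ column is floored at 1e-6 × I to preserve the curve invariant σ > 0.
- `synth_helical_trace` stacks a planar pseudo-atom arc (a crude one-layer
  cross-β stand-in) by the screw symmetry; it has no side chains, no
  β-strand geometry, and uniform scattering lengths.
- `synth_height_profile` is baseline + sinusoid (default 1 nm amplitude,
  the ≈ 43 nm half-crossover period) + white noise, with a seeded random
  phase; it rejects sampling coarser than period/4.  Real AFM traces add
  baseline drift, tip convolution and height heterogeneity that the
  generator does not model, so passing tests demonstrate the estimator,
  not instrument robustness.

## Problem sizes

The test and analysis problem sizes are chosen to exercise every code path
at desk scale: 10–30 planted operons (the real census spans ~1200
clusters), 1000 sampled repeats, 40 height profiles of 500 points, SAXS
curves of 80–150 points, fibrils of 60–225 layers of 12–20 pseudo-atoms.
All quantities compared against planted truth are size-calibrated (TV
bounds, χ² bands) rather than scale-dependent constants.

## Known limitations

- The operon miner assumes one genome's genes carry unique ids and does
  not model split genes, frameshifts or contig-edge truncation.
- The consensus-motif thresholds are defaults, not fitted to any reference
  motif; different thresholds move columns between classes near the
  boundaries.
- The elliptical-cylinder model has no explicit cross-terms between the
  cylinder and polymer contributions (they are assumed incoherent), and
  the surface grading form is one of several in use.
- The hydration shell is a uniform-density bead layer; real hydration
  density varies with surface chemistry.
- The period estimator assumes a single dominant periodicity; beating
  between polymorphs in one trace will yield the stronger component only.
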