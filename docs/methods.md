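# Methods

## Distance matrix as a texture image

A domain is reduced to its ordered C-alpha trace; the N×N matrix of
pairwise Euclidean distances (Å) is treated as a grayscale image.
Because secondary-structure elements constrain local C-alpha
geometry, each element class leaves a stereotyped low-distance pattern:

- **α-helix** (≈3.6 residues/turn): d(i,i+3) ≈ 5.1 Å < d(i,i+4) ≈ 6.2 Å,
  producing a strip 3–4 residues wide, parallel to and near the main
  diagonal;
- **anti-parallel β-sheet**: residue p pairs with q, p+1 with q−1 — a
  low-distance strip perpendicular to the diagonal;
- **parallel β-sheet**: p pairs with q, p+1 with q+1 — a strip parallel
  to the diagonal at a sequence separation set by the connector length;
- **other packing contacts** (helix–helix, helix–sheet): short
  horizontal/vertical dashes 3–4 residues apart.

## Gabor decomposition into binary contact matrices

Three real (cosine-phase) Gabor kernels are sampled on an odd integer
grid: t₁₃₅ (stripes along the main diagonal; helices and parallel
sheets), t₄₅ (stripes along the anti-diagonal; anti-parallel sheets)
and t₀₊₉₀ (sum of the 0° and 90° kernels; dash/cross textures). The DM
is convolved with each kernel (same-size output, edge replication at
the borders — zero padding would fabricate spurious "near contacts"
because real border distances are large) and binarized at **response
≤ 0**. The 135° response is split at sequence separation d₀ = 5 into a
near-diagonal band (BCM_H) and the remainder (BCM_P); the other two
responses have the trivial |i−j| ≤ 1 band zeroed (adjacent residues
are ~3.8 Å apart in every structure and carry no signal), giving BCM_A
and BCM_O. All four matrices are binary and symmetric by construction
(the kernels are transpose-symmetric and the DM is symmetric).

**Why the kernels keep a positive DC component.** The sign threshold
only carries information if a featureless background maps to a strictly
positive response. A zero-mean kernel annihilates constants, so on the
smooth large-distance background the response hovers around zero with
an oscillating sign and the ≤ 0 rule marks roughly half of it (measured
~30% spurious BCM_A density on an ideal helix). We therefore keep the
sampled kernel's natural positive mean — background regions (large
distances) then convolve to positive values, and only a low-distance
strip aligned with the kernel's negative lobes flips the sign.
Configurations whose sampled mean is not positive are rejected at bank
construction. The trade-off is that the output is intentionally not
invariant to a global additive offset of the DM; that offset dependence
is the mechanism that separates contacts from background.

**Filter parameters** (config `gabor.*`): wavelength 8 residues (the
flanking negative lobes sit ±4 residues from the kernel center,
matching the 3–4-residue strip width), aspect ratio 1.5, major axis 8
(= 2σ of the Gaussian envelope along the orientation), size 9×9.
These were calibrated once on noise-free generator output (helices of
25 and 40 residues, 8+8 and 12+12 hairpins, an 8+8 parallel sheet with
a 20-residue spacer) by scanning a parameter grid for the region where
every strip lands in its own BCM with cross-class densities < 0.02;
the defaults sit inside that region with margin (helix band density
≈ 0.70, cross-class densities 0.00), not on its edge. Domains shorter
than the kernel (N < 9) cannot be filtered and are rejected.

Note that a β-strand's own zigzag also texture-matches t₁₃₅ near the
diagonal, so sheet-containing domains show some BCM_H band signal;
H vs P is a band-position split of one filter response, not a
pattern-level discrimination, and the relative densities remain
strongly class-informative.

## Moments

**Composition moments.** c_k = (number of 1s in the strict upper
triangle of BCM_k) / (N(N−1)/2) ∈ [0, 1] — the density of each contact
class. The area uses the strict upper triangle (the diagonal carries no
contact information).

**Legendre moments.** For an image f on an N×N grid mapped onto
[−1, 1]² by xᵢ = −1 + 2i/(N−1),

λ_pq = (2p+1)(2q+1)/N² · Σᵢⱼ P_p(xᵢ) P_q(yⱼ) f(i, j),

with P_n the Legendre polynomial (three-term recurrence, degrees 0–5).
Low orders capture the mass and center of each contact class along the
sequence, order 2 its spread, order 3 its asymmetry, orders 4–5 outlier
layout. Moments are computed on the full symmetric BCM, which makes
λ_pq = λ_qp hold exactly; only the 11 pairs with p ≤ q and
1 ≤ p + q ≤ 5 are kept per matrix. (0,0) is excluded because it
duplicates the composition moment up to a constant.

**Descriptor.** 49 features: [c_H, c_P, c_A, c_O, ln N, then 11
Legendre moments for each of H, P, A, O]. The length feature is ln N
by default (domain sizes are heavy-tailed, so the log equalizes scale;
`moments.length_mode = "raw"` selects N itself). The descriptor is
invariant under rigid-body motion of the input coordinates (the DM is)
and deterministic.

## Synthetic structures

The generator emulates ideal secondary-structure geometry with
textbook parameters: helices with 1.5 Å rise, 2.3 Å radius, 100°/residue
twist (3.6 residues/turn, consecutive C-alpha 3.83 Å); strands with
3.3 Å axial spacing, a 0.6 Å alternating zigzag and 4.8 Å pairing
distance; connecting loops laid on circular arcs with ≈3.5 Å steps so
every consecutive C-alpha distance stays in the physical 3.0–4.3 Å
band. Four domain classes are built from these parts: packed
antiparallel helix bundles (`all_alpha`), meander antiparallel sheets
(`all_beta_antiparallel`), same-direction strands with out-of-plane
crossovers (`all_beta_parallel`), and β-α-β repeats whose crossover
helices run back over the sheet plane (`alpha_beta`). Unit counts adapt
to the requested size; a construction that cannot land within ±10% of
the target residue count raises.

Coordinate noise is Gaussian per coordinate with the requested marginal
standard deviation but **correlated along the chain** (white noise
smoothed with a σ = 2-residue Gaussian along the residue index, then
rescaled): independent jitter of 0.2–0.3 Å routinely breaks bond
lengths out of the physical band, whereas correlated displacement —
like the low-frequency deformation of an elastic backbone — moves
neighbours together and keeps consecutive distances in 3.0–4.3 Å up to
noise_sd = 0.3.

What the generator does **not** emulate: real loop conformations,
sidechains, strand twist/bulges, imperfect helix geometry, chain
breaks, or the length/class distributions of real fold databases.
Passing tests therefore demonstrate that the pipeline recovers the
patterns the descriptor is designed around, and that the feature
space separates idealized classes; they do not certify accuracy on
CATH/SCOP-scale real data.

## Downstream analyses

- **Classification harness**: stratified k-fold (default 3)
  cross-validation; per-column standardization and, for the RBF-SVM, a
  small C/γ grid search are fit inside each training fold only
  (leakage-free). Random forest (200 trees) is the alternative backend.
  The harness configures off-the-shelf scikit-learn estimators; it is
  infrastructure, not a novel method.
- **Kernel PCA**: Gaussian kernel K = exp(−d²/w), w defaulting to the
  median pairwise squared distance; double centering; the top three
  eigenvectors (scaled by 1/√λ and projected, i.e. coordinates
  v·√λ) form the 3-D embedding. Component signs are fixed by making
  each eigenvector's first nonzero entry positive, so the embedding is
  deterministic. Degenerate input (all rows identical, or fewer
  distinct rows than components) raises.
- **Mean shift**: Gaussian kernel of bandwidth h (default: 0.3 quantile
  of pairwise distances); every point iterates to a kernel-weighted
  mean until the shift is < 10⁻⁵·h or 300 iterations; converged modes
  closer than h/2 are merged in point order and each point is labeled
  by its mode. The cluster count #C serves as a structural-variation
  proxy. The kernel choice, bandwidth rule and merge radius are this
  package's documented conventions (standard mode-seeking practice);
  all are arguments.

## Numerical and edge-case conventions

- Convolution runs over the full symmetric matrix; symmetry of the
  binarized output is then structural, and the composition moments read
  only the upper triangle.
- A constant DM is degenerate for the sign rule and logs a warning.
- PDB input: ATOM records only, one CA per residue (highest-occupancy
  altloc, ties to the first in file); missing residues are simply
  absent (logged), insertion codes keep file order; with no chain
  argument the first chain is used with a warning. Duplicate CA records
  within a residue and altloc are a format error.
- The trace table format (`residue_id x y z`, floats via `repr`)
  round-trips exactly.
- Benchmarks in the test suite and acceptance script run at desk scale
  (domains of 40–120 residues, 100-domain datasets, oracle checks at
  N ≤ 40), chosen so the full pipeline — generation, featurization,
  cross-validation — completes in seconds while still exercising every
  stage end to end.

## Known limitations

- The Gabor defaults are calibrated to ideal geometry; real, distorted
  SSEs may need different `gabor.*` settings, and strongly curved
  helices/sheets will blur across BCM classes.
- BCM_H on β-domains picks up strand zigzag texture near the diagonal
  (see above); consumers should read H/P/A/O densities jointly, as the
  classifier does.
- The d₀ = 5 band split misassigns parallel-sheet contacts with
  sequence separation ≤ 5 (rare: such short connectors are
  geometrically strained) and helix contacts beyond separation 5.
- Mean-shift cluster counts depend on the bandwidth rule; #C is a
  relative, not absolute, measure of variation.
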