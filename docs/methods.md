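# Methods

## Descriptor model

Each monomer contributes one SOAP center (its bead position, or the
center of geometry of a bead group computed with minimum-image unwrapping
relative to the group's first bead). The neighbour density around center
*i* is a sum of unit-amplitude Gaussians of width `sigma` on every
neighbour *j* within `rcut` (minimum-image convention), each weighted by a
smooth cutoff factor f(r<sub>ij</sub>): 1 below `rcut − w_switch`, a cosine
half-switch to 0 at `rcut`. The density is expanded in spherical harmonics
and radial functions orthonormal on [0, rcut] under the r² measure, and
contracted over m into the power spectrum γ<sub>nn′l</sub> with the
1/√(2l+1) prefactor and n′ ≥ n; components are ordered l-major, then
(n, n′) lexicographic. With nmax = lmax = 8 this gives 324 components.

Numerically, the coefficient of one neighbour Gaussian separates into
Y\*<sub>lm</sub>(r̂<sub>ij</sub>) times a 1-D radial integral against the
scaled modified spherical Bessel function e⁻ᶻ i<sub>l</sub>(z),
z = r·r<sub>ij</sub>/σ². The Bessel factor is evaluated by a three-branch
scheme (power series for z ≤ 0.7, Miller downward recurrence for
0.7 < z < 25, upward recurrence for z ≥ 25; relative accuracy ~1e-9), and
the radial integral by Gauss–Legendre quadrature with
max(64, 8·rcut/σ) nodes. The fast path agrees with a dense 3-D quadrature
of the density to better than 1e-6 relative (tested), and spectra are
invariant under rotation, translation and neighbour permutation to 1e-8.

Parameter defaults and rationale:

| parameter | default | meaning / rationale |
|---|---|---|
| nmax, lmax | 8, 8 | standard descriptor size; D = 324 |
| rcut | 0.8 nm | first coordination shell at Martini-like resolution; 1.6 and 3.0 nm probe wider environments |
| sigma | 0.1 nm | Gaussian smearing, a fraction of the ~0.5 nm contact distance |
| w_switch | 0.05 nm | small enough to approximate a sharp cutoff, wide enough for a C¹ switch |
| include_self | True | the center's own Gaussian contributes (density-of-all-centers convention); configurable |
| radial_basis | "poly" | x^(n−1)(1−x)² family, Gram–Schmidt-orthonormalized with exact rational LDLᵀ; a numerically orthonormalized Gaussian family is available as an alternative |

Only single-species systems are supported. Conventions (self term, cutoff
switch, radial family) are recorded in `SoapParams`; invariance properties
and the normalized-kernel metric are robust to these choices.

## Global fingerprints and the d_SOAP metric

The frame-average fingerprint is the power spectrum of the *averaged
coefficients* c̄ = (1/M) Σᵢ cⁱ — not the mean of per-center spectra; the two
differ whenever environments are heterogeneous, and the test suite checks
the distinction. The simulation average is the plain mean of frame
fingerprints, stored unnormalized; unit normalization happens only inside
the kernel K = q_a·q_b. The induced distance d = √(2−2K) is computed as the
Euclidean distance between unit vectors, which makes the metric axioms
exact (d ≤ √2, triangle inequality) and d(a, a) identically zero.

## Dimensionality reduction

Compared systems are pooled with equal numbers of SOAP vectors per system
(seeded, without replacement) so the PCA basis is shared and unbiased
toward any one system. Three components are kept; on the shipped
four-class synthetic panel they retain ≈ 91–93 % of total variance.
Components carry a deterministic sign (largest-magnitude loading positive)
so projections, cluster labels and trees reproduce across platforms.
Vectors are not rescaled per component before clustering.

## Density-based motif detection

The density of the 3-D projections is estimated on a farthest-point-sampled
grid (greedy max-min, seeded first point, default N_grid = min(1000, N/5)).
At each grid point the KDE bandwidth is the covariance of the ⌈N/4⌉ nearest
dataset points scaled by the squared Silverman factor (4/(N(k+2)))^(2/(k+4)),
ridge-regularized by 1e-8·trace/k. Microclusters come from quick-shift: each
grid point links to its nearest higher-density grid point within
λ = 3 × (median nearest-neighbour grid spacing); link-free points are modes.
Dataset vectors inherit the label of their nearest grid point.

The localization fraction (N/4) and λ = 3 were chosen after direct
experimentation on the synthetic fiber: smaller localization windows make
the bandwidth track the core of a density basin rather than the basin
itself, which fragments tight descriptor clouds into dozens of spurious
modes; λ below ~3 grid spacings leaves KDE sampling noise unmerged. With
the defaults, planted two- and three-component structures are recovered
with adjusted Rand ≥ 0.9 and the fiber motif populations exactly.

Robustness is quantified by a bootstrap: 73 seeded resamples with
replacement are re-clustered, every original vector is re-assigned, and the
stability matrix entry (a,b) averages the overlap
Σ_c min(n_ac/n_a, n_bc/n_b) of the two reference clusters' distributions
over resampled clusters (1 = always merged, 0 = never; a degenerate
single-cluster resample counts as merging all pairs). Microclusters are
condensed by average-linkage on (1 − stability) plus a 1e-3-scaled
mode-distance term: the term is far too small to override any measured
confusion, but orders merges among *never-confused* microclusters by
structural adjacency, so an isolated satellite motif merges into its
nearest neighbour rather than surviving a K-cut arbitrarily. K (the
macrostate count) is a user input; no automatic model selection is done.

## State dynamics

Per-(frame, center) macrostate labels become an M×T matrix; populations are
fractions of all M·T observations; the transition matrix at lag 1 frame
(1 ns at the reference sampling) is the row-normalized count matrix with
self-transitions on the diagonal. Rows never observed as a source are
flagged undefined. Exports include the off-diagonal-only, row-renormalized
interconversion variant, since published diagrams often show only
between-state probabilities. No Markovianity testing or hidden-state
smoothing is performed. With ≥1e5 observations a planted 3×3 chain is
recovered to ±0.02 per entry (tested).

## Synthetic assemblies

The generator produces monomer-center trajectories with planted ground
truth; geometry is Martini-scale (0.5 nm contacts, thermal jitter
0.03 nm), deterministic under its seed.

- **fiber**: ordered monomers on consecutive stack sites along z; the box
  height is exactly n_sites × spacing so the backbone crosses the periodic
  boundary without a seam. A *defect* branches off a single backbone host
  at one stack radius (0.6 nm) — bound to the stack through exactly one
  first-shell contact; hosts are kept two sites apart so defects never see
  each other. *Adsorbed* monomers random-walk on a cylindrical surface
  (1.4 nm) outside the first shell, at stratified z slots so they do not
  dimerize. This side-bound defect geometry was chosen over an in-stack
  vacancy/gap variant because a gap unavoidably hands a one-sided
  environment to the neighbouring backbone monomer, which then clusters
  with the defects and double-counts the planted defect fraction.
- **planar**: periodic triangular lattice; gel = small jitter, liquid =
  larger jitter plus a cumulative 2-D walk; mixed = contiguous blocks.
- **shell**: Fibonacci-lattice sphere, radius from a 4 nm⁻² surface
  density by default, tangential surface diffusion.
- **ball**: uniform-in-volume sphere, radius from a 6 nm⁻³ density by
  default; surface label within a configurable shell thickness (0.4 nm);
  optional planted Markov surface/bulk exchange.

These are geometric emulations: no forces, no barrier crossings, no
chemically specific monomer shapes, no bead substructure (one center per
monomer). Passing tests therefore demonstrate that the analysis stack
recovers planted structure and dynamics under realistic geometry, noise
and sampling — not that any particular chemistry behaves this way; on real
trajectories the motif separation, and hence the reliability of the
population estimates, depends on sampling quality and on rcut matching the
model resolution.

## Problem sizes

Shipped analyses are desk-scale by design: 100–200 monomers, 10–100
frames, 5-system comparison panels; the end-to-end fiber analysis uses
N = 20 000 SOAP vectors and the pooled PCA panel N = 8 000. These sizes
were chosen so the full test battery exercises every stage in minutes on
one CPU; all stages scale linearly in the number of (center, neighbour)
pairs and resamples.

## Known limitations

- Orthorhombic periodic boxes only; rcut must not exceed half the smallest
  periodic box length (no lattice-sum beyond minimum image).
- Single chemical species; no multi-species partial spectra, gradients or
  bispectra.
- Macrostate count K is user-chosen; the stability dendrogram informs but
  does not automate the choice.
- The bootstrap stability matrix measures confusion under resampling, not
  kinetic connectivity; dynamics are reported separately.
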