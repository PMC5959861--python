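# Methods

This note records the models implemented in `cntor`, the assumptions they
make, the defaults they ship with, and the design choices taken where
several defensible options existed. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Conventions

Coordinates in Å, times in ps, energies in kcal mol⁻¹, charges in
elementary charge units. Indices are 0-based internally; 1-based residue
numbers appear only at PDB boundaries. Hydrogens are identified by the
element field, falling back to the atom-name leading letter after digit
stripping, because deposited PDB files vary. Nanotube carbons are modelled
as an uncharged Lennard-Jones pseudo-residue `CNT` with a single atom
type.

## Adsorption metrics

A receptor heavy atom counts as adsorbed when its minimum distance to any
tube atom is **≤ 6 Å, inclusive**. The boundary convention is not fixed by
the "within 6 Å" phrasing; inclusive was chosen and is applied
consistently (`adsorbed_atom_count`, `adsorbed_residues`). Only receptor
heavy atoms are counted; all tube atoms act as potential contacts.
Neighbor searches use a scipy k-d tree; the brute-force all-pairs scan is
retained as the test oracle.

The buried interface is
`contact area = ½[(SAS_rec + SAS_cnt) − SAS_complex]`, with the three SASA
terms evaluated on the isolated receptor, the isolated tube, and their
union, all with the same probe. It is ~0 whenever the minimum
inter-selection distance exceeds 2(r_max + probe), and equals ½·SAS_rec
when the "tube" is a coincident copy of the receptor.

## SASA

Shrake–Rupley with a deterministic golden-spiral point set (default 960
points, probe 1.4 Å). Determinism was preferred over random point sets so
reruns are bit-identical; 960 points give ≤ 0.5 % error on an isolated
sphere and ~1 % against a dense-grid oracle on a dimer (both asserted in
tests). A surface point lying exactly on a neighbor sphere is buried only
by lower-index neighbors; this tie-break makes two fully coincident equal
spheres contribute exactly one sphere's area in total and has no effect
away from exact degeneracy. Per-atom areas sum to the total by
construction. Totals are rotation-invariant only to ~0.1 % because the
point set is fixed in the lab frame.

## Superposition and RMSD

Kabsch superposition via SVD with the determinant correction, so the
rotation is always proper. Fewer than three fit atoms, or a collinear fit
set, raises a degenerate-fit error. RMSD series superpose each frame on a
fit selection and measure on a possibly different selection (whole
backbone fit, pocket backbone measurement, as in the pocket-RMSD
workflow). The reference structure is caller-supplied (crystal/initial
structure in the reference workflow); it is configuration, not a constant.

## DCCM

`C(i,j) = ⟨Δr_i·Δr_j⟩ / [⟨Δr_i²⟩⟨Δr_j²⟩]^{1/2}` over Cα displacement
vectors. By default frames are superposed onto an iteratively refined mean
structure (fit → recompute mean → refit, until the mean moves < 1e-6 Å RMS
or 10 passes) so rigid-body motion is not read as correlation.
`align=None` skips the fit for inputs that are already aligned: the
synthetic correlated-fluctuation generator emits pure fluctuations with no
rigid-body component, and mean-removal over a small fit set would mix
O(1/n_res) translation bias into the correlations, so recovery tests run
with `align=None`. Zero-variance residues raise an error by default and
can be dropped explicitly. Symmetry, unit diagonal, and clipping to
[−1, 1] are enforced against floating-point drift.

## Structure network and pathways

Edge strength `I_ij = n_ij/√(N_i N_j) × 100`, where n_ij counts distinct
side-chain heavy-atom pairs within 4.5 Å. The side chain is everything
except N, CA, C, O; glycine keeps CA as a one-atom pseudo-side-chain so it
does not vanish from the network. Sequence neighbors (|i−j| ≤ 1) are
excluded as covalently connected — standard structure-network practice.
The normalization constants N_i ship as a package CSV of published
per-residue-type values from the protein-structure-network literature,
with a configurable default (100) for unknown types.

Two network views are kept: per-frame networks (edges where I_ij ≥ Imin in
that frame) drive path frequencies, and an occupancy network (edges
present in ≥ occupancy_min of frames, default 0.5, mean strength over
frames where present) gives one summary topology. Defaults Imin = 3.0 and
corr_min = 0.3 are configurable; the originating analysis does not report
its cutoffs, so published pathway counts (e.g. 42/98 paths above 50 %
frequency) are parameter-dependent and are not asserted anywhere.

Pathways are minimal-hop routes through occupancy-network edges whose
endpoints are correlated (|C| ≥ corr_min). Ties break by larger total mean
edge strength, then lexicographic node order, making results
deterministic. A path's frequency is the percentage of frames in which
every edge of the path clears Imin in that frame's network — the
per-frame-conjunction reading of path frequency; it is monotone under
taking subpaths. Node summaries weight source/sink occurrences by path
frequency and order ties by ascending residue index.

## Energy ledger

Single-trajectory scheme: receptor and ligand coordinates are extracted
from complex frames, so internal terms cancel and ΔE_int ≡ 0. Gas-phase
terms are all-pairs sums with k = 332.0637 kcal Å mol⁻¹ e⁻² and
Lorentz–Berthelot combining; no real-space cutoff is applied, because
these are finite rescoring systems (an MD engine's simulation cutoff is a
different concern). ΔG_npsolv = γ·ΔSASA with γ = 0.0072 kcal mol⁻¹ Å⁻².
Standard errors come from 5-block averaging over the analysis window — the
reporting convention chosen since no method is stated for the published
standard errors.

Polar solvation is a pluggable per-frame contract (deterministic, additive
over pairwise terms). The built-in is a generalized-Born-style screening
model with fixed effective radii a_i = radius_i + probe and pair distance
f = √(r² + a_i a_j exp(−r²/4a_i a_j)); total
−½(1/ε_in − 1/ε_out)k Σ q_i q_j/f_ij with ε 1/80. It is a simple,
deterministic stand-in where a finite-difference Poisson–Boltzmann solver
would otherwise be used; quantitative agreement with PB values is **not**
claimed, and published absolute psolv numbers are not treated as targets.
In single-trajectory Δ bookkeeping the Born self terms and within-group
pair terms cancel exactly, so ΔG_psolv reduces to the receptor–ligand
cross terms.

Per-residue decomposition splits each receptor–ligand pair term (Coulomb,
LJ, GB cross) half/half between the two owning residues and assigns each
atom's ΔSASA to its own residue; summed over all residues this reproduces
the total binding energy exactly, which the tests assert to 1e-6.

The ledger identities (gas = ele + vdw, solv = npsolv + psolv,
binding = gas + solv) are checked to a 0.05 kcal mol⁻¹ rounding tolerance.
`EnergyComponents.residuals()` reports how far an externally supplied
table is from satisfying them; inconsistent published rows are flagged,
never silently repaired.

## Pocket volume and hydration

No standard pocket-volume algorithm is mandated by the workflow this
package follows, so a simple deterministic grid method was chosen: grid
points (default 0.5 Å spacing) inside the convex hull of the
pocket-lining atoms, padded outward by 1 Å, that lie ≥ (atom radius +
probe) from every receptor atom, times the voxel volume. It is exact on
analytic fixtures (a 5 Å spherical cavity to within 5 %) and monotone
under adding occluders, but it is one of several defensible definitions
and is **not** guaranteed to reproduce volumes from other cavity tools;
published pocket volumes are therefore not acceptance targets. The
lining-residue list is a required input.

Water analysis uses oxygen positions only (standard occupancy
convention). Each frame is rigid-fit on all receptor atoms onto a
reference, then oxygens are binned on a cubic grid (defaults 0.5 Å
spacing, 150 Å box — the reference analysis conditions; tests use smaller
boxes purely as problem-size choices). Waters outside the grid are
tallied separately so in-box + out-of-box equals n_waters × n_frames
exactly. The Z-axis is taken as the membrane normal of the input frames;
there is no axis auto-detection. Grids export as OpenDX scalar fields.

## Screening statistics

Docking scores are kcal mol⁻¹ with more-negative-is-stronger; all
rankings order ascending scores first, and the manifest records the
orientation. AUC is computed from the Mann–Whitney rank formula with
average ranks, so ties count ½; curve points come from the thresholded
ranking. ROC positives are always caller-supplied — typically a
top-one-third descriptor subset (⌊n/3⌋ = 44 of 132, ties broken by id) —
because no active/decoy labelling of the odor set is defined; no AUC
value is asserted against published numbers for that reason.
Descriptor trends use equal-count bins and Spearman rank correlation
(reported as 0 under total ties). Class selectivity uses two-sided
Wilcoxon rank-sum per class pair with Benjamini–Hochberg adjustment at
α = 0.05 (configurable); singleton classes are excluded with a warning.

## Synthetic generators

Each generator draws from one explicit `numpy.random.default_rng(seed)`
stream and emits a truth block sufficient to compute every downstream
expected value. Defaults follow the study conditions where stated: the
odor generator produces 132 records with MW 42–236, volume 45–267 Å³,
logP 0.7–9.6, and a rise-then-fall volume response turning over at
170 Å³; score noise defaults to 0.5 kcal mol⁻¹, a typical docking-score
scatter chosen once. Molecular weight tracks volume linearly with small
scatter, as in real small-molecule sets. The adsorption generator uses a
coarse 4-helix Cα + pseudo-side-chain bundle over a cylindrical lattice —
countable, not realistic — with exact per-frame contact counts computed
brute-force on the emitted coordinates. The correlated-fluctuation
generator defaults to a two-block correlation (ρ = 0.6 in-block) with
0.3 Å amplitude.

What passing tests show, and do not show: the generators have no
force-field physics, no membrane, no explicit hydrogen networks, and
water boxes are oxygen-only ideal-gas draws; recovery tests therefore
validate the estimators and bookkeeping, not the behaviour of real MD
ensembles.

## Numerical choices and degenerate inputs

Coincident atom pairs (r < 1e-6 Å) in energy sums raise a singularity
error rather than returning infinities. Collinear or undersized fit sets
raise degenerate-fit errors. Empty selections, empty frame windows,
non-PSD correlation models, overlapping schedule ranges, and negative
densities all raise typed package errors; the CLI maps them to exit
status 3 (2 for usage errors). Problem sizes in the tests (≤ 5000 frames,
≤ 1000 atoms) were chosen so the full suite runs in well under a minute
on one core.

## Known limitations

- The GB-style polar model shares only the dielectric bookkeeping with a
  PB solver; its absolute values are not comparable to PB results.
- Pocket volumes are method-dependent; comparisons across tools require
  the same cavity definition.
- SASA rotation invariance is approximate (fixed lab-frame point set).
- The PSN normalization table covers the 20 standard amino acids;
  non-standard residues use the configurable default.
- No binary trajectory formats (DCD/XTC) are read; multi-model PDB and
  XYZ cover the supported interchange.
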