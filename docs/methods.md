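# Methods

This note documents the models implemented in `groovedyn`, the parameter
choices that matter, what the synthetic-data generators do and do not
emulate, and the numerical decisions taken where the design was open.

## Structures, selections, and atom properties

Coordinates are in Å throughout; residue numbering is taken verbatim from
the input file. PDB parsing and writing are delegated to biotite behind
`structio`. Alternate locations are resolved on read to one conformer per
atom: the highest occupancy wins, with ties broken toward the
alphabetically first alt-loc identifier, since all downstream analyses
assume a single conformer. Hydrogens are retained on read; every
heavy-atom analysis deselects them explicitly via the `heavy` selection
class. For asymmetric units with several copies of a complex,
`first_copy` keeps the first chain carrying each distinct residue-name
sequence.

Masses are standard atomic weights and vdW radii the Bondi set, both
keyed by element so lookups are total over nonstandard residues
(benzothienylalanine, 5-fluorotryptophan) whose atoms are ordinary
C/N/O/S/F; unknown elements fall back to 1.70 Å. A reader encountering an
unknown residue name treats it as a generic heavy-atom residue.

The selection language is deliberately small (chain / resid / resname /
name / element terms, `heavy`, `backbone`, `sidechain`, `calpha`,
boolean combinators). `sidechain` means non-backbone *heavy* atoms.
Resolution is ordered by topology order and deterministic; an empty
result is an error rather than an empty list, because silent empty
selections are the classic trajectory-analysis footgun.

## Geometry

Superposition is an unweighted least-squares (Kabsch) fit, computed via
`scipy`'s `Rotation.align_vectors`; for groove analyses the fit selection
is the Cα atoms of the MHC platform, residues 1–180. RMSD over a target
selection is computed *without* refitting after a single common-reference
superposition. Common-atom pairing matches atoms by (residue position
within the selection, atom name) and drops unmatched atoms, which handles
position-2 anchor substitutions (His vs Leu) and partially resolved side
chains.

Mass-weighted RMSF is taken about the trajectory-mean structure (not
frame 1): per residue, `sqrt( Σ_i m_i ⟨|r_i − ⟨r_i⟩|²⟩ / Σ_i m_i )`.
Mass weighting applies only inside the fluctuation average; the
superposition fit stays unweighted. The estimate is invariant to frame
order.

Dihedrals use the IUPAC sign convention (positive clockwise looking from
atom 2 to atom 3) in (−180°, 180°]. Contacts are pair distances strictly
below a 4.0 Å cutoff. vdW overlap per atom pair is
`max(0, r_a + r_b − d)`; the per-frame value is the mean over positively
overlapping pairs, zero when none overlap. Hydrogen bonds use a
heavy-atom distance ≤ 3.5 Å and a D–H···A angle ≥ 135°; these defaults
are declared, configurable values — common geometric criteria, not
inferred from any particular trajectory tool.

## Conformational metrics

The per-residue D-score between two conformations is
`D = 2(1 − cos Δϕ) + 2(1 − cos Δψ)` with differences taken on the
circle. This functional form is adopted because it reproduces the defined
endpoints: 0 for identical torsions, 8 when both differ by 180°.
Residues missing ϕ or ψ (chain termini) are reported as missing (NaN),
never as zero.

Ramachandran strain counts frame–residue (ϕ, ψ) pairs outside the union
of allowed and generously allowed regions. The region map ships as a
versioned boolean lattice at the native 4° step of its source: the
MDAnalysis `Rama_ref` reference torsion histogram, whose contours at 90 %
and 99 % of reference measurements define allowed and generously allowed;
the shipped map is the 99 % union (histogram count ≥ 1). Tests probe
points deep inside/outside regions, never near boundaries.

2D-RMSD matrices superpose every frame (and any appended reference
structure) once onto a single common reference over the fit selection and
then take plain RMSD over the target selection. The single-fit reading
guarantees the matrix is a true metric (symmetric, zero diagonal,
triangle inequality), which per-pair refitting would not.

Cluster analysis runs scikit-learn agglomerative clustering directly on
the precomputed distance matrix (average linkage by default). The
Calinski–Harabasz index needs coordinates, so it is evaluated on a
classical (Torgerson) MDS embedding of the matrix, retaining components
that cover ≥ 95 % of squared-distance variance, capped at 10 dimensions.
The selected k maximizes the index over the candidate range with ties
broken toward smaller k; labels are renumbered by first appearance so the
partition is invariant to input relabeling. Cluster averages are
arithmetic means of superposed coordinates with population fractions
`n_c / n`.

The bound-vs-free survey superposes each bound structure onto its free
partner over the groove Cα atoms and records Cα and all-common-atom
peptide RMSDs, stripping atoms absent from either side. Replicate groups
(several structures of the same peptide) are collapsed to the single
comparison with the largest Cα-or-all-atom RMSD. Records are emitted in
sorted pair-id order, making the survey order-invariant.

LOWESS smoothing (statsmodels, default span 0.1) is provided strictly as
a presentation utility and is never applied before quantitative analysis.

## Volumetrics

Occupancy grids count atom *centers*: a voxel is occupied in a frame when
at least one selected atom center falls in it, and its occupancy is the
fraction of such frames. The default spacing is 0.1 Å with the grid
origin snapped to a multiple of the spacing for reproducibility. The
occupied volume applies a minimum sampling fraction (default 10 %) and
equals voxel count × spacing³ exactly when smoothing is off; optional
Gaussian smoothing (σ default 2× spacing) mimics visualization pipelines
and is excluded from quantitative use. A vdW-smeared density alternative
was considered and deliberately not implemented: center counting is the
simplest reading of grid-space occupancy and is exactly testable.

SASA is Shrake–Rupley quadrature: deterministic golden-spiral points on
each atom's probe-inflated sphere (probe 1.4 Å, default 960 points/atom),
a point being accessible when outside every other inflated sphere. At 960
points the total SASA of a small residue is rotation-stable to ~1 % and
at 2000 points to ~0.3 %.

vdW molecular volume is a grid fill of the union of Bondi spheres. The
nominal spacing (default 0.2 Å) is refined 2× internally (midpoint rule
at 0.1 Å) to keep single-sphere discretization bias below 0.5 %. The
idealized tryptophan fixture (ideal component-library geometry, heavy
atoms including OXT) yields ≈ 159 Å³.

Cavity detection rasterizes probe-inflated atoms (probe 1.4 Å, default
grid 0.4 Å) over the region of interest plus margin, then flood-fills
empty voxels from the grid boundary (6-connectivity): empty voxels
unreachable from outside, restricted to the region, are cavity. This is
an original implementation; third-party cavity tools differ in detail and
their absolute volumes are treated as order-of-magnitude anchors only,
since cavity volumes are sensitive to atomic positions.

## Biophysical fits

All fitters are least squares (`scipy.optimize.curve_fit`) and are exact
to numerical tolerance on noiseless inputs of their own model class.

* Dissociation: `A·e^(−k t) + c`, or biphasic
  `A₁e^(−k₁t) + A₂e^(−k₂t) + c` with rates reported fastest-first.
  Non-decaying signals are fitted but flagged.
* Steady-state 1:1 binding: `R = R_max·c/(K_D + c)`; a top concentration
  below K_D/3 triggers an extrapolation warning.
* `k_on = k_off / K_D` (s⁻¹ / M → M⁻¹ s⁻¹).
* pKa-shift energetics: `ΔΔG° = −2.303·R·T·(pK_a,bound − pK_a,free)` with
  R = 1.987 cal K⁻¹ mol⁻¹, default T = 298.15 K, reported in kcal/mol;
  positive means the bound state is destabilized (protonation suppressed
  on burial).
* Thermal melts: the first-derivative curve is fitted with a sum of two
  Gaussians; Tm₁ is the dominant-amplitude center. Single-transition data
  converge with a negligible second amplitude and are flagged as such.
* Lorentzian mixtures: area-parameterized Lorentzians, optionally over a
  linear baseline (the baseline model is a declared choice). Multi-start
  (default 16) initialization is seeded from prominence-ranked peak
  picking with seeded random perturbations; restarts stop early once the
  residual reaches the apparent noise floor. Components are returned
  sorted by center with area fractions normalized to 1.
* CEST: peak intensities in each saturated spectrum are re-estimated by
  non-negative linear fitting of the *fixed* reference line shapes, so
  overlapping peaks are treated consistently across the series. The
  exchange graph draws an edge when irradiating one peak reduces another
  by ≥ 25 % (a declared default; "significant reduction" is qualitative
  in practice). Irradiation offsets within 0.5 ppm of a non-target peak
  trigger a direct-saturation contamination warning. EXSY cross-peak
  patterns are summarized with the same present/absent exchange-graph
  abstraction; simulating 2D spectra is out of scope.

## Weighted-ensemble engine

The resampler is the classic split-highest / merge-lowest scheme: per
occupied bin, merge the two lowest-weight walkers (survivor chosen with
probability proportional to weight, inheriting the summed weight) until
the bin is at the cap, then split the highest-weight walker into two
children of equal weight until the bin holds exactly `max_per_bin` (8)
walkers. Weight is conserved exactly (≤ 1e-12 drift over 10³
iterations). The default progress-coordinate layout divides [0, 2), [2,
6), [6, 11) Å evenly into 7, 40 and 24 bins plus one open bin for ≥ 11 Å
(72 bins total); the per-segment step sizes usually quoted with these
counts (0.3/0.1/0.2 Å) are arithmetically inconsistent with the segment
ranges, so the bin counts and segment endpoints are what is honored,
giving even steps of 2/7, 0.1 and 5/24 Å. A transition is successful when
the progress coordinate drops below 1 Å (configurable; the desk-scale
demonstrations use a tighter toy threshold).

The toy propagator is overdamped Brownian dynamics with unit mobility,
`x ← x − ∇U dt + sqrt(2 kT dt)·ξ`, on double-well / harmonic / flat 1D
potentials with optional flat-welled parabolic wall restraints. The toy
progress coordinate is `|x − x_target|`, an RMSD analog; a callback
adapter accepts structural RMSD for real data. Recycling (restart at the
source on success, keeping the weight) is optional and off by default;
with recycling on, the mean recycled flux estimates the steady-state
transition rate. On a 6 kT double well, 2000 iterations of 10 × 10⁻³
time-unit steps give a flux within a factor of ~1.5 of a direct
mean-first-passage estimate; these problem sizes were chosen as the
smallest that sit comfortably inside that factor-of-two band.

## Synthetic data: what it does and does not emulate

Generators are deterministic by seed and always return their ground
truth. The toy groove/peptide complex is built from ideal internal
coordinates (NeRF chain construction; side chains grafted from ideal
residue templates), giving chemically plausible bonded geometry
(backbone bond lengths 1.2–1.6 Å, no non-bonded vdW overlap > 0.4 Å) but
no force field and no biological fold: it exists to exercise selections,
superposition and volumetrics, including sealed/open variants for cavity
flood-fill. Trajectories displace residues rigidly by isotropic Gaussians
(per-axis σ/√3 so the planted per-residue RMSF is σ) and can plant
two-state side-chain χ₁ switching at prescribed occupancies — they have
no inertia, no correlated collective modes, no solvent. Cluster
ensembles plant k conformer centers at pairwise RMSD ≥ the requested
separation with Gaussian scatter (expected RMSD = spread) about each.
Traces and spectra are drawn from exactly the model classes the fitters
assume, plus i.i.d. Gaussian noise; SPR drift/bulk artifacts,
spectrometer baselines and crystallographic noise are not modeled.
Passing tests therefore demonstrate estimator correctness and
calibration under the stated noise models, not robustness to real-data
artifacts.

Default generator parameters follow the study conditions they emulate:
off-rate 0.039 s⁻¹ with 1 % noise over two half-lives (200 points), K_D
62 µM isotherms, three-state ¹⁹F spectra at −126.90/−125.18/−123.09 ppm
with 8/77/15 % areas and 0.4 ppm linewidths (appropriate to a ~44 kDa
complex) at SNR 20, and eight-conformer ensembles at 10× separation over
spread.

## Known limitations

* The cavity and occupancy grids are axis-aligned; volumes carry
  O(spacing) surface discretization error (the tests bound it).
* The Lorentzian deconvolution assumes a known component count; model
  selection across counts is the caller's task.
* The WE engine is 1D/toy-scale by design; it demonstrates the
  resampling scheme and bookkeeping, not molecular sampling.
* The Ramachandran map is residue-type-agnostic (no Gly/Pro-specific
  regions).
* The bound-vs-free survey operates on user-supplied structure pairs; it
  does not query the PDB.
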