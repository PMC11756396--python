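# groovedyn

Analysis toolkit for conformational dynamics of peptides bound in class I
MHC grooves — and for the biophysical experiments used to probe them.

Class I MHC proteins (e.g. HLA-A*03:01) present short peptides to T cell
receptors (TCRs). Whether a TCR can engage often hinges on motions of the
bound peptide that crystal structures do not show: a bulky side chain may
have to flip between a groove-buried and a TCR-facing state, anchored or
released by seemingly distant substitutions. `groovedyn` packages the
quantitative layer needed to study such *dynamic allostery* from
simulation output and from solution measurements:

* **structio** — PDB structures/trajectories, atom selections, a single
  source of masses and Bondi vdW radii.
* **geometry** — Kabsch superposition, common-atom RMSD, mass-weighted
  RMSF, IUPAC dihedrals, contacts (< 4 Å), vdW overlap, center-of-mass
  distances, hydrogen bonds.
* **confmetrics** — backbone-torsion D-score
  `D = 2(1 − cos Δϕ) + 2(1 − cos Δψ)` ∈ [0, 8]; Ramachandran strain
  counting against allowed + generously-allowed regions; 2D-RMSD
  matrices; agglomerative clustering with Calinski–Harabasz selection of
  the cluster count; bound-vs-free crystallographic surveys.
* **volumes** — voxel occupancy grids (0.1 Å spacing, 10 % sampling
  threshold), Shrake–Rupley SASA (1.4 Å probe), grid-fill vdW molecular
  volumes, flood-fill cavity detection.
* **biophys** — SPR 1:1 steady-state (`R = R_max·c/(K_D + c)`) and
  dissociation (`R = A·e^{−k_off t}`) fits, `k_on = k_off/K_D`, the
  pKa-shift energetics `ΔΔG° = −2.303·R·T·(pK_a,bound − pK_a,free)`,
  bi-Gaussian melt fits, Lorentzian line-shape deconvolution of 1D ¹⁹F
  spectra, and CEST saturation-transfer exchange graphs.
* **we_engine** — a desk-scale weighted-ensemble rare-event engine
  (72-bin RMSD progress coordinate, ≤ 8 walkers/bin, exact weight
  conservation) with a Brownian toy propagator.
* **synthetic_data** — generators for every input class with embedded
  ground truth, so the whole stack is testable without downloads.

## Worked example

```python
import numpy as np
from groovedyn import biophys, confmetrics, geometry, synthetic_data

# kinetics of a slow, conformational-change-limited TCR association
kon = biophys.kon_from_koff_kd(koff=0.039, KD=62e-6)
print(f"kon = {kon:.0f} M^-1 s^-1")           # kon = 629 M^-1 s^-1

# energetic cost of burying a protonatable histidine in a hydrophobic
# pocket
ddg = biophys.ddg_from_pka(pka_bound=4.9, pka_free=6.1)
print(f"ddG = {ddg:.2f} kcal/mol")            # ddG = 1.64 kcal/mol

# per-residue fluctuations of a peptide with a mobile central bulge
base = synthetic_data.gen_toy_complex(seed=1)
sigma = [0.4, 0.3, 0.5, 0.9, 1.0, 1.1, 0.8, 0.5, 0.4]   # planted RMSF, Å
traj = synthetic_data.gen_trajectory(base, sigma, n_frames=2000, seed=2)
labels, rmsf = geometry.mw_rmsf(traj, spec="chain C and heavy")
print(np.round(rmsf, 2))
# [0.4  0.3  0.49 0.9  1.01 1.1  0.79 0.49 0.4 ]

# three-state 19F spectrum: deconvolved state populations
spec, truth = synthetic_data.gen_spectrum(seed=3, snr=20)
for c in biophys.fit_lorentzian_mixture(spec, 3, seed=3):
    print(f"{c.center:8.2f} ppm  {100 * c.area_fraction:5.1f} %")
#  -126.91 ppm    8.6 %
#  -125.18 ppm   76.0 %
#  -123.09 ppm   15.4 %
```

The fluctuation profile recovers the planted per-residue mobility (rigid
termini, mobile center), and the line-shape fit recovers the planted
8/77/15 % three-state population split from a noisy spectrum to about a
percentage point.

A command-line interface mirrors the library
(`groovedyn ddg|kon|rmsf|contacts|fit-koff|fit-nmr|sasa|vdwvol|we-run|synth|pipeline …`);
`groovedyn pipeline --seed 1 --out out/` runs a synthetic end-to-end
recipe and writes a reproducibility manifest.

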