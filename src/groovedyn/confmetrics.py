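"""Conformational comparison and ensemble structure.

Covers the backbone-torsion D-score, Ramachandran strain counting, pairwise
(2D) RMSD matrices, agglomerative clustering with Calinski-Harabasz model
selection, per-cluster average structures, and the bound-vs-free survey of
crystallographic peptide pairs.

The D-score for one residue compares its (phi, psi) pair between two
conformations::

    D = 2 (1 - cos d_phi) + 2 (1 - cos d_psi)

which is 0 for identical angles and 8 when both angles differ by 180
degrees; differences are taken on the circle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.linalg import eigh
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import calinski_harabasz_score
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .geometry import (PairingError, common_atom_pairs, rmsd, superpose)
from .structio import Structure, Trajectory, select

__all__ = [
    "dscore",
    "dscore_profile",
    "RamaRegionMap",
    "rama_strain_count",
    "RMSDMatrix",
    "pairwise_rmsd",
    "ClusterResult",
    "cluster_select_k",
    "cluster_average",
    "SurveyRecord",
    "bound_free_survey",
    "smooth_lowess",
]


# ---------------------------------------------------------------------------
# D-score
# ---------------------------------------------------------------------------

def dscore(phi_a, psi_a, phi_b, psi_b):
    """Per-residue backbone-torsion dissimilarity in [0, 8] (degrees in)."""
    dphi = np.radians(np.asarray(phi_a, dtype=float)
                      - np.asarray(phi_b, dtype=float))
    dpsi = np.radians(np.asarray(psi_a, dtype=float)
                      - np.asarray(psi_b, dtype=float))
    return 2.0 * (1.0 - np.cos(dphi)) + 2.0 * (1.0 - np.cos(dpsi))


def dscore_profile(angles_a, angles_b) -> np.ndarray:
    """D-score per residue for two equal-length (phi, psi) profiles.

    Each profile is a sequence of (phi, psi) pairs in degrees; entries where
    either angle is None/NaN (terminal residues) yield NaN, marking the
    residue as missing rather than scoring it 0.
    """
    a = np.array([[np.nan if v is None else v for v in p] for p in angles_a],
                 dtype=float)
    b = np.array([[np.nan if v is None else v for v in p] for p in angles_b],
                 dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles must have equal residue counts")
    out = dscore(a[:, 0], a[:, 1], b[:, 0], b[:, 1])
    out[np.isnan(a).any(axis=1) | np.isnan(b).any(axis=1)] = np.nan
    return out


# ---------------------------------------------------------------------------
# Ramachandran strain
# ---------------------------------------------------------------------------

@dataclass
class RamaRegionMap:
    """Boolean (phi, psi) lattice marking allowed + generously allowed
    backbone torsions.

    The bundled map is a 4-degree lattice derived from a published
    reference torsion histogram (the 99% "generously allowed" union); see
    the packaged data file header for provenance.
    """

    grid: np.ndarray  # (n_psi, n_phi) bool; cell 0 covers [-180, -180+step)
    step: float

    def __post_init__(self):
        if 360.0 % self.step:
            raise ValueError("grid step must divide 360")
        n = int(360.0 // self.step)
        if self.grid.shape != (n, n):
            raise ValueError("grid does not cover the full torus")

    @classmethod
    def bundled(cls) -> "RamaRegionMap":
        text = (resources.files("groovedyn") / "data"
                / "rama_allowed_4deg.txt").read_text()
        rows, step = [], None
        for line in text.splitlines():
            if line.startswith("#") or not line.strip():
                continue
            if line.startswith("step"):
                step = float(line.split()[1])
                continue
            rows.append([c == "1" for c in line.strip()])
        return cls(grid=np.array(rows, dtype=bool), step=step)

    def allowed(self, phi, psi):
        """Whether (phi, psi) degrees fall in an allowed cell
        (vectorized)."""
        phi = np.mod(np.asarray(phi, dtype=float) + 180.0, 360.0)
        psi = np.mod(np.asarray(psi, dtype=float) + 180.0, 360.0)
        j = np.minimum((phi // self.step).astype(int), self.grid.shape[1] - 1)
        i = np.minimum((psi // self.step).astype(int), self.grid.shape[0] - 1)
        return self.grid[i, j]


def rama_strain_count(phi_values, psi_values,
                      region_map: RamaRegionMap | None = None):
    """Count frame-residue torsion pairs outside the allowed regions.

    ``phi_values``/``psi_values`` are (n_frames, n_residues) arrays in
    degrees for the non-terminal residues under study. Returns
    ``(per_residue_counts, total)``.
    """
    region_map = region_map or RamaRegionMap.bundled()
    phi = np.asarray(phi_values, dtype=float)
    psi = np.asarray(psi_values, dtype=float)
    if phi.shape != psi.shape:
        raise ValueError("phi and psi arrays must share a shape")
    ok = region_map.allowed(phi, psi)
    per_residue = np.sum(~ok, axis=0).astype(int)
    return per_residue, int(per_residue.sum())


# ---------------------------------------------------------------------------
# Pairwise RMSD matrices
# ---------------------------------------------------------------------------

@dataclass
class RMSDMatrix:
    values: np.ndarray  # (n, n) A
    labels: list  # provenance per row: (ensemble name, frame index)

    def __post_init__(self):
        v = self.values
        if not np.allclose(v, v.T, atol=1e-9) or np.any(np.diag(v) > 1e-9):
            raise ValueError("matrix must be symmetric with zero diagonal")


def pairwise_rmsd(ensembles, fit_spec, target_spec,
                  references=()) -> RMSDMatrix:
    """2D-RMSD over one or more ensembles plus optional reference
    structures.

    Every frame (and reference) is first superposed onto a single common
    reference — the first frame of the first ensemble — over ``fit_spec``;
    matrix entries are then plain RMSD over ``target_spec`` with no per-pair
    refitting, which makes the result a true metric. ``ensembles`` is a
    mapping name -> Trajectory; references a sequence of (name, Structure).
    """
    if isinstance(ensembles, Trajectory):
        ensembles = {"ensemble": ensembles}
    items = []  # (label, coords over target selection, after fitting)
    ref_traj = next(iter(ensembles.values()))
    ref_fit_idx = select(ref_traj.topology, fit_spec)
    ref_coord = ref_traj.frames[0]
    for name, traj in ensembles.items():
        fit_idx = select(traj.topology, fit_spec)
        tgt_idx = select(traj.topology, target_spec)
        for f in range(traj.n_frames):
            t = superpose(traj.frames[f][fit_idx], ref_coord[ref_fit_idx])
            items.append(((name, f), t.apply(traj.frames[f][tgt_idx])))
    for name, structure in references:
        fit_idx = select(structure, fit_spec)
        tgt_idx = select(structure, target_spec)
        t = superpose(structure.coord[fit_idx], ref_coord[ref_fit_idx])
        items.append(((name, None), t.apply(structure.coord[tgt_idx])))
    n = len(items)
    shapes = {c.shape for _, c in items}
    if len(shapes) != 1:
        raise PairingError("target selections differ in atom count across "
                           "ensembles/references")
    coords = np.stack([c for _, c in items])
    flat = coords.reshape(n, -1)
    sq = np.sum(flat ** 2, axis=1)
    n_atoms = coords.shape[1]
    g = flat @ flat.T
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2 * g, 0.0) / n_atoms
    values = np.sqrt(d2)
    np.fill_diagonal(values, 0.0)
    values = 0.5 * (values + values.T)
    return RMSDMatrix(values=values, labels=[lab for lab, _ in items])


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    labels: np.ndarray  # in [1, selected_k]
    selected_k: int
    scores: dict  # k -> Calinski-Harabasz index
    linkage: str
    populations: np.ndarray  # fraction per cluster, sums to 1
    averages: np.ndarray | None = None  # (k, n_atoms, 3) if computed


def _classical_mds(dist: np.ndarray, var_target: float = 0.95,
                   max_dim: int = 10) -> np.ndarray:
    """Classical (Torgerson) MDS embedding of a distance matrix."""
    n = dist.shape[0]
    d2 = dist ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    w, V = eigh(B)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    pos = np.clip(w, 0, None)
    total = pos.sum()
    ndim = 1
    if total > 0:
        cum = np.cumsum(pos) / total
        ndim = int(np.searchsorted(cum, var_target) + 1)
    ndim = min(max(ndim, 1), max_dim, n - 1)
    return V[:, :ndim] * np.sqrt(pos[:ndim])


def cluster_select_k(matrix: RMSDMatrix | np.ndarray, k_range=range(2, 11),
                     linkage: str = "average") -> ClusterResult:
    """Agglomerative clustering with Calinski-Harabasz selection of k.

    Clustering runs directly on the precomputed distance matrix; the
    Calinski-Harabasz index needs coordinates, so it is evaluated on a
    classical-MDS embedding of the matrix (components covering >= 95% of
    squared-distance variance, capped at 10 dimensions). Ties in the index
    break toward the smaller k. Labels are renumbered 1..k by first
    appearance, making the result invariant to input relabeling.
    """
    dist = matrix.values if isinstance(matrix, RMSDMatrix) else \
        np.asarray(matrix, dtype=float)
    n = dist.shape[0]
    ks = sorted(set(int(k) for k in k_range))
    if not ks or ks[0] < 2 or ks[-1] > n:
        raise ValueError(f"k_range must lie in [2, {n}]")
    emb = _classical_mds(dist)
    scores, labelings = {}, {}
    for k in ks:
        model = AgglomerativeClustering(n_clusters=k, metric="precomputed",
                                        linkage=linkage)
        raw = model.fit_predict(dist)
        labelings[k] = raw
        scores[k] = float(calinski_harabasz_score(emb, raw))
    best_k = max(ks, key=lambda k: (scores[k], -k))
    raw = labelings[best_k]
    # renumber by first appearance -> labels in [1, k], deterministic
    remap, labels = {}, np.empty(n, dtype=int)
    for i, r in enumerate(raw):
        if r not in remap:
            remap[r] = len(remap) + 1
        labels[i] = remap[r]
    populations = np.bincount(labels, minlength=best_k + 1)[1:] / n
    return ClusterResult(labels=labels, selected_k=best_k, scores=scores,
                         linkage=linkage, populations=populations)


def cluster_average(ensemble, labels):
    """Per-cluster arithmetic mean coordinates and population fractions.

    ``ensemble`` is a Trajectory (frames assumed superposed) or an
    (n_frames, n_atoms, 3) array; labels are 1-based cluster ids, one per
    frame. Returns ``(averages, fractions)``.
    """
    frames = ensemble.frames if isinstance(ensemble, Trajectory) \
        else np.asarray(ensemble, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(labels) != len(frames):
        raise ValueError("one label per frame required")
    k = labels.max()
    counts = np.bincount(labels, minlength=k + 1)[1:]
    if np.any(counts == 0):
        missing = [c + 1 for c in np.nonzero(counts == 0)[0]]
        raise ValueError(f"empty cluster label(s): {missing}")
    averages = np.stack([frames[labels == c].mean(axis=0)
                         for c in range(1, k + 1)])
    return averages, counts / len(frames)


# ---------------------------------------------------------------------------
# Bound-vs-free crystallographic survey
# ---------------------------------------------------------------------------

@dataclass
class SurveyRecord:
    pair_id: str
    peptide_length: int
    ca_rmsd: float
    all_atom_rmsd: float
    atoms_stripped: int
    replicate_rule_applied: bool = False


def bound_free_survey(pairs) -> list:
    """Survey of free-vs-bound peptide conformational change.

    Each entry of ``pairs`` is a dict with keys ``pair_id``, ``group``
    (replicate-group identifier; entries sharing a group describe the same
    peptide), ``free``/``bound`` (Structure), ``peptide_spec`` and
    ``fit_spec``. Per pair the bound structure is superposed onto the free
    one over ``fit_spec`` (the MHC groove Calpha atoms), then Calpha and
    all-common-atom RMSDs are computed over the peptide selection, pairing
    by residue position and atom name with unmatched atoms stripped.

    Replicate groups are collapsed to the single comparison with the
    largest Calpha-or-all-atom RMSD. Output order follows sorted pair ids,
    so results are invariant to input order.
    """
    records = {}
    for p in sorted(pairs, key=lambda p: str(p["pair_id"])):
        free, bound = p["free"], p["bound"]
        fit_spec, pep_spec = p["fit_spec"], p["peptide_spec"]
        t = superpose(bound, free, fit_spec)
        bound_fit = bound.with_coord(t.apply(bound.coord))
        ia_all = select(free, pep_spec)
        ib_all = select(bound_fit, pep_spec)
        _check_same_sequence(free, bound, ia_all, ib_all)
        ia, ib = common_atom_pairs(free, bound_fit, ia_all, ib_all)
        stripped = (len(ia_all) - len(ia)) + (len(ib_all) - len(ib))
        all_atom = rmsd(free.coord[ia], bound_fit.coord[ib])
        ca_mask = free.atom_name[ia] == "CA"
        if not ca_mask.any():
            raise PairingError("no Calpha atoms in the peptide pairing")
        ca = rmsd(free.coord[ia[ca_mask]], bound_fit.coord[ib[ca_mask]])
        n_res = len(set(zip(free.chain_id[ia], free.res_id[ia])))
        rec = SurveyRecord(pair_id=str(p["pair_id"]), peptide_length=n_res,
                           ca_rmsd=ca, all_atom_rmsd=all_atom,
                           atoms_stripped=int(stripped))
        group = p.get("group", p["pair_id"])
        prev = records.get(group)
        if prev is None:
            records[group] = rec
        else:
            rec.replicate_rule_applied = True
            prev.replicate_rule_applied = True
            if max(rec.ca_rmsd, rec.all_atom_rmsd) > \
                    max(prev.ca_rmsd, prev.all_atom_rmsd):
                records[group] = rec
    return [records[g] for g in sorted(records, key=str)]


def _check_same_sequence(a: Structure, b: Structure, ia, ib):
    def seq(s, idx):
        out = {}
        for i in idx:
            out.setdefault((s.chain_id[i], s.res_id[i], s.ins_code[i]),
                           s.res_name[i])
        return list(out.values())
    sa, sb = seq(a, ia), seq(b, ib)
    if len(sa) != len(sb):
        raise PairingError(
            f"peptide residue counts differ: {len(sa)} vs {len(sb)}"
        )
    bad = [i + 1 for i, (ra, rb) in enumerate(zip(sa, sb)) if ra != rb]
    if bad:
        raise PairingError(f"peptide sequences differ at position(s) {bad}")


def smooth_lowess(x, y, span: float = 0.1) -> np.ndarray:
    """LOWESS presentation smoothing (never applied before quantitative
    analysis); span is the fraction of points in each local fit."""
    out = _sm_lowess(np.asarray(y, float), np.asarray(x, float), frac=span,
                     return_sorted=False)
    return out
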