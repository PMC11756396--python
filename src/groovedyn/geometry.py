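"""Per-frame geometric primitives: superposition, RMSD/RMSF, dihedrals,
distances, contacts, steric overlap and hydrogen bonds.

Conventions used throughout:

* superposition is an unweighted least-squares (Kabsch) fit over the
  supplied fit selection — for groove analyses the Calpha atoms of the MHC
  platform (residues 1-180);
* RMSF mass-weighting applies only inside the fluctuation average, never to
  the fit;
* dihedrals follow the IUPAC sign convention (clockwise positive looking
  from atom 2 to atom 3) and live in (-180, 180] degrees;
* contacts are interatomic distances strictly below the cutoff (default
  4.0 A); vdW overlap is the positive part of r_a + r_b - d.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .structio import SelectionSpec, Structure, Trajectory, select

__all__ = [
    "Transform",
    "DihedralSeries",
    "PairMetricSeries",
    "superpose",
    "apply_transform",
    "rmsd",
    "common_atom_pairs",
    "mw_rmsf",
    "dihedral",
    "dihedral_series",
    "contacts",
    "vdw_overlap",
    "com_distance",
    "hbonds",
]


class PairingError(ValueError):
    """Atom sets could not be paired for comparison."""


@dataclass(frozen=True)
class Transform:
    """Rigid-body transform ``y = x @ rotation.T + translation``."""

    rotation: np.ndarray  # (3, 3), proper rotation
    translation: np.ndarray  # (3,)
    fit_rmsd: float  # A, over the fit selection

    def apply(self, coord: np.ndarray) -> np.ndarray:
        return np.asarray(coord) @ self.rotation.T + self.translation


@dataclass
class DihedralSeries:
    """Per-frame dihedral values (degrees) for a list of labelled angles."""

    labels: list  # (residue_id, angle_name) or custom tuples
    values: np.ndarray  # (n_frames, n_angles), degrees in (-180, 180]


@dataclass
class PairMetricSeries:
    """A per-frame scalar series (distance, count or overlap)."""

    metric: str
    values: np.ndarray  # (n_frames,)
    selections: tuple = ()
    detail: object = None


def _coords(obj, indices=None) -> np.ndarray:
    """Normalize Structure | Trajectory | ndarray to (n_frames, n, 3)."""
    if isinstance(obj, Trajectory):
        xyz = obj.frames
    elif isinstance(obj, Structure):
        xyz = obj.coord[None]
    else:
        xyz = np.asarray(obj, dtype=float)
        if xyz.ndim == 2:
            xyz = xyz[None]
    if indices is not None:
        xyz = xyz[:, indices, :]
    return xyz


def _resolve(obj, spec) -> np.ndarray:
    topo = obj.topology if isinstance(obj, Trajectory) else obj
    return select(topo, spec)


# ---------------------------------------------------------------------------
# Superposition and RMSD
# ---------------------------------------------------------------------------

def superpose(mobile, reference, fit_spec: SelectionSpec | str | None = None,
              mobile_indices=None, reference_indices=None) -> Transform:
    """Least-squares rigid-body fit of ``mobile`` onto ``reference``.

    The fit selection must resolve to the same atom count (>= 3,
    non-degenerate) on both sides. Returns the optimal Transform; apply it
    with :meth:`Transform.apply` to move full coordinate sets.
    """
    if fit_spec is not None:
        mobile_indices = _resolve(mobile, fit_spec)
        reference_indices = _resolve(reference, fit_spec)
    x = _coords(mobile, mobile_indices)[0]
    y = _coords(reference, reference_indices)[0]
    if x.shape != y.shape:
        raise PairingError(
            f"fit selections resolve to {len(x)} vs {len(y)} atoms"
        )
    if len(x) < 3:
        raise PairingError("fit needs at least 3 atom pairs")
    xc, yc = x.mean(axis=0), y.mean(axis=0)
    x0, y0 = x - xc, y - yc
    if np.linalg.matrix_rank(x0, tol=1e-9) < 2:
        raise np.linalg.LinAlgError("degenerate (collinear) fit selection")
    rot, rssd = Rotation.align_vectors(y0, x0)
    R = rot.as_matrix()
    fitted = x0 @ R.T + yc
    fit_rmsd = float(np.sqrt(np.mean(np.sum((fitted - y) ** 2, axis=1))))
    translation = yc - R @ xc
    return Transform(rotation=R, translation=translation, fit_rmsd=fit_rmsd)


def apply_transform(transform: Transform, obj):
    """Apply a Transform to a Structure, Trajectory or coordinate array."""
    if isinstance(obj, Trajectory):
        frames = obj.frames @ transform.rotation.T + transform.translation
        return Trajectory(obj.topology, frames, obj.frame_interval)
    if isinstance(obj, Structure):
        return obj.with_coord(transform.apply(obj.coord))
    return transform.apply(np.asarray(obj))


def rmsd(a: np.ndarray, b: np.ndarray, weights=None) -> float:
    """Root-mean-square deviation over paired coordinates, no refitting."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or len(a) == 0:
        raise PairingError("coordinate sets must pair atom-for-atom")
    sq = np.sum((a - b) ** 2, axis=1)
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        return float(np.sqrt(np.sum(w * sq) / np.sum(w)))
    return float(np.sqrt(np.mean(sq)))


def common_atom_pairs(a: Structure, b: Structure,
                      a_indices=None, b_indices=None):
    """Pair atoms by (residue position, atom name), dropping unmatched ones.

    Residue position means the ordinal position of the residue within the
    supplied selection, so peptides with different residue numbering (or
    different side chains, e.g. His vs Leu at an anchor position) pair by
    their common atoms only.
    """
    def keyed(s, idx):
        idx = np.arange(s.n_atoms) if idx is None else np.asarray(idx)
        res_keys = list(dict.fromkeys(
            (s.chain_id[i], s.res_id[i], s.ins_code[i]) for i in idx
        ))
        pos = {k: p for p, k in enumerate(res_keys)}
        return {
            (pos[(s.chain_id[i], s.res_id[i], s.ins_code[i])],
             s.atom_name[i]): i
            for i in idx
        }

    ka, kb = keyed(a, a_indices), keyed(b, b_indices)
    common = [k for k in ka if k in kb]
    if not common:
        raise PairingError("no common atoms between the two structures")
    common.sort()
    ia = np.array([ka[k] for k in common], dtype=int)
    ib = np.array([kb[k] for k in common], dtype=int)
    return ia, ib


def rmsd_structures(a: Structure, b: Structure, spec=None) -> float:
    """Common-atom RMSD between two structures (coordinates as given)."""
    ia_all = select(a, spec) if spec is not None else None
    ib_all = select(b, spec) if spec is not None else None
    ia, ib = common_atom_pairs(a, b, ia_all, ib_all)
    return rmsd(a.coord[ia], b.coord[ib])


# ---------------------------------------------------------------------------
# Fluctuations
# ---------------------------------------------------------------------------

def mw_rmsf(traj: Trajectory, spec: SelectionSpec | str = "heavy",
            group_by_residue: bool = True,
            fit_spec: SelectionSpec | str | None = None):
    """Mass-weighted RMS fluctuation about the time-average position.

    With ``group_by_residue`` the result is one value per residue: the
    square root of the mass-weighted mean of per-atom variances within the
    residue. If ``fit_spec`` is given, every frame is first superposed onto
    the trajectory-average structure over that selection; otherwise frames
    are taken as already superposed.

    Returns ``(labels, values)`` where labels are residue keys (or atom
    indices when ``group_by_residue`` is off).
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    idx = _resolve(traj, spec)
    frames = traj.frames
    if fit_spec is not None:
        fit_idx = _resolve(traj, fit_spec)
        ref = frames.mean(axis=0)
        aligned = np.empty_like(frames)
        for f in range(traj.n_frames):
            t = superpose(frames[f][fit_idx], ref[fit_idx],
                          mobile_indices=None, reference_indices=None)
            aligned[f] = t.apply(frames[f])
        frames = aligned
    xyz = frames[:, idx, :]
    mean = xyz.mean(axis=0)
    msd = np.mean(np.sum((xyz - mean) ** 2, axis=2), axis=0)  # per atom
    masses = traj.topology.masses()[idx]
    if not group_by_residue:
        return list(idx), np.sqrt(msd)
    topo = traj.topology
    keys = [(topo.chain_id[i], int(topo.res_id[i]), topo.ins_code[i])
            for i in idx]
    labels = list(dict.fromkeys(keys))
    values = np.empty(len(labels))
    for r, key in enumerate(labels):
        at = np.array([k == key for k in keys])
        values[r] = np.sqrt(np.sum(masses[at] * msd[at]) / np.sum(masses[at]))
    return labels, values


# ---------------------------------------------------------------------------
# Dihedrals
# ---------------------------------------------------------------------------

def dihedral(p0, p1, p2, p3) -> np.ndarray:
    """Signed dihedral angle(s) in degrees, IUPAC convention, (-180, 180].

    Accepts single points or (n, 3) stacks of frames.
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm = np.linalg.norm(n1, axis=-1) * np.linalg.norm(n2, axis=-1)
    if np.any(norm < 1e-12):
        raise ValueError("undefined dihedral: collinear atom triple")
    b2n = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(np.cross(n1, n2) * b2n, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    # map -180 to +180 to keep the half-open (-180, 180] convention
    return np.where(np.isclose(ang, -180.0), 180.0, ang)


def _find_atom(topo: Structure, chain, res_id, name) -> int:
    hit = np.nonzero(
        (topo.chain_id == chain) & (topo.res_id == res_id)
        & (topo.atom_name == name)
    )[0]
    if len(hit) != 1:
        raise ValueError(
            f"atom {chain}/{res_id}/{name} resolves to {len(hit)} atoms"
        )
    return int(hit[0])


#: backbone/side-chain dihedral definitions: name -> list of
#: (residue offset, atom name)
NAMED_ANGLES = {
    "phi": [(-1, "C"), (0, "N"), (0, "CA"), (0, "C")],
    "psi": [(0, "N"), (0, "CA"), (0, "C"), (1, "N")],
    "omega": [(0, "CA"), (0, "C"), (1, "N"), (1, "CA")],
    "chi1": [(0, "N"), (0, "CA"), (0, "CB"), (0, "CG")],
}

#: per-residue replacement for the fourth chi1 atom where CG is absent
_CHI1_LAST = {"ILE": "CG1", "VAL": "CG1", "THR": "OG1", "SER": "OG",
              "CYS": "SG", "ALA": None, "GLY": None}


def resolve_named_angle(topo: Structure, chain, res_id, angle: str):
    """Map a named angle at a residue to four atom indices, or None."""
    defn = NAMED_ANGLES[angle]
    idx = []
    for off, name in defn:
        if angle == "chi1" and (off, name) == (0, "CG"):
            rn = topo.res_name[
                _find_atom(topo, chain, res_id, "CA")]
            name = _CHI1_LAST.get(rn, "CG")
            if name is None:
                return None
        try:
            idx.append(_find_atom(topo, chain, res_id + off, name))
        except ValueError:
            return None
    return tuple(idx)


def dihedral_series(traj: Trajectory, angles) -> DihedralSeries:
    """Compute per-frame dihedrals for a list of angle requests.

    Each request is either four atom indices, or ``(chain, res_id, name)``
    with name in phi/psi/omega/chi1.
    """
    labels, quads = [], []
    topo = traj.topology
    for req in angles:
        if len(req) == 4 and all(isinstance(i, (int, np.integer))
                                 for i in req):
            labels.append(tuple(req))
            quads.append(tuple(int(i) for i in req))
        else:
            chain, res_id, name = req
            quad = resolve_named_angle(topo, chain, int(res_id), name)
            if quad is None:
                raise ValueError(
                    f"angle {name} undefined at {chain}/{res_id} "
                    "(terminal residue or missing atoms)"
                )
            labels.append((chain, int(res_id), name))
            quads.append(quad)
    values = np.empty((traj.n_frames, len(quads)))
    for j, (i0, i1, i2, i3) in enumerate(quads):
        values[:, j] = dihedral(
            traj.frames[:, i0], traj.frames[:, i1],
            traj.frames[:, i2], traj.frames[:, i3],
        )
    return DihedralSeries(labels=labels, values=values)


# ---------------------------------------------------------------------------
# Distances, contacts, overlap
# ---------------------------------------------------------------------------

def _pair_selections(traj, spec_a, spec_b, allow_overlap=False):
    ia = _resolve(traj, spec_a)
    ib = _resolve(traj, spec_b)
    if not allow_overlap and len(np.intersect1d(ia, ib)) > 0:
        raise ValueError("selections overlap; pair metrics need disjoint "
                         "atom sets")
    return ia, ib


def contacts(traj, spec_a, spec_b, cutoff: float = 4.0) -> PairMetricSeries:
    """Per-frame count of atom pairs at distance strictly < cutoff (A)."""
    ia, ib = _pair_selections(traj, spec_a, spec_b)
    frames = _coords(traj)
    counts = np.empty(len(frames), dtype=int)
    for f, xyz in enumerate(frames):
        d = cdist(xyz[ia], xyz[ib])
        counts[f] = int(np.count_nonzero(d < cutoff))
    return PairMetricSeries(metric=f"contacts<{cutoff}A", values=counts,
                            selections=(spec_a, spec_b))


def vdw_overlap(traj, spec_a, spec_b) -> PairMetricSeries:
    """Per-frame mean positive vdW overlap between two selections.

    Overlap for a pair is max(0, r_a + r_b - d). The frame value is the
    mean over pairs with positive overlap (0 when no pair overlaps); the
    signed per-pair matrix for the last frame set is kept in ``detail``.
    """
    ia, ib = _pair_selections(traj, spec_a, spec_b)
    topo = traj.topology if isinstance(traj, Trajectory) else traj
    radii = topo.vdw_radii()
    rsum = radii[ia][:, None] + radii[ib][None, :]
    frames = _coords(traj)
    values = np.empty(len(frames))
    detail = []
    for f, xyz in enumerate(frames):
        signed = rsum - cdist(xyz[ia], xyz[ib])
        pos = signed[signed > 0]
        values[f] = float(pos.mean()) if len(pos) else 0.0
        detail.append(signed)
    return PairMetricSeries(metric="vdw_overlap", values=values,
                            selections=(spec_a, spec_b), detail=detail)


def com_distance(traj, spec_a, spec_b) -> PairMetricSeries:
    """Distance between mass-weighted centroids of two selections, per
    frame."""
    ia = _resolve(traj, spec_a)
    ib = _resolve(traj, spec_b)
    topo = traj.topology if isinstance(traj, Trajectory) else traj
    m = topo.masses()
    wa = m[ia] / m[ia].sum()
    wb = m[ib] / m[ib].sum()
    frames = _coords(traj)
    coma = np.einsum("fij,i->fj", frames[:, ia, :], wa)
    comb = np.einsum("fij,i->fj", frames[:, ib, :], wb)
    values = np.linalg.norm(coma - comb, axis=1)
    return PairMetricSeries(metric="com_distance", values=values,
                            selections=(spec_a, spec_b))


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------

def hbonds(frame: Structure, donor_spec, acceptor_spec,
           d_max: float = 3.5, angle_min: float = 135.0,
           h_bond_max: float = 1.3):
    """Geometric hydrogen-bond detection on a single frame.

    A bond is reported when the donor-heavy-atom to acceptor distance is
    <= d_max and the D-H...A angle is >= angle_min. Hydrogens are located
    as H/D atoms within ``h_bond_max`` A of the donor heavy atom, in the
    same residue; donors without a hydrogen are skipped (with no error).

    Returns a list of (donor_idx, h_idx, acceptor_idx, distance_A,
    angle_deg).
    """
    don = select(frame, donor_spec)
    acc = select(frame, acceptor_spec)
    is_h = np.isin(frame.element, ("H", "D"))
    h_idx = np.nonzero(is_h)[0]
    out = []
    for d in don:
        if is_h[d]:
            continue
        same_res = (
            (frame.chain_id[h_idx] == frame.chain_id[d])
            & (frame.res_id[h_idx] == frame.res_id[d])
        )
        cand_h = h_idx[same_res]
        if len(cand_h) == 0:
            continue
        dist_h = np.linalg.norm(frame.coord[cand_h] - frame.coord[d], axis=1)
        attached = cand_h[dist_h <= h_bond_max]
        for h in attached:
            for a in acc:
                if a == d or is_h[a]:
                    continue
                da = np.linalg.norm(frame.coord[a] - frame.coord[d])
                if da > d_max:
                    continue
                v1 = frame.coord[d] - frame.coord[h]
                v2 = frame.coord[a] - frame.coord[h]
                cosang = np.dot(v1, v2) / (
                    np.linalg.norm(v1) * np.linalg.norm(v2)
                )
                ang = float(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
                if ang >= angle_min:
                    out.append((int(d), int(h), int(a), float(da), ang))
    return out
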