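"""Synthetic inputs with known ground truth for every analysis stage.

The generators emulate, at desk scale, the data classes the analysis stack
consumes: a toy class-I-like groove/peptide complex, trajectories with
planted per-residue fluctuations and side-chain rotamer switching, planted
conformational clusters, SPR/DSF/anisotropy traces, and 1D spectra with
prescribed Lorentzian components and saturation-transfer coupling. Every
generator is deterministic given its seed and returns its ground truth
alongside the data.

The toy complex is deliberately non-biological: it is built from ideal
internal coordinates (no force field) and needs only to exercise
selections, superposition and volumetrics. Peptide side chains come from
ideal residue templates grafted onto the backbone, so bonded geometry is
chemically plausible (bond lengths 1.2-1.6 A) even though the fold is not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import biotite.structure.info as _binfo

from .biophys import Spectrum1D, lorentzian
from .geometry import dihedral
from .structio import Structure, Trajectory

__all__ = [
    "build_backbone",
    "ideal_residue_coords",
    "gen_toy_complex",
    "gen_trajectory",
    "gen_cluster_ensemble",
    "gen_binding_data",
    "gen_spectrum",
    "gen_cest_family",
    "NEOANTIGEN_SHIFTS",
    "NEOANTIGEN_AREAS",
]

# 19F chemical shifts (ppm) and relative areas of the three-state
# neoantigen/HLA-A3 complex used as the default spectrum plan.
NEOANTIGEN_SHIFTS = (-126.90, -125.18, -123.09)
NEOANTIGEN_AREAS = (0.08, 0.77, 0.15)

# ideal backbone internal coordinates (A, degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8


def _principal_align(coords: np.ndarray) -> np.ndarray:
    """Center a chain and rotate its principal axes onto x >= y >= z."""
    c = coords - coords.mean(0)
    vt = np.linalg.svd(c, full_matrices=False)[2]
    if np.linalg.det(vt) < 0:  # keep a proper rotation
        vt[2] *= -1
    return c @ vt.T


def _place_atom(a, b, c, bond, angle, torsion):
    """NeRF placement of atom d given chain a-b-c and internal
    coordinates."""
    angle = np.radians(angle)
    torsion = np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array([
        -np.cos(angle),
        np.sin(angle) * np.cos(torsion),
        np.sin(angle) * np.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(phi_psi, omega: float = 180.0):
    """Build an ideal N-CA-C-O backbone from (phi, psi) per residue.

    Returns ``(coords, names)``: a ((4 n_res), 3) array and matching atom
    names. phi of the first residue and psi of the last are ignored (they
    are undefined at chain termini).
    """
    n_res = len(phi_psi)
    coords, names = [], []
    # seed the first residue in a canonical frame
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    ang = np.radians(_A_N_CA_C)
    c0 = ca0 + _B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    prev = {"N": n0, "CA": ca0, "C": c0}
    for r, (phi, psi) in enumerate(phi_psi):
        if r > 0:
            n = _place_atom(prev["N"], prev["CA"], prev["C"],
                            _B_C_N, _A_CA_C_N, prev_psi)
            ca = _place_atom(prev["CA"], prev["C"], n,
                             _B_N_CA, _A_C_N_CA, omega)
            c = _place_atom(prev["C"], n, ca, _B_CA_C, _A_N_CA_C, phi)
            prev = {"N": n, "CA": ca, "C": c}
        # carbonyl O: trans to the next N, i.e. torsion psi + 180 about
        # N-CA-C
        o = _place_atom(prev["N"], prev["CA"], prev["C"],
                        _B_C_O, _A_CA_C_O, psi + 180.0)
        coords += [prev["N"], prev["CA"], prev["C"], o]
        names += ["N", "CA", "C", "O"]
        prev_psi = psi
    return np.array(coords), names


def ideal_residue_coords(res_name: str):
    """Heavy-atom template of a residue from the ideal component library.

    Returns ``(coords, atom_names, elements)`` excluding hydrogens and the
    terminal OXT.
    """
    tpl = _binfo.residue(res_name.upper())
    keep = (tpl.element != "H") & (tpl.atom_name != "OXT")
    tpl = tpl[keep]
    return (np.asarray(tpl.coord, dtype=float), list(tpl.atom_name),
            list(tpl.element))


def _graft_sidechain(res_name, bb_n, bb_ca, bb_c):
    """Side-chain heavy atoms of ``res_name`` posed on a backbone slot."""
    from scipy.spatial.transform import Rotation
    coords, names, elements = ideal_residue_coords(res_name)
    by = {n: coords[i] for i, n in enumerate(names)}
    src = np.stack([by["N"], by["CA"], by["C"]])
    dst = np.stack([bb_n, bb_ca, bb_c])
    rot, _ = Rotation.align_vectors(dst - dst.mean(0), src - src.mean(0))
    moved = rot.apply(coords - src.mean(0)) + dst.mean(0)
    side = [
        (moved[i], n, elements[i])
        for i, n in enumerate(names) if n not in ("N", "CA", "C", "O")
    ]
    return side


def _mk_structure(records, metadata=None) -> Structure:
    """Assemble a Structure from (name, element, res_name, chain, res_id,
    xyz)."""
    n = len(records)
    return Structure(
        serial=np.arange(1, n + 1),
        atom_name=np.array([r[0] for r in records]),
        alt_loc=np.array([""] * n),
        res_name=np.array([r[2] for r in records]),
        chain_id=np.array([r[3] for r in records]),
        res_id=np.array([r[4] for r in records], dtype=int),
        ins_code=np.array([""] * n),
        coord=np.array([r[5] for r in records], dtype=float),
        element=np.array([r[1] for r in records]),
        occupancy=np.ones(n),
        b_factor=np.zeros(n),
        metadata=metadata or {},
    )


def idealized_tryptophan() -> Structure:
    """Idealized free tryptophan (heavy atoms incl. OXT) as a Structure.

    Geometry comes from the ideal component library; used for molecular
    volume calculations (grid-fill of Bondi spheres gives ~160 A^3).
    """
    tpl = _binfo.residue("TRP")
    tpl = tpl[tpl.element != "H"]
    records = [
        (str(tpl.atom_name[i]), str(tpl.element[i]).upper(), "TRP", "A", 1,
         np.asarray(tpl.coord[i], dtype=float))
        for i in range(len(tpl))
    ]
    return _mk_structure(records, metadata={"source": "ideal template"})


#: default toy peptide: neoantigen-like nonamer with a variable position-2
#: anchor and a bulky position-6 tryptophan
TOY_PEPTIDE_SEQ = ("ALA", "LEU", "HIS", "GLY", "GLY", "TRP", "THR", "THR",
                   "LYS")


def gen_toy_complex(seed: int = 0, anchor2: str = "LEU",
                    cavity: str | None = None) -> Structure:
    """Toy groove/peptide complex.

    Chain A holds a 180-residue "groove": a 100-residue extended-strand
    floor and two 40-residue helical walls flanking the peptide. Chain C is
    a 9-mer peptide with a bulky position-6 tryptophan and a configurable
    position-2 anchor, lying above the floor between the walls. A small
    seeded jitter (0.02 A) makes distinct seeds distinct while keeping the
    geometry chemically plausible.

    ``cavity`` adds a chain-D shell enclosing the space under the peptide:
    ``"sealed"`` closes it completely (positive cavity volume),
    ``"open"`` leaves the top open so flood fill drains it (zero cavity).
    """
    rng = np.random.default_rng(seed)
    records = []
    res_id = 0
    # --- floor: 10 antiparallel extended strands of 10 residues at z = 0
    for s in range(10):
        bb, names = build_backbone([(-120.0, 120.0)] * 10)
        bb = _principal_align(bb)
        if s % 2:
            bb = bb @ np.diag([-1.0, 1.0, -1.0])  # flip alternate strands
        bb = bb + np.array([0.0, (s - 4.5) * 5.4, 0.0])
        for i, (xyz, nm) in enumerate(zip(bb, names)):
            if i % 4 == 0:
                res_id += 1
            records.append((nm, nm[0], "GLY", "A", res_id, xyz))
    # --- two helical walls of 40 residues flanking the peptide
    for ysign in (-1.0, 1.0):
        bb, names = build_backbone([(-57.0, -47.0)] * 40)
        bb = _principal_align(bb)
        bb = bb + np.array([0.0, ysign * 12.0, 7.0])
        for i, (xyz, nm) in enumerate(zip(bb, names)):
            if i % 4 == 0:
                res_id += 1
            records.append((nm, nm[0], "ALA", "A", res_id, xyz))
    # --- peptide: extended 9-mer above the floor center
    seq = list(TOY_PEPTIDE_SEQ)
    seq[1] = anchor2.upper()
    pep_z = 16.0 if cavity is not None else 8.5
    bb, names = build_backbone([(-130.0, 130.0)] * 9)
    bb = _principal_align(bb) + np.array([0.0, 0.0, pep_z])
    per_res = [bb[4 * i:4 * i + 4] for i in range(9)]
    for i, res_name in enumerate(seq):
        rid = i + 1
        n_xyz, ca_xyz, c_xyz, o_xyz = per_res[i]
        records.append(("N", "N", res_name, "C", rid, n_xyz))
        records.append(("CA", "C", res_name, "C", rid, ca_xyz))
        records.append(("C", "C", res_name, "C", rid, c_xyz))
        records.append(("O", "O", res_name, "C", rid, o_xyz))
        for xyz, nm, el in _graft_sidechain(res_name, n_xyz, ca_xyz, c_xyz):
            records.append((nm, el, res_name, "C", rid, xyz))
    # --- optional cavity shell enclosing the under-peptide space (chain D)
    metadata = {"seed": seed, "anchor2": anchor2}
    if cavity is not None:
        if cavity not in ("sealed", "open"):
            raise ValueError("cavity must be 'sealed', 'open' or None")
        step = 2.0
        grid = np.arange(-8.0, 8.0 + 1e-9, step)
        zs = np.arange(0.0, 12.0 + 1e-9, step)
        shell = []
        for x in grid:
            for y in grid:
                for z in zs:
                    on_side = abs(x) == 8.0 or abs(y) == 8.0
                    on_top = z == zs[-1]
                    if on_side or (on_top and cavity == "sealed"):
                        shell.append((x, y, z))
        for xyz in shell:
            res_id += 1
            records.append(("C", "C", "CAP", "D", res_id,
                            np.array(xyz, dtype=float)))
        metadata["cavity_region"] = ((-6.0, -6.0, 4.0), (6.0, 6.0, 9.0))
    s = _mk_structure(records, metadata=metadata)
    jitter_scale = 0.02
    mask = s.chain_id != "D"  # keep the shell exact
    s.coord[mask] += rng.normal(0.0, jitter_scale, s.coord[mask].shape)
    return s


# ---------------------------------------------------------------------------
# Trajectories with planted dynamics
# ---------------------------------------------------------------------------

def _rotate_about_axis(points, origin, axis, angle_deg):
    from scipy.spatial.transform import Rotation
    axis = axis / np.linalg.norm(axis)
    rot = Rotation.from_rotvec(np.radians(angle_deg) * axis)
    return rot.apply(points - origin) + origin


def gen_trajectory(base: Structure, sigma_per_residue, n_frames: int = 200,
                   seed: int = 0, chain: str = "C",
                   chi1_plan: dict | None = None) -> Trajectory:
    """Frames of ``base`` with planted per-residue fluctuations.

    ``sigma_per_residue`` gives the target RMSF (A) of each residue of
    ``chain``: every frame displaces each residue rigidly by an isotropic
    Gaussian with per-axis standard deviation sigma/sqrt(3), so the
    measured (mass-weighted) RMSF converges to sigma. Atoms outside
    ``chain`` stay fixed.

    ``chi1_plan`` optionally plants two-state side-chain switching:
    ``{"res_id": 6, "modes": (-60.0, 180.0), "occupancy": 0.7}`` rotates
    the side chain beyond CB about the CA-CB axis to the first chi1 mode
    with the given probability per frame (independently), else the second.
    """
    res_ids = [int(r) for r in
               dict.fromkeys(base.res_id[base.chain_id == chain])]
    sigma = np.asarray(sigma_per_residue, dtype=float)
    if len(sigma) != len(res_ids):
        raise ValueError(
            f"sigma profile length {len(sigma)} != residue count "
            f"{len(res_ids)} of chain {chain!r}"
        )
    rng = np.random.default_rng(seed)
    frames = np.repeat(base.coord[None], n_frames, axis=0)
    for rid, sig in zip(res_ids, sigma):
        if sig == 0:
            continue
        at = np.nonzero((base.chain_id == chain) & (base.res_id == rid))[0]
        disp = rng.normal(0.0, sig / np.sqrt(3.0), (n_frames, 1, 3))
        frames[:, at, :] += disp
    if chi1_plan is not None:
        rid = int(chi1_plan["res_id"])
        modes = chi1_plan["modes"]
        occ = float(chi1_plan["occupancy"])
        sel = (base.chain_id == chain) & (base.res_id == rid)
        def atom(name):
            i = np.nonzero(sel & (base.atom_name == name))[0]
            if len(i) != 1:
                raise ValueError(f"chi1 plan: atom {name} not unique")
            return int(i[0])
        i_n, i_ca, i_cb = atom("N"), atom("CA"), atom("CB")
        side = np.nonzero(
            sel & ~np.isin(base.atom_name, ("N", "CA", "C", "O", "CB"))
        )[0]
        choice = rng.random(n_frames) < occ
        for f in range(n_frames):
            target = modes[0] if choice[f] else modes[1]
            cg = frames[f, side[0]] if len(side) else None
            current = float(dihedral(frames[f, i_n], frames[f, i_ca],
                                     frames[f, i_cb], cg))
            frames[f, side] = _rotate_about_axis(
                frames[f, side], frames[f, i_ca],
                frames[f, i_cb] - frames[f, i_ca], target - current,
            )
    return Trajectory(topology=base, frames=frames)


def gen_cluster_ensemble(k: int, separation: float, spread: float, sizes,
                         seed: int = 0, n_atoms: int = 20,
                         max_retries: int = 50):
    """Planted conformational clusters in coordinate space.

    Generates ``k`` conformer centers with pairwise RMSD >= ``separation``
    and frames scattered about each center with expected RMSD ``spread``
    (isotropic Gaussian, per-axis sigma spread/sqrt(3)). ``sizes`` is a
    sequence of frame counts, or fractions summing to 1 together with a
    total (then pass ``(fractions, n_total)``). Frames are returned shuffled
    with their true labels (1-based).

    Returns ``(frames, labels, centers)``.
    """
    if k < 1 or separation <= 0:
        raise ValueError("need k >= 1 and positive separation")
    rng = np.random.default_rng(seed)
    if (len(sizes) == 2 and np.ndim(sizes[0]) == 1
            and not np.isscalar(sizes[0])):
        fracs, total = np.asarray(sizes[0], dtype=float), int(sizes[1])
        counts = np.round(fracs * total).astype(int)
        counts[-1] = total - counts[:-1].sum()
    else:
        counts = np.asarray(sizes, dtype=int)
    if len(counts) != k or np.any(counts < 1):
        raise ValueError("sizes must give a positive count per cluster")
    base = rng.normal(0.0, 3.0, (n_atoms, 3))
    for attempt in range(max_retries):
        # random orthogonal-ish displacement shapes, normalized to unit RMSD
        shapes = rng.normal(0.0, 1.0, (k, n_atoms, 3))
        shapes /= np.sqrt(
            (shapes ** 2).sum(axis=(1, 2)) / n_atoms
        )[:, None, None]
        centers = base[None] + shapes * separation
        ok = True
        for i in range(k):
            for j in range(i + 1, k):
                d = np.sqrt(((centers[i] - centers[j]) ** 2).sum() / n_atoms)
                if d < separation:
                    ok = False
        if ok:
            break
    else:
        raise RuntimeError("could not place cluster centers; increase "
                           "separation or retries")
    frames, labels = [], []
    for c in range(k):
        noise = rng.normal(0.0, spread / np.sqrt(3.0),
                           (counts[c], n_atoms, 3))
        frames.append(centers[c][None] + noise)
        labels += [c + 1] * counts[c]
    frames = np.concatenate(frames)
    labels = np.array(labels)
    perm = rng.permutation(len(labels))
    return frames[perm], labels[perm], centers


# ---------------------------------------------------------------------------
# Binding / stability / anisotropy traces
# ---------------------------------------------------------------------------

@dataclass
class TracePlan:
    """Generating parameters for one synthetic biophysical trace."""

    kind: str
    truth: dict
    noise: float
    seed: int


def gen_binding_data(kind: str, seed: int = 0, noise: float = 0.01,
                     **truth):
    """Synthetic biophysical traces with embedded ground truth.

    kinds and their truth parameters (all noise is i.i.d. Gaussian, scaled
    by the signal amplitude):

    * ``dissociation``: koff (s^-1, default 0.039), amplitude, offset,
      n_points (200), half_lives (2); biphasic with ``koff2``/``amp2``.
    * ``isotherm``: KD (M, default 62e-6), Rmax, n_conc (8),
      span (10x around KD).
    * ``melt``: Tm1/Tm2 (deg C), amplitudes, widths; derivative curve.
    * ``anisotropy``: same decay model as dissociation with r0/r_inf.

    Returns ``(x, y, plan)`` where plan records the generating truth.
    """
    rng = np.random.default_rng(seed)
    if kind in ("dissociation", "anisotropy"):
        koff = truth.get("koff", 0.039)
        amp = truth.get("amplitude", 1.0)
        offset = truth.get("offset",
                           0.1 if kind == "anisotropy" else 0.0)
        n = int(truth.get("n_points", 200))
        half_lives = truth.get("half_lives", 2.0)
        t = np.linspace(0.0, half_lives * np.log(2) / koff, n)
        y = amp * np.exp(-koff * t) + offset
        if "koff2" in truth:
            y = y + truth.get("amp2", amp) * np.exp(-truth["koff2"] * t)
        y = y + rng.normal(0.0, noise * amp, n)
        return t, y, TracePlan(kind, {**truth, "koff": koff}, noise, seed)
    if kind == "isotherm":
        KD = truth.get("KD", 62e-6)
        Rmax = truth.get("Rmax", 100.0)
        n = int(truth.get("n_conc", 8))
        span = truth.get("span", 10.0)
        c = np.geomspace(KD / span, KD * span, n)
        r = Rmax * c / (KD + c)
        r = r + rng.normal(0.0, noise * Rmax, n)
        return c, r, TracePlan(kind, {"KD": KD, "Rmax": Rmax}, noise, seed)
    if kind == "melt":
        tm1 = truth.get("Tm1", 65.0)
        tm2 = truth.get("Tm2", None)
        a1 = truth.get("amp1", 1.0)
        a2 = truth.get("amp2", 0.5 if tm2 is not None else 0.0)
        w1 = truth.get("width1", 2.5)
        w2 = truth.get("width2", 2.5)
        T = np.linspace(truth.get("T_min", 35.0), truth.get("T_max", 90.0),
                        int(truth.get("n_points", 200)))
        y = a1 * np.exp(-0.5 * ((T - tm1) / w1) ** 2)
        if tm2 is not None:
            y = y + a2 * np.exp(-0.5 * ((T - tm2) / w2) ** 2)
        y = y + rng.normal(0.0, noise * a1, len(T))
        return T, y, TracePlan(kind, {"Tm1": tm1, "Tm2": tm2}, noise, seed)
    raise ValueError(f"unknown trace kind {kind!r}")


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------

def gen_spectrum(components=None, snr: float = 20.0, seed: int = 0,
                 axis=None, n_points: int = 2000):
    """Sum-of-Lorentzians 1D spectrum with Gaussian noise.

    ``components`` is a list of (center ppm, fwhm ppm, area); the default
    is the three-state neoantigen-like plan (shifts -126.90 / -125.18 /
    -123.09 ppm, areas 8 / 77 / 15 %, linewidths ~0.4 ppm as appropriate
    for a 44 kDa complex). ``snr`` is max signal over noise sigma.

    Returns ``(Spectrum1D, components)``.
    """
    if components is None:
        components = [
            (c, 0.40, a) for c, a in zip(NEOANTIGEN_SHIFTS,
                                         NEOANTIGEN_AREAS)
        ]
    rng = np.random.default_rng(seed)
    if axis is None:
        centers = [c for c, _, _ in components]
        lo = min(centers) - 3.0
        hi = max(centers) + 3.0
        axis = np.linspace(lo, hi, n_points)
    y = np.zeros_like(axis)
    for c, w, a in components:
        y = y + lorentzian(axis, c, w, a)
    if snr and snr > 0:
        y = y + rng.normal(0.0, y.max() / snr, len(axis))
    return Spectrum1D(axis=axis, intensity=y,
                      metadata={"seed": seed, "snr": snr}), list(components)


def gen_cest_family(components=None, transfer=None, snr: float = 50.0,
                    seed: int = 0, **kwargs):
    """Reference spectrum plus one saturated spectrum per irradiated peak.

    ``transfer[i, j]`` prescribes the fractional attenuation of peak j when
    peak i is irradiated; the diagonal defaults to ~1 (self-saturation).
    Returns ``(reference, {irradiation_ppm: Spectrum1D}, components,
    transfer)``.
    """
    ref, components = gen_spectrum(components, snr=snr, seed=seed, **kwargs)
    n = len(components)
    if transfer is None:
        transfer = np.full((n, n), 0.5)
        np.fill_diagonal(transfer, 0.95)
    transfer = np.asarray(transfer, dtype=float)
    family = {}
    for i, (c, _, _) in enumerate(components):
        attenuated = [
            (cj, wj, aj * (1.0 - transfer[i, j]))
            for j, (cj, wj, aj) in enumerate(components)
        ]
        spec, _ = gen_spectrum(attenuated, snr=snr, seed=seed + 1000 + i,
                               axis=ref.axis.copy())
        family[c] = spec
    return ref, family, components, transfer
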