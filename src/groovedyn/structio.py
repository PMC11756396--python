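"""Structure and trajectory I/O, atom selections, and mass/radius lookup.

This module is the single entry point for coordinates: PDB reading/writing is
delegated to biotite, after which atoms live in a plain array-of-columns
:class:`Structure` (or a :class:`Trajectory` of frames over a fixed topology).
All coordinates are in Angstrom and residue numbering is taken verbatim from
the input file.

Alternate locations are resolved on read to a single conformer per atom: the
highest-occupancy alt-loc wins, ties go to the alphabetically first
identifier. Hydrogens are kept; heavy-atom analyses deselect them explicitly
(selection class ``heavy``).
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as _bst
import biotite.structure.io.pdb as _bpdb

from ._tables import BACKBONE_NAMES, element_masses, element_radii

__all__ = [
    "Structure",
    "Trajectory",
    "SelectionSpec",
    "SelectionError",
    "EmptySelectionError",
    "PDBParseError",
    "PDBFormatError",
    "read_pdb",
    "write_pdb",
    "select",
    "first_copy",
]


class PDBParseError(ValueError):
    """A PDB record could not be parsed; carries a 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class PDBFormatError(ValueError):
    """A structure cannot be represented in fixed-width PDB fields."""


class SelectionError(ValueError):
    """A selection expression could not be parsed or applied."""


class EmptySelectionError(SelectionError):
    """A selection resolved to zero atoms."""


@dataclass
class Structure:
    """A single model: parallel per-atom columns plus free-text metadata."""

    serial: np.ndarray
    atom_name: np.ndarray
    alt_loc: np.ndarray
    res_name: np.ndarray
    chain_id: np.ndarray
    res_id: np.ndarray
    ins_code: np.ndarray
    coord: np.ndarray  # (n_atoms, 3) Angstrom
    element: np.ndarray
    occupancy: np.ndarray
    b_factor: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_name)

    def masses(self) -> np.ndarray:
        """Per-atom standard atomic weights (u)."""
        return element_masses(self.element)

    def vdw_radii(self) -> np.ndarray:
        """Per-atom Bondi vdW radii (A)."""
        return element_radii(self.element)

    def subset(self, indices) -> "Structure":
        """New Structure restricted to ``indices`` (topology order kept)."""
        idx = np.asarray(indices, dtype=int)
        return Structure(
            serial=self.serial[idx],
            atom_name=self.atom_name[idx],
            alt_loc=self.alt_loc[idx],
            res_name=self.res_name[idx],
            chain_id=self.chain_id[idx],
            res_id=self.res_id[idx],
            ins_code=self.ins_code[idx],
            coord=self.coord[idx].copy(),
            element=self.element[idx],
            occupancy=self.occupancy[idx],
            b_factor=self.b_factor[idx],
            metadata=dict(self.metadata),
        )

    def with_coord(self, coord: np.ndarray) -> "Structure":
        out = self.subset(np.arange(self.n_atoms))
        out.coord = np.asarray(coord, dtype=float).reshape(self.n_atoms, 3)
        return out

    def validate(self) -> None:
        """Check structural invariants; raise ValueError on violation."""
        if not np.all(np.isfinite(self.coord)):
            raise ValueError("non-finite coordinates")
        keys = list(
            zip(self.chain_id, self.res_id, self.ins_code, self.atom_name,
                self.alt_loc)
        )
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate atom identifiers within model")
        if np.any(self.masses() <= 0) or np.any(self.vdw_radii() <= 0):
            raise ValueError("non-positive mass or vdW radius")


@dataclass
class Trajectory:
    """Ordered frames of coordinates over a fixed topology."""

    topology: Structure
    frames: np.ndarray  # (n_frames, n_atoms, 3)
    frame_interval: float | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError(
                "frames must be (n_frames, n_atoms, 3) matching the topology"
            )
        if self.frames.shape[0] < 1:
            raise ValueError("trajectory needs at least one frame")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.topology.n_atoms

    def frame(self, i: int) -> Structure:
        return self.topology.with_coord(self.frames[i])


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

_COORD_RE = re.compile(r"^(ATOM|HETATM)")


def _check_record_lines(text: str) -> int:
    """Pre-scan ATOM/HETATM records; return their count.

    Raises PDBParseError naming the first malformed line.
    """
    n = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not _COORD_RE.match(line):
            continue
        n += 1
        if len(line.rstrip("\n")) < 54:
            raise PDBParseError("coordinate record shorter than 54 columns",
                                lineno)
        for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
            fragment = line[lo:hi]
            try:
                float(fragment)
            except ValueError:
                raise PDBParseError(
                    f"unparseable {what} coordinate field {fragment!r}", lineno
                ) from None
    return n


def _resolve_altloc(s: Structure) -> Structure:
    """Keep one conformer per atom: max occupancy, ties to first alt_loc."""
    best: dict[tuple, int] = {}
    for i in range(s.n_atoms):
        key = (s.chain_id[i], int(s.res_id[i]), s.ins_code[i], s.atom_name[i])
        j = best.get(key)
        if j is None:
            best[key] = i
            continue
        oi, oj = s.occupancy[i], s.occupancy[j]
        if oi > oj or (oi == oj and s.alt_loc[i] < s.alt_loc[j]):
            best[key] = i
    keep = np.array(sorted(best.values()), dtype=int)
    if len(keep) == s.n_atoms:
        return s
    return s.subset(keep)


def _structure_from_atoms(atoms: _bst.AtomArray, metadata: dict) -> Structure:
    element = np.array(
        [e if e else _bst.infer_elements([n])[0]
         for e, n in zip(atoms.element, atoms.atom_name)]
    )
    return Structure(
        serial=atoms.atom_id.astype(int),
        atom_name=atoms.atom_name.astype(str),
        alt_loc=np.char.strip(atoms.altloc_id.astype(str)),
        res_name=atoms.res_name.astype(str),
        chain_id=atoms.chain_id.astype(str),
        res_id=atoms.res_id.astype(int),
        ins_code=atoms.ins_code.astype(str),
        coord=np.asarray(atoms.coord, dtype=float),
        element=np.char.upper(element),
        occupancy=atoms.occupancy.astype(float),
        b_factor=atoms.b_factor.astype(float),
        metadata=metadata,
    )


def read_pdb(text: str):
    """Parse PDB content into a Structure (single model) or Trajectory.

    Files carrying MODEL/ENDMDL records yield a Trajectory whose topology is
    the first model; all models must share the atom count. Alt-locs are
    resolved to a single conformer. Elements missing from column 77-78 are
    inferred from the atom name.
    """
    n_records = _check_record_lines(text)
    if n_records == 0:
        raise PDBParseError("no ATOM/HETATM records in input")
    pdb_file = _bpdb.PDBFile.read(io.StringIO(text))
    metadata = {"header": [l for l in text.splitlines()
                           if l[:6].strip() in ("HEADER", "TITLE", "REMARK")]}
    extra = ["atom_id", "occupancy", "b_factor"]
    multi_model = any(l.startswith("MODEL") for l in text.splitlines())
    try:
        if multi_model:
            stack = pdb_file.get_structure(model=None, altloc="all",
                                           extra_fields=extra)
            topo = _resolve_altloc(
                _structure_from_atoms(stack[0], metadata)
            )
            # apply the same alt-loc choice to every frame
            if stack.array_length() != topo.n_atoms:
                keep = _altloc_keep_indices(
                    _structure_from_atoms(stack[0], metadata))
                frames = stack.coord[:, keep, :]
            else:
                frames = stack.coord
            return Trajectory(topology=topo,
                              frames=np.asarray(frames, dtype=float))
        atoms = pdb_file.get_structure(model=1, altloc="all",
                                       extra_fields=extra)
    except PDBParseError:
        raise
    except Exception as exc:  # map library failures to our error type
        raise PDBParseError(f"PDB parsing failed: {exc}") from exc
    return _resolve_altloc(_structure_from_atoms(atoms, metadata))


def _altloc_keep_indices(s: Structure) -> np.ndarray:
    resolved = _resolve_altloc(s)
    kept = set(zip(resolved.chain_id, resolved.res_id, resolved.ins_code,
                   resolved.atom_name, resolved.alt_loc))
    return np.array(
        [i for i in range(s.n_atoms)
         if (s.chain_id[i], s.res_id[i], s.ins_code[i], s.atom_name[i],
             s.alt_loc[i]) in kept],
        dtype=int,
    )


def read_pdb_file(path) -> Structure | Trajectory:
    with open(path) as fh:
        return read_pdb(fh.read())


def _atoms_from_structure(s: Structure) -> _bst.AtomArray:
    arr = _bst.AtomArray(s.n_atoms)
    arr.coord = np.asarray(s.coord, dtype=np.float32)
    arr.atom_name = s.atom_name
    arr.res_name = s.res_name
    arr.chain_id = s.chain_id
    arr.res_id = s.res_id
    arr.ins_code = s.ins_code
    arr.element = s.element
    arr.hetero = np.zeros(s.n_atoms, dtype=bool)
    arr.set_annotation("atom_id", s.serial.astype(int))
    arr.set_annotation("occupancy", s.occupancy.astype(float))
    arr.set_annotation("b_factor", s.b_factor.astype(float))
    return arr


def write_pdb(obj: Structure | Trajectory) -> str:
    """Serialize to fixed-width PDB text; trajectories use MODEL/ENDMDL."""
    if isinstance(obj, Trajectory):
        coords = obj.frames
        topo = obj.topology
    else:
        coords = obj.coord[None]
        topo = obj
    if np.any(coords >= 10000.0) or np.any(coords <= -1000.0):
        raise PDBFormatError(
            "coordinate magnitude exceeds the fixed 8.3f PDB field"
        )
    pdb_file = _bpdb.PDBFile()
    if isinstance(obj, Trajectory):
        stack = _bst.stack(
            [_atoms_from_structure(topo.with_coord(f)) for f in coords]
        )
        pdb_file.set_structure(stack)
    else:
        pdb_file.set_structure(_atoms_from_structure(topo))
    out = io.StringIO()
    pdb_file.write(out)
    return out.getvalue()


def first_copy(structure: Structure) -> Structure:
    """Restrict to the first chain carrying each distinct molecule.

    Crystallographic asymmetric units often contain several copies of the
    same complex; analyses here use only the first copy. Chains are grouped
    by their residue-name sequence and only the first chain of each distinct
    sequence is kept.
    """
    seen: set[tuple] = set()
    keep_chains = []
    for ch in dict.fromkeys(structure.chain_id):
        mask = structure.chain_id == ch
        order = np.lexsort((structure.ins_code[mask], structure.res_id[mask]))
        resseq = tuple(
            dict.fromkeys(
                zip(structure.res_id[mask][order],
                    structure.res_name[mask][order])
            )
        )
        sig = tuple(name for _, name in resseq)
        if sig not in seen:
            seen.add(sig)
            keep_chains.append(ch)
    mask = np.isin(structure.chain_id, keep_chains)
    return structure.subset(np.nonzero(mask)[0])


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")

_KEYWORDS_WITH_ARG = {"chain", "resid", "resname", "name", "element"}
_KEYWORDS_BARE = {"all", "heavy", "hydrogen", "backbone", "sidechain",
                  "calpha"}


@dataclass(frozen=True)
class SelectionSpec:
    """A textual atom selection.

    Grammar (lowest to highest precedence): ``or``, ``and`` (synonym:
    ``of``), ``not``; parentheses group.  Terms::

        all | heavy | hydrogen | backbone | sidechain | calpha
        chain <id[,id...]>        resname <name[,name...]>
        resid <n | a-b [,...]>    name <name[,name...]>
        element <sym[,sym...]>

    ``sidechain`` means non-backbone heavy atoms. Resolution is ordered by
    topology order and deterministic; an empty result is an error.
    """

    expression: str

    def resolve(self, structure: Structure) -> np.ndarray:
        mask = _eval_selection(self.expression, structure)
        idx = np.nonzero(mask)[0]
        if len(idx) == 0:
            raise EmptySelectionError(
                f"selection {self.expression!r} matched no atoms"
            )
        return idx


def select(structure: Structure, spec: SelectionSpec | str) -> np.ndarray:
    """Resolve a selection to an ordered atom-index array."""
    if isinstance(spec, str):
        spec = SelectionSpec(spec)
    return spec.resolve(structure)


def _eval_selection(expression: str, s: Structure) -> np.ndarray:
    tokens = _TOKEN_RE.findall(expression.strip())
    if not tokens:
        raise SelectionError("empty selection expression")
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def advance():
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or():
        left = parse_and()
        while peek() == "or":
            advance()
            left = left | parse_and()
        return left

    def parse_and():
        left = parse_not()
        while peek() in ("and", "of"):
            advance()
            left = left & parse_not()
        return left

    def parse_not():
        if peek() == "not":
            advance()
            return ~parse_not()
        return parse_primary()

    def parse_primary():
        tok = peek()
        if tok is None:
            raise SelectionError(f"unexpected end of expression "
                                 f"{expression!r}")
        if tok == "(":
            advance()
            inner = parse_or()
            if peek() != ")":
                raise SelectionError("unbalanced parenthesis")
            advance()
            return inner
        advance()
        low = tok.lower()
        if low in _KEYWORDS_BARE:
            return _bare_term(low, s)
        if low in _KEYWORDS_WITH_ARG:
            arg = peek()
            if arg is None or arg in (")", "and", "or", "of", "not"):
                raise SelectionError(f"keyword {low!r} needs an argument")
            advance()
            return _arg_term(low, arg, s)
        raise SelectionError(f"unknown selection token {tok!r}")

    mask = parse_or()
    if pos != len(tokens):
        raise SelectionError(f"trailing tokens in {expression!r}")
    return mask


def _bare_term(kw: str, s: Structure) -> np.ndarray:
    is_h = np.isin(s.element, ("H", "D"))
    if kw == "all":
        return np.ones(s.n_atoms, dtype=bool)
    if kw == "heavy":
        return ~is_h
    if kw == "hydrogen":
        return is_h
    if kw == "backbone":
        return np.isin(s.atom_name, tuple(BACKBONE_NAMES)) & ~is_h
    if kw == "sidechain":
        return ~np.isin(s.atom_name, tuple(BACKBONE_NAMES)) & ~is_h
    if kw == "calpha":
        return (s.atom_name == "CA") & (s.element == "C")
    raise AssertionError(kw)


def _arg_term(kw: str, arg: str, s: Structure) -> np.ndarray:
    values = arg.split(",")
    if kw == "chain":
        return np.isin(s.chain_id, values)
    if kw == "resname":
        return np.isin(s.res_name, [v.upper() for v in values])
    if kw == "name":
        return np.isin(s.atom_name, [v.upper() for v in values])
    if kw == "element":
        return np.isin(s.element, [v.upper() for v in values])
    if kw == "resid":
        mask = np.zeros(s.n_atoms, dtype=bool)
        for part in values:
            if "-" in part.lstrip("-")[0:]:  # allow negative ids
                lo_s, _, hi_s = part.rpartition("-")
                if lo_s:
                    lo, hi = int(lo_s), int(hi_s)
                    mask |= (s.res_id >= lo) & (s.res_id <= hi)
                    continue
            mask |= s.res_id == int(part)
        return mask
    raise AssertionError(kw)
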