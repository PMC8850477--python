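"""Structure and ensemble I/O.

Reads and writes PDB files (single- and multi-model) into array-backed
containers, assigns van der Waals radii, and resolves atom selections.
This module is the boundary between file formats and the geometric core:
everything downstream works on :class:`Structure` / :class:`Ensemble`.

Coordinates are in Angstrom throughout; residue numbering is the author
numbering from the file.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

logger = logging.getLogger("alphapocket")

__all__ = [
    "AtomRecord",
    "Structure",
    "Ensemble",
    "RadiusTable",
    "DEFAULT_RADIUS_TABLE",
    "PDBParseError",
    "TopologyError",
    "SelectionError",
    "read_structure",
    "read_ensemble",
    "write_structure",
    "write_ensemble",
    "assign_radii",
    "select_atoms",
]

# Waters excluded by default; standard amino acids recognised as protein.
WATER_NAMES = {"HOH", "WAT", "H2O", "DOD"}

STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

BACKBONE_ATOMS = ("N", "CA", "C", "O")


class PDBParseError(ValueError):
    """Raised when a PDB file cannot be parsed."""


class TopologyError(ValueError):
    """Raised when ensemble frames disagree in atom count/ordering/identity."""


class SelectionError(KeyError):
    """Raised for unknown selection keywords or absent residues."""


@dataclass(frozen=True)
class AtomRecord:
    """A single atom, as read from a PDB ATOM/HETATM record.

    ``vdw_radius`` is assigned by :func:`assign_radii`, never read from the
    file; it is NaN until assignment.
    """

    serial: int
    atom_name: str
    element: str
    residue_name: str
    chain_id: str
    residue_seq: int
    insertion_code: str
    position: np.ndarray
    vdw_radius: float = float("nan")
    occupancy: float = 1.0


@dataclass
class Structure:
    """An array-backed molecular structure.

    Attributes
    ----------
    serial, atom_names, elements, res_names, chain_ids, res_seqs, icodes,
    occupancies : per-atom arrays in file order.
    coords : (n_atoms, 3) float array, Angstrom.
    radii : (n_atoms,) float array, Angstrom; NaN before radius assignment.
    residue_starts : (n_residues + 1,) int array; atoms of residue ``r`` are
        ``range(residue_starts[r], residue_starts[r+1])``.
    """

    serial: np.ndarray
    atom_names: np.ndarray
    elements: np.ndarray
    res_names: np.ndarray
    chain_ids: np.ndarray
    res_seqs: np.ndarray
    icodes: np.ndarray
    coords: np.ndarray
    occupancies: np.ndarray
    radii: np.ndarray = field(default=None)  # type: ignore[assignment]
    residue_starts: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if self.radii is None:
            self.radii = np.full(self.n_atoms, np.nan)
        if self.residue_starts is None:
            self.residue_starts = _build_residue_index(self)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates in structure")
        self._check_unique_atom_keys()

    # -- basic properties -------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    @property
    def n_residues(self) -> int:
        return len(self.residue_starts) - 1

    def residue_keys(self) -> list[tuple[str, int, str, str]]:
        """Ordered (chain_id, residue_seq, insertion_code, residue_name) keys."""
        starts = self.residue_starts[:-1]
        return [
            (
                str(self.chain_ids[i]),
                int(self.res_seqs[i]),
                str(self.icodes[i]),
                str(self.res_names[i]),
            )
            for i in starts
        ]

    def atom_residue_indices(self) -> np.ndarray:
        """Per-atom residue index (0-based into the residue order)."""
        out = np.empty(self.n_atoms, dtype=int)
        for r in range(self.n_residues):
            out[self.residue_starts[r]: self.residue_starts[r + 1]] = r
        return out

    def atoms(self) -> Iterable[AtomRecord]:
        for i in range(self.n_atoms):
            yield AtomRecord(
                serial=int(self.serial[i]),
                atom_name=str(self.atom_names[i]),
                element=str(self.elements[i]),
                residue_name=str(self.res_names[i]),
                chain_id=str(self.chain_ids[i]),
                residue_seq=int(self.res_seqs[i]),
                insertion_code=str(self.icodes[i]),
                position=self.coords[i].copy(),
                vdw_radius=float(self.radii[i]),
                occupancy=float(self.occupancies[i]),
            )

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """A copy of this structure with replaced coordinates (topology shared)."""
        coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        if len(coords) != self.n_atoms:
            raise ValueError("coordinate count does not match atom count")
        return replace(self, coords=coords.copy())

    def subset(self, indices: np.ndarray) -> "Structure":
        """A new structure restricted to ``indices`` (kept in structure order)."""
        idx = np.sort(np.asarray(indices, dtype=int))
        return Structure(
            serial=self.serial[idx],
            atom_names=self.atom_names[idx],
            elements=self.elements[idx],
            res_names=self.res_names[idx],
            chain_ids=self.chain_ids[idx],
            res_seqs=self.res_seqs[idx],
            icodes=self.icodes[idx],
            coords=self.coords[idx],
            occupancies=self.occupancies[idx],
            radii=self.radii[idx],
            residue_starts=None,
        )

    # -- internals --------------------------------------------------------

    def _check_unique_atom_keys(self) -> None:
        keys = set()
        for i in range(self.n_atoms):
            k = (
                str(self.chain_ids[i]),
                int(self.res_seqs[i]),
                str(self.icodes[i]),
                str(self.atom_names[i]),
            )
            if k in keys:
                raise ValueError(f"duplicate atom key {k}")
            keys.add(k)


def _build_residue_index(s: Structure) -> np.ndarray:
    starts = [0]
    prev = None
    for i in range(s.n_atoms):
        key = (str(s.chain_ids[i]), int(s.res_seqs[i]), str(s.icodes[i]),
               str(s.res_names[i]))
        if prev is not None and key != prev:
            starts.append(i)
        prev = key
    starts.append(s.n_atoms)
    return np.asarray(starts, dtype=int)


@dataclass
class Ensemble:
    """A conformer ensemble: one topology, many coordinate frames.

    All frames share the topology of ``topology`` (atom count, ordering and
    residue identity); ``coords`` has shape (n_frames, n_atoms, 3).
    ``frame_times`` is optional, in picoseconds.
    """

    topology: Structure
    coords: np.ndarray
    frame_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("ensemble coords must have shape (F, N, 3)")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise TopologyError("frame atom count differs from topology")
        if self.n_frames < 1:
            raise ValueError("ensemble needs at least one frame")
        if self.frame_times is not None:
            self.frame_times = np.asarray(self.frame_times, dtype=float)
            if len(self.frame_times) != self.n_frames:
                raise ValueError("frame_times length mismatch")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def frame(self, i: int) -> Structure:
        return self.topology.with_coords(self.coords[i])


@dataclass(frozen=True)
class RadiusTable:
    """van der Waals radii by element (optionally overridden by atom name).

    Defaults are Bondi-style: C 1.70, N 1.55, O 1.52, S 1.80, H 1.20,
    P 1.80 A. ``probe_radius`` (default 1.4 A, a water molecule) is carried
    here because solvent-accessible computations expand every ball by it.
    """

    by_element: dict[str, float]
    by_atom_name: dict[str, float] = field(default_factory=dict)
    default_radius: float = 1.70
    probe_radius: float = 1.4

    def __post_init__(self) -> None:
        for r in list(self.by_element.values()) + [self.default_radius]:
            if r <= 0:
                raise ValueError("radii must be positive")
        if self.probe_radius < 0:
            raise ValueError("probe radius must be non-negative")

    def lookup(self, element: str, atom_name: str = "") -> float | None:
        if atom_name and atom_name in self.by_atom_name:
            return self.by_atom_name[atom_name]
        return self.by_element.get(element.upper())


DEFAULT_RADIUS_TABLE = RadiusTable(
    by_element={"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "P": 1.80},
)


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _validate_pdb_columns(path: Path) -> None:
    """Strict check of coordinate/occupancy columns of ATOM/HETATM records.

    The underlying reader is lenient about trailing garbage inside numeric
    fields, so malformed files are rejected here with the offending line
    number.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM  ", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                raise PDBParseError(
                    f"{path}: line {lineno}: truncated coordinate record")
            for col, name in ((slice(30, 38), "x"), (slice(38, 46), "y"),
                              (slice(46, 54), "z")):
                fieldtxt = line[col].strip()
                try:
                    float(fieldtxt)
                except ValueError:
                    raise PDBParseError(
                        f"{path}: line {lineno}: malformed {name}-coordinate "
                        f"field {fieldtxt!r}") from None


def _resolve_element(name: str, element: str) -> str:
    el = element.strip()
    if el:
        return el.upper()
    # Fall back to the atom-name prefix: strip digits, take leading letters.
    stripped = name.strip().lstrip("0123456789")
    if len(stripped) >= 2 and stripped[:2].upper() in ("CL", "BR", "FE", "ZN",
                                                       "MG", "NA", "SE"):
        return stripped[:2].upper()
    return stripped[:1].upper()


def _gemmi_model_to_structure(
    model: gemmi.Model,
    *,
    keep_waters: bool,
    keep_hetero: bool,
    keep_hydrogens: bool,
) -> Structure:
    serial, names, elements, resnames, chains, seqs, icodes = \
        [], [], [], [], [], [], []
    coords, occs = [], []
    for chain in model:
        for residue in chain:
            rname = residue.name.strip()
            if rname in WATER_NAMES and not keep_waters:
                continue
            het = residue.het_flag == "H"
            if het and rname not in STANDARD_AA and rname not in WATER_NAMES \
                    and not keep_hetero:
                continue
            # Resolve altlocs: group by atom name, keep highest occupancy
            # (ties -> first in file order).
            groups: dict[str, gemmi.Atom] = {}
            for atom in residue:
                key = atom.name
                prev = groups.get(key)
                if prev is None or atom.occ > prev.occ + 1e-12:
                    groups[key] = atom
            for atom in groups.values():
                el = _resolve_element(atom.name, atom.element.name)
                if el == "H" and not keep_hydrogens:
                    continue
                serial.append(atom.serial)
                names.append(atom.name)
                elements.append(el)
                resnames.append(rname)
                chains.append(chain.name or "A")
                seqs.append(residue.seqid.num)
                icodes.append((residue.seqid.icode or " ").strip())
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                occs.append(atom.occ)
    if not coords:
        raise PDBParseError("no atoms retained from structure")
    return Structure(
        serial=np.asarray(serial, dtype=int),
        atom_names=np.asarray(names, dtype=object),
        elements=np.asarray(elements, dtype=object),
        res_names=np.asarray(resnames, dtype=object),
        chain_ids=np.asarray(chains, dtype=object),
        res_seqs=np.asarray(seqs, dtype=int),
        icodes=np.asarray(icodes, dtype=object),
        coords=np.asarray(coords, dtype=float),
        occupancies=np.asarray(occs, dtype=float),
    )


def _read_gemmi(path: str | Path) -> gemmi.Structure:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such structure file: {path}")
    _validate_pdb_columns(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise PDBParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise PDBParseError(f"{path}: file contains no models")
    return st


def read_structure(
    path: str | Path,
    model_index: int = 0,
    *,
    keep_waters: bool = False,
    keep_hetero: bool = False,
    keep_hydrogens: bool = False,
) -> Structure:
    """Read one model of a PDB file.

    Waters and non-protein HETATM records are excluded by default, hydrogens
    too (crystal/model PDBs typically lack them); alternate locations are
    resolved to the highest-occupancy conformer (ties go to the first).
    """
    st = _read_gemmi(path)
    if not 0 <= model_index < len(st):
        raise IndexError(
            f"model_index {model_index} out of range (file has {len(st)} models)")
    return _gemmi_model_to_structure(
        st[model_index], keep_waters=keep_waters, keep_hetero=keep_hetero,
        keep_hydrogens=keep_hydrogens)


def _check_topology(ref: Structure, other: Structure, frame: int) -> None:
    if ref.n_atoms != other.n_atoms:
        # find first divergent atom for the error message
        n = min(ref.n_atoms, other.n_atoms)
        raise TopologyError(
            f"frame {frame}: atom count {other.n_atoms} != {ref.n_atoms} "
            f"(first divergence at atom index {n})")
    for i in range(ref.n_atoms):
        same = (ref.atom_names[i] == other.atom_names[i]
                and ref.res_names[i] == other.res_names[i]
                and ref.chain_ids[i] == other.chain_ids[i]
                and ref.res_seqs[i] == other.res_seqs[i]
                and ref.icodes[i] == other.icodes[i])
        if not same:
            raise TopologyError(
                f"frame {frame}: atom {i} "
                f"({other.chain_ids[i]}:{other.res_seqs[i]}:{other.res_names[i]}:"
                f"{other.atom_names[i]}) diverges from reference "
                f"({ref.chain_ids[i]}:{ref.res_seqs[i]}:{ref.res_names[i]}:"
                f"{ref.atom_names[i]})")


def read_ensemble(
    path: str | Path,
    *,
    keep_waters: bool = False,
    keep_hetero: bool = False,
    keep_hydrogens: bool = False,
) -> Ensemble:
    """Read a multi-model PDB as a conformer ensemble (one frame per MODEL).

    Single-model files yield a one-frame ensemble. All frames must match the
    first frame's topology exactly.
    """
    st = _read_gemmi(path)
    kw = dict(keep_waters=keep_waters, keep_hetero=keep_hetero,
              keep_hydrogens=keep_hydrogens)
    frames = [_gemmi_model_to_structure(m, **kw) for m in st]
    ref = frames[0]
    for f, s in enumerate(frames[1:], start=1):
        _check_topology(ref, s, f)
    coords = np.stack([f.coords for f in frames])
    return Ensemble(topology=ref, coords=coords)


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def _structure_to_gemmi_model(s: Structure, name: str) -> gemmi.Model:
    model = gemmi.Model(name)
    chain_map: dict[str, gemmi.Chain] = {}
    res_map: dict[tuple, gemmi.Residue] = {}
    for i in range(s.n_atoms):
        cid = str(s.chain_ids[i])
        if cid not in chain_map:
            chain_map[cid] = gemmi.Chain(cid)
        chain = chain_map[cid]
        rkey = (cid, int(s.res_seqs[i]), str(s.icodes[i]), str(s.res_names[i]))
        if rkey not in res_map:
            res = gemmi.Residue()
            res.name = str(s.res_names[i])
            res.seqid = gemmi.SeqId(int(s.res_seqs[i]),
                                    str(s.icodes[i]) or " ")
            chain.add_residue(res)
            res_map[rkey] = chain[-1]
        res = res_map[rkey]
        atom = gemmi.Atom()
        atom.name = str(s.atom_names[i])
        atom.serial = int(s.serial[i])
        atom.element = gemmi.Element(str(s.elements[i]))
        atom.occ = float(s.occupancies[i])
        atom.pos = gemmi.Position(*s.coords[i])
        res.add_atom(atom)
    for chain in chain_map.values():
        model.add_chain(chain)
    return model


def write_structure(s: Structure, path: str | Path) -> None:
    """Write a structure as a single-model PDB file."""
    st = gemmi.Structure()
    st.add_model(_structure_to_gemmi_model(s, "1"))
    st.setup_entities()
    st.write_pdb(str(path))


def write_ensemble(e: Ensemble, path: str | Path) -> None:
    """Write an ensemble as a multi-model PDB (MODEL/ENDMDL blocks)."""
    st = gemmi.Structure()
    for f in range(e.n_frames):
        st.add_model(_structure_to_gemmi_model(e.frame(f), str(f + 1)))
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Radii and selections
# ---------------------------------------------------------------------------

def assign_radii(s: Structure, table: RadiusTable = DEFAULT_RADIUS_TABLE) -> Structure:
    """Return a copy of ``s`` with van der Waals radii set from ``table``.

    Unknown elements fall back to ``table.default_radius`` with a warning.
    """
    radii = np.empty(s.n_atoms)
    unknown: set[str] = set()
    for i in range(s.n_atoms):
        r = table.lookup(str(s.elements[i]), str(s.atom_names[i]))
        if r is None:
            r = table.default_radius
            unknown.add(str(s.elements[i]))
        radii[i] = r
    if unknown:
        msg = (f"unknown element(s) {sorted(unknown)}; "
               f"using default radius {table.default_radius} A")
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    return replace(s, radii=radii)


def select_atoms(
    s: Structure,
    selection: str | Sequence[int] = "all",
) -> np.ndarray:
    """Resolve a selection to atom indices in structure order.

    ``selection`` is a named set ("backbone" = N, CA, C, O; "ca"; "heavy";
    "all") or an explicit sequence of residue numbers (author numbering,
    all chains). Deterministic; unknown keywords or absent residues raise
    :class:`SelectionError`.
    """
    if isinstance(selection, str):
        key = selection.strip().lower()
        if key == "all":
            return np.arange(s.n_atoms)
        if key == "heavy":
            return np.flatnonzero(np.array(
                [el != "H" for el in s.elements], dtype=bool))
        if key == "ca":
            return np.flatnonzero(np.array(
                [n == "CA" for n in s.atom_names], dtype=bool))
        if key == "backbone":
            return np.flatnonzero(np.array(
                [n in BACKBONE_ATOMS for n in s.atom_names], dtype=bool))
        raise SelectionError(f"unknown selection keyword {selection!r}")
    wanted = list(selection)
    present = set(int(x) for x in s.res_seqs)
    for r in wanted:
        if int(r) not in present:
            raise SelectionError(f"residue {r} not present in structure")
    wanted_set = set(int(r) for r in wanted)
    return np.flatnonzero(np.array(
        [int(x) in wanted_set for x in s.res_seqs], dtype=bool))
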