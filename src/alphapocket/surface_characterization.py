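"""Residue-level surface characterization and variant mapping.

Classifies every residue as pocket / surface / interior (pocket-wall
membership, then relative solvent accessibility against Tien-style
reference areas), computes a simplified electrostatic patch potential
(a screened Coulomb surrogate with distance-dependent dielectric
eps(r) = 4r, dimensionless output), finds spatially clustered residue
triads such as Arg-Gly-Asp patches, and maps nsSNP-style variant strings
("H84K") onto the structure with geometric class, segment and
charge-change annotations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .alpha_geometry import Pocket
from .ensemble_analysis import SegmentPartition
from .structure_io import Structure

__all__ = [
    "GeometricClassification",
    "ChargeModel",
    "TriadHit",
    "VariantRecord",
    "classify_residue_locations",
    "compute_patch_potential",
    "find_residue_triads",
    "map_variants",
    "sidechain_centroids",
]

AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA_1TO3 = {v: k for k, v in AA_3TO1.items()}

# Theoretical maximum accessible areas (A^2) per residue type
# (Tien et al. 2013), used to normalize residue SASA.
REFERENCE_MAX_ASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}
DEFAULT_REFERENCE_ASA = 200.0

BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}

DEFAULT_CHARGES = {"ASP": -1.0, "GLU": -1.0, "LYS": +1.0, "ARG": +1.0,
                   "HIS": 0.0}

# preferred charge-site atoms per residue type; first present wins,
# pairs are averaged (carboxylate midpoints)
CHARGE_SITE_ATOMS = {
    "ASP": (("OD1", "OD2"),),
    "GLU": (("OE1", "OE2"),),
    "LYS": (("NZ",),),
    "ARG": (("CZ",),),
}


@dataclass(frozen=True)
class ChargeModel:
    """Residue net charges (elementary units) and the dielectric model.

    The potential is a unit-free Coulomb surrogate
    V(x) = sum_i q_i / (eps(r_i) * r_i) with eps(r) = dielectric_slope * r.
    """

    charges: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CHARGES))
    dielectric_slope: float = 4.0

    def charge_of(self, res_name: str) -> float:
        return float(self.charges.get(res_name, 0.0))


@dataclass
class GeometricClassification:
    """Per-residue geometric class with supporting quantities."""

    residue_keys: list[tuple[str, int, str, str]]
    classes: np.ndarray            # "pocket" | "surface" | "interior"
    pocket_id: np.ndarray          # id of the pocket, -1 otherwise
    rel_accessibility: np.ndarray  # residue SASA / reference max ASA

    def class_of(self, chain: str, resseq: int) -> str:
        for i, (c, rs, _, _) in enumerate(self.residue_keys):
            if c == chain and rs == resseq:
                return str(self.classes[i])
        raise KeyError(f"{chain}:{resseq}")


@dataclass(frozen=True)
class TriadHit:
    residues: tuple[tuple[str, int, str, str], ...]
    distances: tuple[float, float, float]   # pairwise, Angstrom
    all_on_pocket: bool

    @property
    def max_distance(self) -> float:
        return max(self.distances)


@dataclass(frozen=True)
class VariantRecord:
    variant: str
    wild_type: str | None = None      # 1-letter
    position: int | None = None
    substitute: str | None = None     # 1-letter
    geometric_class: str | None = None
    segment: str | None = None
    pocket_id: int | None = None
    charge_flag: str | None = None
    error: str | None = None


def classify_residue_locations(
    structure: Structure,
    pockets: list[Pocket],
    sasa_per_atom: np.ndarray,
    surface_threshold: float = 0.05,
) -> GeometricClassification:
    """Assign pocket / surface / interior to every residue.

    A residue is "pocket" if it lines any detected pocket or void wall
    (the largest-MV pocket wins when several claim it), else "surface"
    when its relative accessibility (summed atom SASA over the Tien-style
    reference maximum for its type) reaches ``surface_threshold``, else
    "interior".
    """
    keys = structure.residue_keys()
    n_res = len(keys)
    res_idx = structure.atom_residue_indices()

    rel = np.zeros(n_res)
    for r in range(n_res):
        area = float(np.asarray(sasa_per_atom)[res_idx == r].sum())
        ref = REFERENCE_MAX_ASA.get(keys[r][3], DEFAULT_REFERENCE_ASA)
        rel[r] = area / ref

    pocket_id = np.full(n_res, -1, dtype=int)
    for p in sorted(pockets, key=lambda p: -p.mv):
        for key in p.wall_residues:
            i = keys.index(key)
            if pocket_id[i] == -1:
                pocket_id[i] = p.id
    classes = np.where(
        pocket_id >= 0, "pocket",
        np.where(rel >= surface_threshold, "surface", "interior"))
    return GeometricClassification(
        residue_keys=keys, classes=classes.astype(object),
        pocket_id=pocket_id, rel_accessibility=rel)


def _charge_sites(structure: Structure, model: ChargeModel
                  ) -> tuple[np.ndarray, np.ndarray]:
    """(sites, charges) for all charged residues.

    The charge sits on the residue's characteristic atoms (carboxylate
    midpoint for Asp/Glu, terminal N for Lys, guanidinium C for Arg);
    when those atoms are absent (reduced pseudo-residues) the side-chain
    centroid, or failing that the residue centroid, is used.
    """
    keys = structure.residue_keys()
    res_idx = structure.atom_residue_indices()
    sites, charges = [], []
    for r, (chain, seq, icode, name) in enumerate(keys):
        q = model.charge_of(name)
        if q == 0.0:
            continue
        atom_ids = np.flatnonzero(res_idx == r)
        names = [str(structure.atom_names[i]) for i in atom_ids]
        pos = None
        for group in CHARGE_SITE_ATOMS.get(name, ()):
            found = [atom_ids[names.index(a)] for a in group if a in names]
            if len(found) == len(group):
                pos = structure.coords[found].mean(axis=0)
                break
        if pos is None:
            side = [i for i, nm in zip(atom_ids, names)
                    if nm not in BACKBONE_NAMES]
            chosen = side if side else list(atom_ids)
            pos = structure.coords[chosen].mean(axis=0)
        sites.append(pos)
        charges.append(q)
    if not sites:
        return np.zeros((0, 3)), np.zeros(0)
    return np.asarray(sites), np.asarray(charges)


def compute_patch_potential(
    structure: Structure,
    points: np.ndarray,
    charge_model: ChargeModel = ChargeModel(),
) -> np.ndarray:
    """Surrogate electrostatic potential at each evaluation point.

    V(x) = sum_i q_i / (eps(r_i) * r_i), eps(r) = slope * r, so each
    charge contributes q / (slope * r^2). Dimensionless; intended for the
    qualitative sign/character of surface patches, not for energies.
    Raises if a point coincides with a charge site.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    sites, charges = _charge_sites(structure, charge_model)
    if len(sites) == 0:
        return np.zeros(len(points))
    d = np.linalg.norm(points[:, None, :] - sites[None], axis=2)
    if np.any(d < 1e-9):
        raise ValueError("evaluation point coincides with a charge site")
    return (charges[None] / (charge_model.dielectric_slope * d * d)).sum(axis=1)


def sidechain_centroids(structure: Structure) -> np.ndarray:
    """Per-residue side-chain centroid (CA for Gly or when no side chain)."""
    keys = structure.residue_keys()
    res_idx = structure.atom_residue_indices()
    out = np.empty((len(keys), 3))
    for r, (_, _, _, name) in enumerate(keys):
        atom_ids = np.flatnonzero(res_idx == r)
        names = [str(structure.atom_names[i]) for i in atom_ids]
        side = [i for i, nm in zip(atom_ids, names)
                if nm not in BACKBONE_NAMES]
        if name == "GLY" or not side:
            ca = [i for i, nm in zip(atom_ids, names) if nm == "CA"]
            chosen = ca if ca else list(atom_ids)
        else:
            chosen = side
        out[r] = structure.coords[chosen].mean(axis=0)
    return out


def find_residue_triads(
    structure: Structure,
    pattern: tuple[str, str, str] = ("ARG", "GLY", "ASP"),
    distance_cutoff: float = 12.0,
    classification: GeometricClassification | None = None,
) -> list[TriadHit]:
    """All residue triples matching the unordered type pattern whose three
    pairwise side-chain-centroid distances are within the cutoff.

    Repeated eligible residues yield one hit per combination (no
    deduplication). Hits are sorted by maximum pairwise distance
    ascending; ``all_on_pocket`` is set when a classification is supplied
    and all three residues are pocket-class.
    """
    keys = structure.residue_keys()
    centroids = sidechain_centroids(structure)
    want = [p.upper() for p in pattern]
    cand: dict[str, list[int]] = {t: [] for t in set(want)}
    for i, (_, _, _, name) in enumerate(keys):
        if name in cand:
            cand[name].append(i)

    hits: list[TriadHit] = []
    seen: set[tuple[int, ...]] = set()
    pools = [cand[t] for t in want]
    for combo in itertools.product(*pools):
        if len(set(combo)) != 3:
            continue
        key = tuple(sorted(combo))
        if key in seen:
            continue
        seen.add(key)
        a, b, c = combo
        d = (float(np.linalg.norm(centroids[a] - centroids[b])),
             float(np.linalg.norm(centroids[a] - centroids[c])),
             float(np.linalg.norm(centroids[b] - centroids[c])))
        if max(d) > distance_cutoff:
            continue
        on_pocket = False
        if classification is not None:
            on_pocket = all(
                str(classification.classes[i]) == "pocket" for i in combo)
        hits.append(TriadHit(
            residues=tuple(keys[i] for i in combo),
            distances=d, all_on_pocket=on_pocket))
    hits.sort(key=lambda h: h.max_distance)
    return hits


def _charge_flag(q_old: float, q_new: float) -> str:
    if q_old == q_new:
        return "none"
    if q_old == 0.0:
        return "+ gain" if q_new > 0 else "- gain"
    if q_new == 0.0:
        return "+ loss" if q_old > 0 else "- loss"
    if q_old * q_new < 0:
        return "inversion"
    return "magnitude change"


def parse_variant(text: str) -> tuple[str, int, str]:
    """Parse '<WT><position><SUB>' in 1-letter codes, e.g. 'H84K'."""
    t = text.strip().upper()
    if len(t) < 3 or t[0] not in AA_1TO3 or t[-1] not in AA_1TO3 \
            or not t[1:-1].isdigit():
        raise ValueError(f"unparseable variant string {text!r}")
    return t[0], int(t[1:-1]), t[-1]


def map_variants(
    structure: Structure,
    variants: list[str],
    classification: GeometricClassification,
    segments: SegmentPartition | None = None,
    charge_model: ChargeModel = ChargeModel(),
) -> list[VariantRecord]:
    """Map variant strings onto the structure, Table-style.

    Each record carries the parsed fields, the residue's geometric class
    and pocket id, the flexibility segment containing it (when a
    segmentation over the same residue order is given), and a
    charge-change flag (e.g. H->K "+ gain", E->K "inversion"). Parse
    failures and wild-type mismatches are reported per record, not
    raised. Rows are returned in input order.
    """
    keys = classification.residue_keys
    records: list[VariantRecord] = []
    for text in variants:
        try:
            wt, pos, sub = parse_variant(text)
        except ValueError as exc:
            records.append(VariantRecord(variant=text, error=str(exc)))
            continue
        idx = next((i for i, (_, rs, _, _) in enumerate(keys) if rs == pos),
                   None)
        if idx is None:
            records.append(VariantRecord(
                variant=text, wild_type=wt, position=pos, substitute=sub,
                error=f"residue {pos} not present in structure"))
            continue
        actual = keys[idx][3]
        if AA_3TO1.get(actual) != wt:
            records.append(VariantRecord(
                variant=text, wild_type=wt, position=pos, substitute=sub,
                error=f"wild-type mismatch: structure has {actual} at {pos}"))
            continue
        seg_label = None
        if segments is not None:
            for s in segments.segments:
                if s.start_residue <= idx <= s.end_residue:
                    seg_label = s.label
                    break
        pid = int(classification.pocket_id[idx])
        records.append(VariantRecord(
            variant=text, wild_type=wt, position=pos, substitute=sub,
            geometric_class=str(classification.classes[idx]),
            segment=seg_label,
            pocket_id=pid if pid >= 0 else None,
            charge_flag=_charge_flag(
                charge_model.charge_of(AA_1TO3[wt]),
                charge_model.charge_of(AA_1TO3[sub])),
        ))
    return records
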