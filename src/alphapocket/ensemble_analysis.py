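"""Conformer-ensemble statistics.

Least-squares rigid superposition (Kabsch), pairwise RMSD matrices,
hierarchical cutoff-sequence clustering of conformers with representative
selection, per-residue RMSF profiles against an iterated mean structure,
and RMSF-threshold segmentation of the chain into flexibility segments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .structure_io import Ensemble, Structure, select_atoms

__all__ = [
    "SuperpositionResult",
    "RMSDMatrix",
    "ClusterAssignment",
    "RMSFProfile",
    "SegmentPartition",
    "Segment",
    "DEFAULT_CUTOFFS",
    "superpose",
    "pairwise_rmsd_matrix",
    "cluster_conformers",
    "compute_rmsf",
    "segment_by_rmsf",
]

# RMSD thresholds applied in sequence when refining conformer subclasses.
DEFAULT_CUTOFFS = (3.5, 3.0, 2.5, 2.0, 1.5)


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid-body fit of a mobile onto a reference coordinate set."""

    rotation: np.ndarray     # (3, 3), det = +1
    translation: np.ndarray  # (3,)
    rmsd: float              # Angstrom, after the fit

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass(frozen=True)
class RMSDMatrix:
    """Pairwise superposed RMSD (Angstrom) between ensemble frames."""

    values: np.ndarray
    selection: str

    @property
    def n_frames(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class ClusterAssignment:
    """Partition of frames into subclasses with one representative each."""

    subclass_of: np.ndarray          # per-frame subclass id (0-based)
    members: list[np.ndarray]        # per-subclass frame indices
    representatives: list[int]       # per-subclass representative frame
    cutoffs: tuple[float, ...]

    @property
    def n_subclasses(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class RMSFProfile:
    """Per-residue root-mean-square fluctuation about the ensemble mean."""

    rmsf: np.ndarray                 # per residue, Angstrom
    residue_keys: list[tuple[str, int, str, str]]
    selection: str


@dataclass(frozen=True)
class Segment:
    start_residue: int               # 0-based index into the profile
    end_residue: int                 # inclusive
    label: str                       # S1, S2, ...
    flexibility: str                 # "high" or "low"
    mean_rmsf: float


@dataclass(frozen=True)
class SegmentPartition:
    segments: list[Segment]
    cutoff: float


def _kabsch(mobile: np.ndarray, reference: np.ndarray
            ) -> tuple[np.ndarray, np.ndarray, float]:
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    P = mobile - mc
    Q = reference - rc
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    fitted = P @ R.T
    rmsd = float(np.sqrt(((fitted - Q) ** 2).sum() / len(P)))
    t = rc - R @ mc
    return R, t, rmsd


def superpose(mobile: Structure, reference: Structure,
              selection: str = "all") -> SuperpositionResult:
    """Least-squares optimal rigid superposition (reflections disallowed).

    The fit uses the selected atoms of both structures, which must
    correspond one-to-one; at least three non-collinear atoms are required.
    """
    mi = select_atoms(mobile, selection)
    ri = select_atoms(reference, selection)
    if len(mi) != len(ri):
        raise ValueError(
            f"selection lengths differ: {len(mi)} vs {len(ri)}")
    if len(mi) < 3:
        raise ValueError("need at least 3 atoms for superposition")
    P = mobile.coords[mi]
    if np.linalg.matrix_rank(P - P.mean(axis=0), tol=1e-9) < 2:
        raise ValueError("collinear selection: superposition is degenerate")
    R, t, rmsd = _kabsch(P, reference.coords[ri])
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)


def _pairwise_rmsd(coords: np.ndarray) -> np.ndarray:
    """All-pairs superposed RMSD for (F, N, 3) coordinate sets (batched)."""
    F, N, _ = coords.shape
    centered = coords - coords.mean(axis=1, keepdims=True)
    ssq = np.einsum("fij,fij->f", centered, centered)
    ii, jj = np.triu_indices(F, k=1)
    H = np.einsum("pni,pnj->pij", centered[ii], centered[jj])
    U, S, Vt = np.linalg.svd(H)
    det = np.linalg.det(np.einsum("pij,pjk->pik", U, Vt))
    S_adj = S.copy()
    S_adj[:, 2] *= np.sign(det)
    # RMSD^2 = (ssq_i + ssq_j - 2 * sum of adjusted singular values) / N
    msd = (ssq[ii] + ssq[jj] - 2.0 * S_adj.sum(axis=1)) / N
    out = np.zeros((F, F))
    vals = np.sqrt(np.maximum(msd, 0.0))
    out[ii, jj] = vals
    out[jj, ii] = vals
    return out


def pairwise_rmsd_matrix(ensemble: Ensemble,
                         selection: str = "ca") -> RMSDMatrix:
    """Pairwise superposed RMSD over all frame pairs of the ensemble."""
    if ensemble.n_frames < 2:
        raise ValueError("need at least 2 frames")
    idx = select_atoms(ensemble.topology, selection)
    if len(idx) < 3:
        raise ValueError("selection too small for superposition")
    return RMSDMatrix(values=_pairwise_rmsd(ensemble.coords[:, idx]),
                      selection=selection if isinstance(selection, str)
                      else "custom")


def cluster_conformers(
    matrix: RMSDMatrix,
    cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS,
) -> ClusterAssignment:
    """Refine frames into subclasses by a descending sequence of RMSD cutoffs.

    Starting from one all-frames group, each cutoff in turn splits every
    current group by complete-linkage agglomeration at that threshold
    (frames stay together only while their maximal intra-group RMSD can be
    kept within the cutoff). The partition left after the last cutoff is
    the subclass assignment. The representative of a subclass is the frame
    whose mean RMSD to its co-members is closest to the subclass's mean
    pairwise RMSD (the "middle RMSD" frame; ties go to the lowest frame
    index). Subclasses are numbered by their lowest member frame.
    """
    cut = tuple(float(c) for c in cutoffs)
    if any(c <= 0 for c in cut) or any(a >= b for a, b in zip(cut[1:], cut[:-1])):
        raise ValueError("cutoffs must be strictly decreasing and positive")
    D = matrix.values
    groups: list[np.ndarray] = [np.arange(matrix.n_frames)]
    for c in cut:
        new_groups: list[np.ndarray] = []
        for g in groups:
            if len(g) == 1:
                new_groups.append(g)
                continue
            sub = D[np.ix_(g, g)]
            Z = linkage(squareform(sub, checks=False), method="complete")
            lab = fcluster(Z, t=c, criterion="distance")
            for lb in np.unique(lab):
                new_groups.append(g[lab == lb])
        groups = new_groups
    groups.sort(key=lambda g: int(g[0]))

    subclass_of = np.empty(matrix.n_frames, dtype=int)
    reps: list[int] = []
    for sid, g in enumerate(groups):
        subclass_of[g] = sid
        if len(g) == 1:
            reps.append(int(g[0]))
            continue
        sub = D[np.ix_(g, g)]
        mean_to_others = sub.sum(axis=1) / (len(g) - 1)
        iu = np.triu_indices(len(g), k=1)
        target = sub[iu].mean()
        best = int(np.argmin(np.abs(mean_to_others - target)))  # ties: first
        reps.append(int(g[best]))
    return ClusterAssignment(subclass_of=subclass_of, members=groups,
                             representatives=reps, cutoffs=cut)


def compute_rmsf(
    ensemble: Ensemble,
    selection: str = "ca",
    *,
    superposition: bool = True,
    mean_iterations: int = 2,
) -> RMSFProfile:
    """Per-residue RMSF about the ensemble mean structure.

    Frames are superposed (selected atoms) onto the running mean structure,
    iterated ``mean_iterations`` times (mean, fit, new mean). The RMSF of a
    residue is the root-mean-square displacement of its selected atoms from
    their mean positions over frames, averaged over the residue's atoms.
    """
    if ensemble.n_frames < 2:
        raise ValueError("need at least 2 frames")
    idx = select_atoms(ensemble.topology, selection)
    if len(idx) == 0:
        raise ValueError("empty selection")
    X = ensemble.coords[:, idx].copy()       # (F, n, 3)
    if superposition:
        for _ in range(max(1, mean_iterations)):
            mean = X.mean(axis=0)
            for f in range(len(X)):
                R, t, _ = _kabsch(X[f], mean)
                X[f] = X[f] @ R.T + t
    mean = X.mean(axis=0)
    per_atom_msd = ((X - mean) ** 2).sum(axis=2).mean(axis=0)   # (n,)

    res_of_atom = ensemble.topology.atom_residue_indices()[idx]
    keys_all = ensemble.topology.residue_keys()
    res_ids = sorted(set(int(r) for r in res_of_atom))
    rmsf = np.empty(len(res_ids))
    for k, r in enumerate(res_ids):
        rmsf[k] = np.sqrt(per_atom_msd[res_of_atom == r].mean())
    return RMSFProfile(
        rmsf=rmsf,
        residue_keys=[keys_all[r] for r in res_ids],
        selection=selection if isinstance(selection, str) else "custom",
    )


def segment_by_rmsf(profile: RMSFProfile, cutoff: float = 3.0,
                    min_length: int = 1) -> SegmentPartition:
    """Partition the chain into contiguous high/low-flexibility segments.

    Residues above ``cutoff`` are "high", the rest "low"; maximal runs form
    segments. Runs shorter than ``min_length`` are merged into the
    neighboring segment whose mean RMSF is closer (ties go to the preceding
    segment), and merging repeats until all segments satisfy the minimum.
    Labels S1..Sk follow sequence order.
    """
    if len(profile.rmsf) == 0:
        raise ValueError("empty RMSF profile")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if min_length < 1:
        raise ValueError("min_length must be >= 1")

    high = profile.rmsf > cutoff
    runs: list[list[int]] = []   # [start, end, flex(0/1)]
    for i, h in enumerate(high):
        if runs and runs[-1][2] == int(h):
            runs[-1][1] = i
        else:
            runs.append([i, i, int(h)])

    def run_mean(r: list[int]) -> float:
        return float(profile.rmsf[r[0]: r[1] + 1].mean())

    changed = True
    while changed and len(runs) > 1:
        changed = False
        for i, r in enumerate(runs):
            if r[1] - r[0] + 1 >= min_length:
                continue
            mean_r = run_mean(r)
            prev_d = abs(run_mean(runs[i - 1]) - mean_r) if i > 0 else np.inf
            next_d = abs(run_mean(runs[i + 1]) - mean_r) \
                if i < len(runs) - 1 else np.inf
            target = i - 1 if prev_d <= next_d else i + 1
            tgt = runs[target]
            lo, hi = min(r[0], tgt[0]), max(r[1], tgt[1])
            merged = [lo, hi, tgt[2]]
            if target < i:
                runs[target: i + 1] = [merged]
            else:
                runs[i: target + 1] = [merged]
            # adjacent same-class runs may now touch; coalesce
            j = 0
            while j < len(runs) - 1:
                if runs[j][2] == runs[j + 1][2]:
                    runs[j][1] = runs[j + 1][1]
                    del runs[j + 1]
                else:
                    j += 1
            changed = True
            break

    segments = [
        Segment(start_residue=r[0], end_residue=r[1], label=f"S{i + 1}",
                flexibility="high" if r[2] else "low", mean_rmsf=run_mean(r))
        for i, r in enumerate(runs)
    ]
    return SegmentPartition(segments=segments, cutoff=float(cutoff))
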