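"""Pocket dynamics over conformer ensembles.

Runs pocket detection independently on every frame, tracks the main
pocket through the trajectory by wall-residue overlap, computes the
per-residue pocket-occupancy likelihood

    phi = sum_f p_f / n,   p_f = 1 iff the residue lines the tracked
                           pocket in frame f,

and summarizes the per-frame geometric measurements (MV, SAA, residue
counts) over the trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .alpha_geometry import GeometryConfig, Pocket, detect_pockets
from .structure_io import Ensemble

__all__ = [
    "PocketSeries",
    "OccupancyProfile",
    "detect_pockets_per_frame",
    "track_main_pocket",
    "occupancy_likelihood",
    "metrics_summary",
]


@dataclass
class PocketSeries:
    """Per-frame pocket detections plus the tracked main pocket.

    ``tracked[f]`` is the index of the tracked pocket within ``pockets[f]``
    or None when the pocket is absent in that frame.
    """

    pockets: list[list[Pocket]]
    tracked: list[int | None]
    jaccard_min: float

    @property
    def n_frames(self) -> int:
        return len(self.pockets)

    def tracked_pocket(self, f: int) -> Pocket | None:
        t = self.tracked[f]
        return None if t is None else self.pockets[f][t]

    @property
    def present(self) -> np.ndarray:
        return np.array([t is not None for t in self.tracked])

    def metric(self, name: str) -> np.ndarray:
        """Per-frame metric of the tracked pocket (NaN where absent)."""
        out = np.full(self.n_frames, np.nan)
        for f in range(self.n_frames):
            p = self.tracked_pocket(f)
            if p is None:
                continue
            if name == "mv":
                out[f] = p.mv
            elif name == "saa":
                out[f] = p.saa
            elif name == "n_residues":
                out[f] = len(p.wall_residues)
            else:
                raise KeyError(name)
        return out


@dataclass(frozen=True)
class OccupancyProfile:
    """Per-residue occupancy likelihood phi = p_sum / n (exact rational)."""

    residue_keys: list[tuple[str, int, str, str]]
    p_sum: np.ndarray     # integer counts
    n: int

    @property
    def phi(self) -> np.ndarray:
        return self.p_sum / self.n


def detect_pockets_per_frame(
    ensemble: Ensemble,
    config: GeometryConfig = GeometryConfig(),
) -> list[list[Pocket]]:
    """Run the alpha-shape pipeline independently on every frame.

    Each frame uses seed ``config.seed + frame`` for its Monte Carlo
    measurements, so results are deterministic for a given base seed.
    """
    if np.any(~np.isfinite(ensemble.topology.radii)):
        raise ValueError("ensemble topology has unassigned radii")
    out: list[list[Pocket]] = []
    for f in range(ensemble.n_frames):
        frame_cfg = replace(config, seed=config.seed + f)
        try:
            out.append(detect_pockets(ensemble.frame(f), frame_cfg))
        except Exception as exc:
            raise type(exc)(f"frame {f}: {exc}") from exc
    return out


def _residue_set(p: Pocket) -> frozenset:
    return frozenset(p.wall_residues)


def track_main_pocket(
    per_frame: list[list[Pocket]],
    jaccard_min: float = 0.3,
    *,
    include_voids: bool = False,
) -> PocketSeries:
    """Follow the main pocket through the trajectory.

    The main pocket starts as the largest-MV pocket of the first frame in
    which one exists. In each later frame the candidate with maximal
    wall-residue Jaccard overlap to the last tracked state is selected if
    the overlap reaches ``jaccard_min`` (ties go to the larger MV);
    otherwise the frame is marked absent and tracking resumes against the
    last non-absent state. Voids are not candidates unless
    ``include_voids`` is set.
    """
    if not per_frame:
        raise ValueError("empty pocket series")
    tracked: list[int | None] = []
    ref: frozenset | None = None
    for pockets in per_frame:
        cands = [(i, p) for i, p in enumerate(pockets)
                 if include_voids or p.kind == "pocket"]
        if not cands:
            tracked.append(None)
            continue
        if ref is None:
            best_i, best_p = max(cands, key=lambda ip: ip[1].mv)
            tracked.append(best_i)
            ref = _residue_set(best_p)
            continue
        scored = []
        for i, p in enumerate(pockets):
            if not include_voids and p.kind != "pocket":
                continue
            rs = _residue_set(p)
            union = len(ref | rs)
            jac = len(ref & rs) / union if union else 0.0
            scored.append((jac, p.mv, i))
        jac, _, i = max(scored)
        if jac >= jaccard_min:
            tracked.append(i)
            ref = _residue_set(pockets[i])
        else:
            tracked.append(None)
    return PocketSeries(pockets=per_frame, tracked=tracked,
                        jaccard_min=jaccard_min)


def occupancy_likelihood(
    series: PocketSeries,
    ensemble: Ensemble,
    *,
    count_absent_frames: bool = True,
    any_pocket: bool = False,
) -> OccupancyProfile:
    """Per-residue likelihood of lining the tracked pocket.

    For every residue of the structure, p = 1 in a frame iff it is a wall
    residue of that frame's tracked main pocket (``any_pocket`` widens
    this to membership of any detected pocket). Frames where the tracked
    pocket is absent contribute p = 0 and are counted in n by default;
    ``count_absent_frames=False`` excludes them from n, making phi
    conditional on the pocket being open.
    """
    if series.n_frames == 0:
        raise ValueError("empty series")
    keys = ensemble.topology.residue_keys()
    index = {k: i for i, k in enumerate(keys)}
    p_sum = np.zeros(len(keys), dtype=int)
    n = 0
    for f in range(series.n_frames):
        if any_pocket:
            frame_residues: set = set()
            for p in series.pockets[f]:
                frame_residues |= set(p.wall_residues)
            hit = frame_residues
            n += 1
        else:
            p = series.tracked_pocket(f)
            if p is None:
                if count_absent_frames:
                    n += 1
                continue
            hit = set(p.wall_residues)
            n += 1
        for k in hit:
            p_sum[index[k]] += 1
    if n == 0:
        raise ValueError("no frames counted")
    return OccupancyProfile(residue_keys=keys, p_sum=p_sum, n=n)


def metrics_summary(series: PocketSeries) -> dict:
    """Mean/SD/min/max of MV, SAA and wall-residue count over the frames
    where the tracked pocket is present, plus the coverage fraction."""
    present = series.present
    if not present.any():
        raise ValueError("tracked pocket absent in every frame")
    out: dict = {"n_frames": series.n_frames,
                 "coverage": float(present.mean())}
    for name, key in (("mv", "MV_A3"), ("saa", "SAA_A2"),
                      ("n_residues", "n_residues")):
        vals = series.metric(name)[present]
        out[key] = {
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=0)),
            "min": float(vals.min()),
            "max": float(vals.max()),
        }
    return out
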