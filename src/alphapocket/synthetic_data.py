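"""Ground-truthed synthetic structures and conformer ensembles.

Every stage of the pipeline is testable against planted truth produced
here: shell structures with a single deep pocket and a mouth ("cup"),
fully sealed internal cavities ("cavity"), gently dimpled convex blobs
("shallow"), and plain convex clusters ("blob"); Gaussian-perturbed
trajectories with per-residue flexibility, gated (open/closed) pocket
trajectories with a known open fraction, and multi-state ensembles for
clustering. All generators are deterministic under a fixed seed.

Atoms are 1-atom pseudo-residues with standard amino-acid names (a flag
builds 4-atom backbone pseudo-residues) so residue-level logic — occupancy
likelihood, triads, variant mapping, selections — is exercised without
sidechain modelling.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

from .alpha_geometry import fibonacci_sphere
from .structure_io import Ensemble, Structure

__all__ = [
    "FixtureSpec",
    "GroundTruth",
    "GenerationError",
    "make_fixture",
    "make_perturbed_ensemble",
    "make_gated_ensemble",
    "make_multistate_ensemble",
    "write_truth_tables",
]

# Residue-name cycle: includes R, G, D, E, H (and friends) so triad and
# variant logic downstream has material to find.
RESIDUE_CYCLE = ("ARG", "GLY", "ASP", "GLU", "HIS",
                 "SER", "ALA", "LYS", "TYR", "VAL")


class GenerationError(ValueError):
    """Raised when a fixture spec cannot produce a valid structure."""


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a planted-geometry fixture.

    kind : cup (pocket with a mouth), cavity (sealed void), shallow
        (draining depression), blob (convex cluster).
    shell_radius : Angstrom, inner shell radius (or blob radius).
    atom_radius : Angstrom, vdW radius given to every pseudo-atom.
    spacing : Angstrom, target lattice spacing; must be < 2 * atom_radius
        so the shell is sealed.
    aperture : mouth size as a fraction of the full solid angle; in (0, 1)
        for cup, 0 otherwise (defaults to 0.15 for cup, 0 for the rest).
    """

    kind: Literal["cup", "cavity", "shallow", "blob"]
    shell_radius: float = 8.0
    atom_radius: float = 1.8
    spacing: float = 2.6
    aperture: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("cup", "cavity", "shallow", "blob"):
            raise GenerationError(f"unknown fixture kind {self.kind!r}")
        if self.aperture is None:
            object.__setattr__(self, "aperture",
                               0.15 if self.kind == "cup" else 0.0)
        if self.spacing >= 2.0 * self.atom_radius:
            raise GenerationError(
                "spacing must be < 2 * atom_radius (shell would be unsealed)")
        if self.kind == "cup" and not 0.0 < self.aperture < 1.0:
            raise GenerationError("cup aperture must be in (0, 1)")
        if self.kind != "cup" and self.aperture != 0.0:
            raise GenerationError(f"{self.kind} fixture must have aperture 0")


@dataclass
class GroundTruth:
    """Planted truth accompanying a fixture or generated ensemble."""

    wall_atoms: np.ndarray = field(default_factory=lambda: np.array([], int))
    core_wall_atoms: np.ndarray = field(default_factory=lambda: np.array([], int))
    back_atoms: np.ndarray = field(default_factory=lambda: np.array([], int))
    mouth_expected: bool = False
    open_flags: np.ndarray | None = None
    sigma_per_residue: np.ndarray | None = None
    state_labels: np.ndarray | None = None


def _shell_points(radius: float, spacing: float) -> np.ndarray:
    """Near-uniform points on a sphere at roughly hexagonal ``spacing``."""
    n = max(12, int(math.ceil(4.0 * math.pi * radius ** 2
                              / (spacing ** 2 * math.sqrt(3.0) / 2.0))))
    return radius * fibonacci_sphere(n)


def _ball_lattice(radius: float, spacing: float) -> np.ndarray:
    """Cubic-lattice fill of a solid ball."""
    k = int(math.floor(radius / spacing))
    ax = spacing * np.arange(-k, k + 1)
    g = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), axis=-1).reshape(-1, 3)
    return g[np.einsum("ij,ij->i", g, g) <= radius ** 2]


def _build_structure(coords: np.ndarray, radius: float,
                     backbone: bool = False) -> Structure:
    """One pseudo-residue per site; names cycle through RESIDUE_CYCLE."""
    coords = np.asarray(coords, dtype=float)
    n_sites = len(coords)
    if backbone:
        # small rigid N/CA/C/O cluster around each site
        offsets = np.array([[0.0, 0.0, 0.0], [0.7, 0.0, 0.0],
                            [0.0, 0.7, 0.0], [0.0, 0.0, 0.7]])
        names = ["N", "CA", "C", "O"]
        elements = ["N", "C", "C", "O"]
    else:
        offsets = np.zeros((1, 3))
        names = ["CA"]
        elements = ["C"]
    per = len(offsets)
    all_coords = (coords[:, None, :] + offsets[None]).reshape(-1, 3)
    n = n_sites * per
    return Structure(
        serial=np.arange(1, n + 1),
        atom_names=np.array(names * n_sites, dtype=object),
        elements=np.array(elements * n_sites, dtype=object),
        res_names=np.array(
            [RESIDUE_CYCLE[s % len(RESIDUE_CYCLE)]
             for s in range(n_sites) for _ in range(per)], dtype=object),
        chain_ids=np.array(["A"] * n, dtype=object),
        res_seqs=np.repeat(np.arange(1, n_sites + 1), per),
        icodes=np.array([""] * n, dtype=object),
        coords=all_coords,
        occupancies=np.ones(n),
        radii=np.full(n, float(radius)),
    )


def make_fixture(spec: FixtureSpec, *,
                 backbone: bool = False) -> tuple[Structure, GroundTruth]:
    """Build a planted-geometry structure and its ground truth.

    cup/cavity are double concentric shells (the pocket/void is lined by
    the inner shell; the outer shell is the convex back); the cup has a
    cone of ``aperture`` solid-angle fraction removed around +z as the
    mouth. shallow is a convex lattice blob with a wide, shallow
    spherical bite; blob is the plain convex lattice ball.
    """
    R, s = spec.shell_radius, spec.spacing
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xF1]))

    if spec.kind in ("cup", "cavity"):
        inner = _shell_points(R, s)
        outer = _shell_points(R + s, s)
        if spec.kind == "cup":
            cos_theta = 1.0 - 2.0 * spec.aperture
            inner = inner[inner[:, 2] / R <= cos_theta]
            outer = outer[outer[:, 2] / (R + s) <= cos_theta]
        sites = np.vstack([inner, outer])
        n_inner = len(inner)
        truth = GroundTruth(
            wall_atoms=np.arange(n_inner),
            core_wall_atoms=np.flatnonzero(inner[:, 2] < 0.0),
            back_atoms=n_inner + np.flatnonzero(outer[:, 2] < 0.0),
            mouth_expected=(spec.kind == "cup"),
        )
    elif spec.kind == "blob":
        sites = _ball_lattice(R, s)
        truth = GroundTruth()
    else:  # shallow
        sites = _ball_lattice(R, s)
        bite_center = np.array([0.0, 0.0, 2.0 * R - 0.25 * R])
        d = np.linalg.norm(sites - bite_center, axis=1)
        sites = sites[d > R]
        truth = GroundTruth()

    # tiny deterministic displacement so lattice degeneracies never align
    sites = sites + rng.uniform(-0.05, 0.05, size=sites.shape)
    structure = _build_structure(sites, spec.atom_radius, backbone=backbone)
    if backbone:
        # truth indices refer to sites; expand to atom indices (4 per site)
        for name in ("wall_atoms", "core_wall_atoms", "back_atoms"):
            site_idx = getattr(truth, name)
            setattr(truth, name,
                    (4 * site_idx[:, None] + np.arange(4)[None]).ravel())
    return structure, truth


def make_perturbed_ensemble(
    base: Structure,
    sigma_per_residue: np.ndarray | list[float] | None = None,
    n_frames: int = 300,
    seed: int = 0,
    *,
    frame_spacing_ps: float = 100.0,
) -> tuple[Ensemble, GroundTruth]:
    """Ensemble of Gaussian-perturbed copies of ``base``.

    Frame ``f`` adds an independent isotropic Gaussian displacement with
    per-coordinate standard deviation ``sigma`` of the atom's residue. The
    default sampling design is 300 frames at 100 ps spacing (a 30 ns span).
    Expected RMSF of residue i is sigma_i * sqrt(3).
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if sigma_per_residue is None:
        sigma_per_residue = np.full(base.n_residues, 0.5)
    sigma = np.asarray(sigma_per_residue, dtype=float)
    if len(sigma) != base.n_residues:
        raise ValueError("sigma_per_residue length must equal residue count")
    if np.any(sigma < 0):
        raise ValueError("sigma must be non-negative")
    atom_sigma = sigma[base.atom_residue_indices()]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xE2]))
    noise = rng.standard_normal((n_frames, base.n_atoms, 3)) \
        * atom_sigma[None, :, None]
    coords = base.coords[None] + noise
    ens = Ensemble(topology=base, coords=coords,
                   frame_times=frame_spacing_ps * np.arange(n_frames))
    return ens, GroundTruth(sigma_per_residue=sigma)


def _mouth_plug_sites(spec: FixtureSpec) -> np.ndarray:
    """Lattice sites filling the cup's mouth cone (used as the plug)."""
    R, s = spec.shell_radius, spec.spacing
    cos_theta = 1.0 - 2.0 * spec.aperture
    sites = []
    for radius in (R, R + s):
        pts = _shell_points(radius, s)
        sites.append(pts[pts[:, 2] / radius > cos_theta])
    return np.vstack(sites)


def make_gated_ensemble(
    cup: Structure,
    truth: GroundTruth,
    spec: FixtureSpec,
    *,
    open_fraction: float | None = None,
    open_mask: np.ndarray | None = None,
    n_frames: int = 300,
    seed: int = 0,
    jitter: float = 0.03,
    mode: Literal["exact", "bernoulli"] = "exact",
) -> tuple[Ensemble, GroundTruth]:
    """Trajectory of a cup whose mouth opens and closes.

    A plug pseudo-residue of lattice atoms seals the mouth in closed
    frames and is displaced 15 Angstrom outward along the mouth axis in
    open frames. With ``mode="exact"`` the number of open frames is
    exactly round(open_fraction * n_frames), drawn without replacement;
    ``mode="bernoulli"`` flips an independent coin per frame. A small
    Gaussian jitter is applied to all atoms.
    """
    if spec.kind != "cup":
        raise GenerationError("gated ensembles require a cup fixture")
    if open_mask is None:
        if open_fraction is None or not 0.0 <= open_fraction <= 1.0:
            raise ValueError("open_fraction must be in [0, 1]")
        rng_sched = np.random.default_rng(np.random.SeedSequence([seed, 0xC3]))
        if mode == "exact":
            k = int(round(open_fraction * n_frames))
            open_flags = np.zeros(n_frames, dtype=bool)
            open_flags[rng_sched.permutation(n_frames)[:k]] = True
        else:
            open_flags = rng_sched.random(n_frames) < open_fraction
    else:
        open_flags = np.asarray(open_mask, dtype=bool)
        n_frames = len(open_flags)

    plug_sites = _mouth_plug_sites(spec)
    if len(plug_sites) == 0:
        raise GenerationError("aperture too small: empty plug")
    d_shell = np.linalg.norm(
        plug_sites[:, None, :] - cup.coords[None, :, :], axis=2)
    if d_shell.min() < 0.8:
        raise GenerationError("plug collides with shell atoms")

    # append the plug as one extra pseudo-residue (multiple C atoms)
    n_plug = len(plug_sites)
    plug_res = cup.n_residues + 1
    base = Structure(
        serial=np.concatenate([cup.serial,
                               cup.serial.max() + 1 + np.arange(n_plug)]),
        atom_names=np.concatenate([
            cup.atom_names,
            np.array([f"C{i + 1}" for i in range(n_plug)], dtype=object)]),
        elements=np.concatenate([cup.elements,
                                 np.array(["C"] * n_plug, dtype=object)]),
        res_names=np.concatenate([cup.res_names,
                                  np.array(["ALA"] * n_plug, dtype=object)]),
        chain_ids=np.concatenate([cup.chain_ids,
                                  np.array(["A"] * n_plug, dtype=object)]),
        res_seqs=np.concatenate([cup.res_seqs,
                                 np.full(n_plug, plug_res, dtype=int)]),
        icodes=np.concatenate([cup.icodes,
                               np.array([""] * n_plug, dtype=object)]),
        coords=np.vstack([cup.coords, plug_sites]),
        occupancies=np.concatenate([cup.occupancies, np.ones(n_plug)]),
        radii=np.concatenate([cup.radii, np.full(n_plug, spec.atom_radius)]),
    )

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xD4]))
    coords = np.repeat(base.coords[None], n_frames, axis=0)
    shift = np.array([0.0, 0.0, 15.0])
    coords[open_flags, cup.n_atoms:, :] += shift
    coords += rng.standard_normal(coords.shape) * jitter
    ens = Ensemble(topology=base, coords=coords,
                   frame_times=100.0 * np.arange(n_frames))
    out_truth = GroundTruth(
        wall_atoms=truth.wall_atoms.copy(),
        core_wall_atoms=truth.core_wall_atoms.copy(),
        back_atoms=truth.back_atoms.copy(),
        mouth_expected=True,
        open_flags=open_flags,
    )
    return ens, out_truth


def make_multistate_ensemble(
    base: Structure,
    k: int,
    *,
    inter_rmsd_target: float = 6.0,
    jitter: float = 0.3,
    frames_per_state: int = 50,
    seed: int = 0,
    selection_half: Literal["z"] = "z",
) -> tuple[Ensemble, GroundTruth]:
    """Ensemble drawn from ``k`` well-separated reference conformations.

    References are produced by a hinge motion of the half of the structure
    with z > 0: each non-reference state rotates that half about its own
    in-plane hinge axis (k-1 axes fanned through the xy-plane) by a common
    hinge angle, grown until all pairwise superposed RMSDs reach
    ``inter_rmsd_target``. Frames are references plus isotropic Gaussian
    jitter, in shuffled order; truth records the per-frame state label.
    """
    from .ensemble_analysis import _pairwise_rmsd   # local: avoid cycle at import
    from scipy.spatial.transform import Rotation

    if k < 1:
        raise ValueError("k must be >= 1")
    half = base.coords[:, 2] > 0.0
    if k > 1 and half.sum() < 3:
        raise GenerationError("too few atoms in the rotating half")

    def refs_for(angle_deg: float) -> np.ndarray:
        refs = np.repeat(base.coords[None], k, axis=0)
        for i in range(1, k):
            phi = math.pi * (i - 1) / max(1, k - 1)
            axis = np.array([math.cos(phi), math.sin(phi), 0.0])
            Rm = Rotation.from_rotvec(
                math.radians(angle_deg) * axis).as_matrix()
            refs[i, half] = base.coords[half] @ Rm.T
        return refs

    if k == 1:
        refs = base.coords[None].copy()
    else:
        refs = None
        for angle in np.arange(10.0, 180.0, 5.0):
            cand = refs_for(angle)
            D = _pairwise_rmsd(cand)
            iu = np.triu_indices(k, 1)
            if D[iu].min() >= inter_rmsd_target:
                refs = cand
                break
        if refs is None:
            raise GenerationError(
                f"inter-state RMSD target {inter_rmsd_target} A unreachable "
                f"for k={k} with this geometry")

    labels = np.repeat(np.arange(k), frames_per_state)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB5]))
    order = rng.permutation(len(labels))
    labels = labels[order]
    coords = refs[labels] + rng.standard_normal(
        (len(labels), base.n_atoms, 3)) * jitter
    ens = Ensemble(topology=base, coords=coords,
                   frame_times=100.0 * np.arange(len(labels)))
    return ens, GroundTruth(state_labels=labels)


def write_truth_tables(truth: GroundTruth, structure: Structure,
                       out_dir: str | Path, spec: FixtureSpec | None = None
                       ) -> list[Path]:
    """Emit truth tables (truth_wall.tsv, truth_frames.tsv,
    truth_sigma.tsv) and spec.json next to a generated fixture."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    res_idx = structure.atom_residue_indices()
    keys = structure.residue_keys()

    p = out / "truth_wall.tsv"
    with open(p, "w") as fh:
        fh.write("atom_index\tchain\tresseq\tresname\tis_core\tis_back\n")
        core = set(truth.core_wall_atoms.tolist())
        for a in truth.wall_atoms:
            c, rs, _, rn = keys[res_idx[a]]
            fh.write(f"{a}\t{c}\t{rs}\t{rn}\t{int(a in core)}\t0\n")
        for a in truth.back_atoms:
            c, rs, _, rn = keys[res_idx[a]]
            fh.write(f"{a}\t{c}\t{rs}\t{rn}\t0\t1\n")
    written.append(p)

    if truth.open_flags is not None:
        p = out / "truth_frames.tsv"
        with open(p, "w") as fh:
            fh.write("frame\topen\n")
            for f, o in enumerate(truth.open_flags):
                fh.write(f"{f}\t{int(o)}\n")
        written.append(p)

    if truth.sigma_per_residue is not None:
        p = out / "truth_sigma.tsv"
        with open(p, "w") as fh:
            fh.write("residue_index\tsigma_A\n")
            for i, s in enumerate(truth.sigma_per_residue):
                fh.write(f"{i}\t{s:.6f}\n")
        written.append(p)

    if spec is not None:
        p = out / "spec.json"
        with open(p, "w") as fh:
            json.dump({"kind": spec.kind, "shell_radius": spec.shell_radius,
                       "atom_radius": spec.atom_radius, "spacing": spec.spacing,
                       "aperture": spec.aperture, "seed": spec.seed}, fh,
                      indent=2)
        written.append(p)
    return written
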