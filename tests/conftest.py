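"""Shared fixtures: planted-geometry structures and fast configurations.

Session-scoped so the triangulation-heavy objects are built once.
"""

from __future__ import annotations

import numpy as np
import pytest

from alphapocket.alpha_geometry import GeometryConfig, detect_pockets
from alphapocket.synthetic_data import FixtureSpec, make_fixture

FAST = GeometryConfig(mc_samples=10_000, sphere_points=128)


@pytest.fixture(scope="session")
def fast_config() -> GeometryConfig:
    return FAST


@pytest.fixture(scope="session")
def cup():
    return make_fixture(FixtureSpec(kind="cup", seed=0))


@pytest.fixture(scope="session")
def cavity():
    return make_fixture(FixtureSpec(kind="cavity", seed=0))


@pytest.fixture(scope="session")
def shallow():
    return make_fixture(FixtureSpec(kind="shallow", seed=0))


@pytest.fixture(scope="session")
def blob():
    return make_fixture(FixtureSpec(kind="blob", seed=0))


@pytest.fixture(scope="session")
def cup_pockets(cup):
    structure, _ = cup
    return detect_pockets(structure, FAST)


def wall_residue_recall(structure, truth, pocket) -> float:
    """Fraction of planted wall residues recovered on the pocket wall."""
    ri = structure.atom_residue_indices()
    planted = set(ri[truth.wall_atoms].tolist())
    detected = set(ri[pocket.wall_atoms].tolist())
    return len(planted & detected) / len(planted)


def back_face_overlap(structure, truth, pocket) -> int:
    ri = structure.atom_residue_indices()
    back = set(ri[truth.back_atoms].tolist())
    detected = set(ri[pocket.wall_atoms].tolist())
    return len(back & detected)
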