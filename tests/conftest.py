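"""Shared fixtures: simulated runs at two sizes and synthetic structures."""

from __future__ import annotations

import numpy as np
import pytest

from mavemap.scoring import score_counts
from mavemap.synthetic import SimulationConfig, simulate_run


@pytest.fixture(scope="session")
def default_run():
    """Full-size default simulation (seed fixed for the whole session)."""
    return simulate_run(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def default_scores(default_run):
    return score_counts(default_run["lib_counts"], default_run["wt_counts"])


@pytest.fixture(scope="session")
def small_config():
    """Reduced problem size for fast unit tests."""
    return SimulationConfig(L=40, depth=200_000, n_clones=100_000, seed=11)


@pytest.fixture(scope="session")
def small_run(small_config):
    return simulate_run(small_config)


@pytest.fixture(scope="session")
def small_scores(small_run):
    return score_counts(small_run["lib_counts"], small_run["wt_counts"])


def make_pdb(atoms: list[tuple], models: int = 1) -> str:
    """Render ATOM records; each atom tuple is
    (serial, name, resname, chain, resid, x, y, z, element)."""
    lines = []
    multi = models > 1
    for m in range(models):
        if multi:
            lines.append(f"MODEL     {m + 1:4d}")
        for serial, name, resname, chain, resid, x, y, z, elem in atoms:
            lines.append(
                f"ATOM  {serial:5d} {name:^4s}{resname:>4s} {chain}{resid:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {elem:>2s}"
            )
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def glycine_pdb(tmp_path):
    """A single free glycine with idealized backbone geometry."""
    atoms = [
        (1, "N", "GLY", "A", 1, -0.970, 0.964, 0.000, "N"),
        (2, "CA", "GLY", "A", 1, 0.000, 0.000, 0.000, "C"),
        (3, "C", "GLY", "A", 1, 1.420, 0.530, 0.000, "C"),
        (4, "O", "GLY", "A", 1, 2.380, -0.230, 0.000, "O"),
    ]
    path = tmp_path / "gly.pdb"
    path.write_text(make_pdb(atoms))
    return path


def rigid_shift(coords: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Apply one random rotation + translation to an (N, 3) array."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
    t = rng.normal(0, 5.0, 3)
    return coords @ rot.T + t
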