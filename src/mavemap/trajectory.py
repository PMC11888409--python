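"""Post-processing of coordinate trajectories.

Computes the summary statistics used to interpret molecular-dynamics
runs of a protein: per-atom mean-square fluctuations relative to the
initial structure (with optional rigid-body superposition), Calpha
pair-distance statistics, and hydrogen-bond occupancy under a
distance + angle criterion.  Trajectories are read from multi-model PDB
files; atom selections use simple ``chain:resid[:atomname]`` strings.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser

HBOND_DISTANCE_MAX = 3.4  # donor-acceptor heavy-atom distance, Angstrom
HBOND_ANGLE_MIN = 120.0  # donor-hydrogen...acceptor angle, degrees (180 = linear)


@dataclass
class Trajectory:
    """Ordered coordinate frames over a fixed atom table.

    ``coords`` has shape (n_frames, n_atoms, 3); ``atoms`` columns are
    (name, resname, chain, resid, element).
    """

    coords: np.ndarray
    atoms: pd.DataFrame
    frame_interval: float | None = None  # e.g. ns per frame, metadata only

    def __post_init__(self) -> None:
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (frames, atoms, 3)")
        if self.coords.shape[0] < 1:
            raise ValueError("trajectory needs at least one frame")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError("atom table does not match coordinate array")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @classmethod
    def from_multimodel_pdb(cls, path: str | Path) -> "Trajectory":
        parser = PDBParser(QUIET=True)
        structure = parser.get_structure(Path(path).stem, str(path))
        models = list(structure)
        if not models:
            raise ValueError(f"no models in {path}")
        ref_atoms = []
        for chain in models[0]:
            for res in chain:
                for atom in res:
                    ref_atoms.append(
                        dict(name=atom.get_name(), resname=res.get_resname(),
                             chain=chain.id, resid=res.id[1], element=atom.element)
                    )
        n_atoms = len(ref_atoms)
        coords = np.empty((len(models), n_atoms, 3))
        for f, model in enumerate(models):
            frame = [a.coord for a in model.get_atoms()]
            if len(frame) != n_atoms:
                raise ValueError(
                    f"model {f} has {len(frame)} atoms, expected {n_atoms}"
                )
            coords[f] = np.array(frame)
        return cls(coords=coords, atoms=pd.DataFrame(ref_atoms))

    def select(self, spec: str) -> np.ndarray:
        """Atom indices for ``chain``, ``chain:resid`` or ``chain:resid:atom``."""
        parts = spec.split(":")
        mask = self.atoms["chain"] == parts[0]
        if len(parts) > 1 and parts[1]:
            mask &= self.atoms["resid"] == int(parts[1])
        if len(parts) > 2 and parts[2]:
            mask &= self.atoms["name"] == parts[2]
        idx = np.flatnonzero(mask.to_numpy())
        return idx

    def atom_index(self, spec: str) -> int:
        idx = self.select(spec)
        if len(idx) == 0:
            raise ValueError(f"no atom matches selection {spec!r}")
        if len(idx) > 1:
            raise ValueError(f"selection {spec!r} matches {len(idx)} atoms")
        return int(idx[0])


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation + translation of ``mobile`` onto ``reference``.

    Returns (R, t) such that mobile @ R.T + t best fits reference in the
    least-squares sense (Kabsch).
    """
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    h = (mobile - mc).T @ (reference - rc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.diag([1.0, 1.0, d])
    rot = vt.T @ flip @ u.T
    t = rc - rot @ mc
    return rot, t


def msf(
    traj: Trajectory,
    selection: str | np.ndarray = "CA",
    superpose: bool = True,
) -> pd.DataFrame:
    """Mean-square fluctuation of selected atoms relative to frame 0.

    MSF_i = mean over frames of |x_i(t) - x_i(0)|^2 (A^2).  With
    ``superpose`` each frame is first rigid-body aligned onto frame 0
    over the Calpha atoms, so global rotation/translation does not count
    as fluctuation.
    """
    if isinstance(selection, str) and ":" not in selection:
        idx = np.flatnonzero((traj.atoms["name"] == selection).to_numpy())
    elif isinstance(selection, str):
        idx = traj.select(selection)
    else:
        idx = np.asarray(selection, dtype=int)
    if len(idx) == 0:
        raise ValueError(f"selection {selection!r} matches no atoms")

    coords = traj.coords.copy()
    if superpose:
        ca = np.flatnonzero((traj.atoms["name"] == "CA").to_numpy())
        fit_idx = ca if len(ca) >= 3 else np.arange(coords.shape[1])
        ref = coords[0, fit_idx]
        for f in range(1, traj.n_frames):
            rot, t = kabsch_superpose(coords[f, fit_idx], ref)
            coords[f] = coords[f] @ rot.T + t

    disp = coords[:, idx, :] - coords[0, idx, :]
    values = (disp**2).sum(axis=2).mean(axis=0)
    out = traj.atoms.iloc[idx][["chain", "resid", "name"]].reset_index(drop=True)
    out["msf"] = values
    return out


def pair_distance_stats(
    traj: Trajectory, residue_a: str, residue_b: str, atom_name: str = "CA"
) -> tuple[float, float]:
    """Mean and population sd of the per-frame distance between one named
    atom of each residue (``residue`` as ``chain:resid``)."""
    try:
        ia = traj.atom_index(f"{residue_a}:{atom_name}")
    except ValueError as e:
        raise ValueError(f"residue {residue_a}: {e}") from None
    try:
        ib = traj.atom_index(f"{residue_b}:{atom_name}")
    except ValueError as e:
        raise ValueError(f"residue {residue_b}: {e}") from None
    d = np.linalg.norm(traj.coords[:, ia] - traj.coords[:, ib], axis=1)
    return float(d.mean()), float(d.std())


def hbond_occupancy(
    traj: Trajectory,
    donor: str,
    hydrogen: str,
    acceptor: str,
    d_max: float = HBOND_DISTANCE_MAX,
    angle_min: float = HBOND_ANGLE_MIN,
) -> float:
    """Fraction of frames with a donor-H...acceptor hydrogen bond.

    A frame counts when the donor-acceptor heavy-atom distance is at most
    ``d_max`` and the D-H...A angle (vertex at the hydrogen; 180 deg =
    linear) is at least ``angle_min``.  Boundary values are inclusive.
    The hydrogen must be present: no implicit-hydrogen geometry is
    inferred.
    """
    i_d = traj.atom_index(donor)
    i_h = traj.atom_index(hydrogen)
    i_a = traj.atom_index(acceptor)
    if traj.atoms.iloc[i_h]["element"] not in ("H", "D"):
        raise ValueError(f"selection {hydrogen!r} is not a hydrogen atom")

    xd, xh, xa = (traj.coords[:, i] for i in (i_d, i_h, i_a))
    dist = np.linalg.norm(xd - xa, axis=1)
    v1 = xd - xh
    v2 = xa - xh
    cosang = (v1 * v2).sum(axis=1) / (
        np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
    )
    angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    ok = (dist <= d_max) & (angle >= angle_min)
    return float(ok.mean())
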