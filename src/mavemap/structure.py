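"""Structure-based residue annotation.

Relative solvent accessibility (Shrake–Rupley ASA normalized by
theoretical Gly-X-Gly maxima), core/surface/intermediate burial classes,
interface residue detection between chains, interface-set overlaps, and
"painting" per-position map summaries onto a structure's B-factor column.

All calculations use heavy atoms only; hydrogens (absent from the crystal
structures this targets) are ignored when present.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio.PDB import PDBIO, PDBParser, Select, Structure
from Bio.PDB.SASA import ShrakeRupley
from scipy.spatial import cKDTree

#: theoretical maximum ASA (A^2) in a Gly-X-Gly tripeptide (Tien et al. 2013)
MAX_ASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

CORE_RSA = 0.20  # buried below this relative accessibility
SURFACE_RSA = 0.35  # exposed above this

INTERFACE_CUTOFF = 5.0  # Angstrom, heavy-atom distance

#: metal-coordinating residue positions (Cu/Zn site), configurable
DEFAULT_METAL_POSITIONS = frozenset({47, 49, 64, 72, 81, 84})
DEFAULT_DISULFIDE_POSITIONS = frozenset({58, 147})


def load_structure(source: str | Path | Structure.Structure) -> Structure.Structure:
    if isinstance(source, Structure.Structure):
        return source
    parser = PDBParser(QUIET=True)
    return parser.get_structure(Path(source).stem, str(source))


def _heavy_atoms(entity):
    return [a for a in entity.get_atoms() if a.element not in ("H", "D")]


def strip_hydrogens(structure: Structure.Structure) -> Structure.Structure:
    for residue in list(structure.get_residues()):
        for atom in list(residue):
            if atom.element in ("H", "D"):
                residue.detach_child(atom.get_id())
    return structure


def compute_rsa(
    structure,
    chain_id: str | None = None,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> pd.DataFrame:
    """Per-residue relative solvent accessibility.

    ASA comes from the Shrake–Rupley rolling-probe algorithm over heavy
    atoms; rsa = ASA / theoretical maximum for the residue type (may
    exceed 1 for extended conformations).  Burial class: core (rsa <
    0.20), surface (rsa > 0.35), intermediate otherwise.  Pass
    ``chain_id`` to restrict the output (the ASA context is whatever the
    structure contains: monomer vs complex is the caller's choice).
    """
    structure = strip_hydrogens(load_structure(source=structure).copy())
    if not _heavy_atoms(structure):
        raise ValueError("structure has no heavy atoms")
    sr = ShrakeRupley(probe_radius=probe_radius, n_points=n_points)
    sr.compute(structure, level="R")

    rows = []
    for model in structure:
        for chain in model:
            if chain_id is not None and chain.id != chain_id:
                continue
            for res in chain:
                if res.id[0] != " ":
                    continue  # skip waters / hetero residues
                name = res.get_resname()
                if name not in MAX_ASA:
                    raise ValueError(
                        f"no maximum-ASA reference for residue type {name!r} "
                        f"at {chain.id}:{res.id[1]}"
                    )
                rsa = res.sasa / MAX_ASA[name]
                if rsa < CORE_RSA:
                    sclass = "core"
                elif rsa > SURFACE_RSA:
                    sclass = "surface"
                else:
                    sclass = "intermediate"
                rows.append(dict(chain=chain.id, position=res.id[1], resname=name,
                                 asa=float(res.sasa), rsa=float(rsa), sclass=sclass))
        break  # first model only
    return pd.DataFrame(rows)


def interface_residues(
    structure, chain_a: str, chain_b: str, cutoff: float = INTERFACE_CUTOFF
) -> dict[str, set[int]]:
    """Residues of each chain with a heavy atom within ``cutoff`` of the
    other chain's heavy atoms."""
    structure = load_structure(structure)
    model = next(iter(structure))
    chains = {c.id: c for c in model}
    for cid in (chain_a, chain_b):
        if cid not in chains:
            raise ValueError(f"chain {cid!r} not in structure (has {sorted(chains)})")

    def atoms_of(cid):
        atoms = [
            a for a in _heavy_atoms(chains[cid])
            if a.get_parent().id[0] == " "
        ]
        coords = np.array([a.coord for a in atoms])
        resids = np.array([a.get_parent().id[1] for a in atoms])
        return coords, resids

    ca, ra = atoms_of(chain_a)
    cb, rb = atoms_of(chain_b)
    if cutoff <= 0 or len(ca) == 0 or len(cb) == 0:
        return {chain_a: set(), chain_b: set()}
    pairs = cKDTree(ca).query_ball_tree(cKDTree(cb), r=cutoff)
    out_a, out_b = set(), set()
    for i, js in enumerate(pairs):
        if js:
            out_a.add(int(ra[i]))
            out_b.update(int(rb[j]) for j in js)
    return {chain_a: out_a, chain_b: out_b}


def interface_set_overlap(
    homodimer: set[int], ccs_zn: set[int], ccs_apo: set[int]
) -> dict:
    """Venn membership of residues across three interface sets.

    Also reports the transient chaperone-binding set: residues at the
    Zn-bound chaperone interface but not the Zn-free one.
    """
    residues = sorted(homodimer | ccs_zn | ccs_apo)
    table = pd.DataFrame(
        {
            "position": residues,
            "homodimer": [r in homodimer for r in residues],
            "ccs_zn": [r in ccs_zn for r in residues],
            "ccs_apo": [r in ccs_apo for r in residues],
        }
    )
    regions = (
        table.groupby(["homodimer", "ccs_zn", "ccs_apo"]).size().rename("n").reset_index()
    )
    return {
        "table": table,
        "region_counts": regions,
        "transient_ccs": sorted(ccs_zn - ccs_apo),
    }


class _NotDisordered(Select):
    def accept_atom(self, atom):  # keep primary altlocs only
        return not atom.is_disordered() or atom.get_altloc() == "A"


def paint_structure(
    structure,
    positional_values: pd.Series,
    out_path: str | Path,
    offset: int = 0,
    sentinel: float = -99.0,
) -> int:
    """Write per-position scalars into the B-factor column of a PDB copy.

    ``positional_values`` is indexed by map position; structure residue
    number = map position + ``offset``.  Unmatched residues get the
    sentinel.  Returns the number of residues painted; raises if none
    match.
    """
    structure = load_structure(structure).copy()
    painted = 0
    for res in structure.get_residues():
        if res.id[0] != " ":
            continue
        pos = res.id[1] - offset
        value = positional_values.get(pos, np.nan)
        if np.isfinite(value):
            painted += 1
        else:
            value = sentinel
        for atom in res:
            atom.set_bfactor(float(value))
    if painted == 0:
        raise ValueError("no structure residues matched the positional values "
                         "(check the numbering offset)")
    io = PDBIO()
    io.set_structure(structure)
    io.save(str(out_path), select=_NotDisordered())
    return painted


def annotate_structure(
    structure,
    chain_id: str,
    partner_chains: dict[str, str] | None = None,
    metal_positions: set[int] = DEFAULT_METAL_POSITIONS,
    disulfide_positions: set[int] = DEFAULT_DISULFIDE_POSITIONS,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> pd.DataFrame:
    """Combined per-residue annotation table for one chain.

    ``partner_chains`` maps interface-set name -> partner chain id; each
    named set marks the residues of ``chain_id`` within 5 A of that
    partner.  Special sets (metal-binding, disulfide) come from configured
    position lists.
    """
    structure = load_structure(structure)
    ann = compute_rsa(structure, chain_id=chain_id,
                      probe_radius=probe_radius, n_points=n_points)
    sets: dict[str, set[int]] = {}
    for name, partner in (partner_chains or {}).items():
        sets[name] = interface_residues(structure, chain_id, partner)[chain_id]
    ann["interface_sets"] = [
        ",".join(sorted(n for n, s in sets.items() if p in s)) for p in ann["position"]
    ]
    special = []
    for p in ann["position"]:
        tags = []
        if p in metal_positions:
            tags.append("metal_binding")
        if p in disulfide_positions:
            tags.append("disulfide")
        special.append(",".join(tags))
    ann["special"] = special
    return ann
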