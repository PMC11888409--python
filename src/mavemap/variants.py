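"""Protein-level variant identities and saturation-mutagenesis enumeration.

A variant effect map is indexed by protein-level changes (position, wild-type
residue, substituted residue).  Libraries built with NNK degenerate codons
(N = A/C/G/T, K = G/T) reach a defined subset of amino-acid outcomes at each
codon; :func:`enumerate_variant_space` enumerates that subset exactly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum

from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.SeqUtils import seq3

STOP = "*"

_TABLE = unambiguous_dna_by_id[1]  # standard genetic code
_STOP_CODONS = set(_TABLE.stop_codons)

#: the 32 NNK codons (N = any base, K = G or T)
NNK_CODONS = tuple(
    a + b + c for a, b, c in itertools.product("ACGT", "ACGT", "GT")
)

_DNA = set("ACGT")


class VariantClass(str, Enum):
    missense = "missense"
    synonymous = "synonymous"
    nonsense = "nonsense"


def translate_codon(codon: str) -> str:
    """Translate one codon to a one-letter residue, ``*`` for stop."""
    codon = codon.upper()
    if codon in _STOP_CODONS:
        return STOP
    return _TABLE.forward_table[codon]


def _res3(aa: str) -> str:
    return "Ter" if aa == STOP else seq3(aa)


@dataclass(frozen=True, order=True)
class VariantDescriptor:
    """One protein-level change.

    position is 1-based along the protein; ``to_aa`` may be the stop
    symbol ``*``.  The class is fully determined by from/to residues.
    """

    position: int
    from_aa: str
    to_aa: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")

    @property
    def vclass(self) -> VariantClass:
        if self.to_aa == STOP:
            return VariantClass.nonsense
        if self.to_aa == self.from_aa:
            return VariantClass.synonymous
        return VariantClass.missense

    @property
    def hgvs_p(self) -> str:
        return f"p.{_res3(self.from_aa)}{self.position}{_res3(self.to_aa)}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hgvs_p


def parse_hgvs_p(label: str) -> tuple[int, str, str]:
    """Parse ``p.Ala4Val`` into ``(4, 'A', 'Val'->'V')`` one-letter form."""
    from Bio.SeqUtils import seq1

    body = label[2:] if label.startswith("p.") else label
    frm3, rest = body[:3], body[3:]
    i = 0
    while i < len(rest) and rest[i].isdigit():
        i += 1
    if i == 0:
        raise ValueError(f"cannot parse HGVS protein label {label!r}")
    pos = int(rest[:i])
    to3 = rest[i:]
    to1 = STOP if to3 in ("Ter", "*") else seq1(to3)
    return pos, seq1(frm3), to1


def split_codons(codon_sequence: str) -> list[str]:
    seq = "".join(codon_sequence.split()).upper()
    bad = set(seq) - _DNA
    if bad:
        raise ValueError(f"non-DNA characters in codon sequence: {sorted(bad)}")
    if len(seq) % 3:
        raise ValueError(f"sequence length {len(seq)} is not a multiple of 3")
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def enumerate_variant_space(L: int, codon_sequence: str) -> list[VariantDescriptor]:
    """All amino-acid outcomes reachable by NNK replacement of each codon.

    Parameters
    ----------
    L
        Protein length in residues, excluding the stop.
    codon_sequence
        The reference ORF of ``3*(L+1)`` nucleotides including the stop codon.

    Returns
    -------
    One descriptor per distinct ``(position, to_aa)`` outcome, positions
    1..L, classified as missense / synonymous / nonsense.
    """
    codons = split_codons(codon_sequence)
    if len(codons) != L + 1:
        raise ValueError(
            f"expected {L + 1} codons (L residues + stop), got {len(codons)}"
        )
    if codons[-1] not in _STOP_CODONS:
        raise ValueError(f"final codon {codons[-1]} is not a stop codon")
    for i, codon in enumerate(codons[:-1], start=1):
        if codon in _STOP_CODONS:
            raise ValueError(f"internal stop codon {codon} at position {i}")

    out: list[VariantDescriptor] = []
    for pos, ref_codon in enumerate(codons[:-1], start=1):
        ref_aa = translate_codon(ref_codon)
        seen: set[str] = set()
        for codon in NNK_CODONS:
            aa = translate_codon(codon)
            if aa not in seen:
                seen.add(aa)
                out.append(VariantDescriptor(pos, ref_aa, aa))
    return out


def protein_sequence(codon_sequence: str) -> str:
    """Translate an ORF (with terminal stop) to its residue string."""
    codons = split_codons(codon_sequence)
    return "".join(translate_codon(c) for c in codons if c not in _STOP_CODONS)
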