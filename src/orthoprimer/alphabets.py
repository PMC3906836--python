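"""Nucleotide/protein alphabets, IUPAC ambiguity codes and inosine.

The degenerate-primer alphabet is the four bases, the eleven IUPAC
ambiguity codes and ``I`` (inosine).  Inosine pairs with any natural
base, so for matching purposes it behaves like ``N``; it is kept as a
distinct symbol because synthesis cost and duplex stability differ and
the primer audit counts it separately.
"""

from __future__ import annotations

DNA_BASES = "ACGT"
GAP = "-"

# Amino acids accepted in protein records (20 canonical + X for unknown).
PROTEIN_RESIDUES = set("ACDEFGHIKLMNPQRSTVWYX")

IUPAC_TO_SET: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
    # Inosine: base-pairs with all four natural bases.
    "I": frozenset("ACGT"),
}

SET_TO_IUPAC: dict[frozenset[str], str] = {
    v: k for k, v in IUPAC_TO_SET.items() if k != "I"
}

PRIMER_ALPHABET = frozenset(IUPAC_TO_SET)

_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
    "I": "I",  # inosine complements to inosine (matches anything)
    GAP: GAP,
}


def complement(base: str) -> str:
    try:
        return _COMPLEMENT[base]
    except KeyError as exc:
        raise KeyError(f"no complement for {base!r}") from exc


def revcomp(seq: str) -> str:
    """Reverse complement of a (possibly degenerate) DNA string."""
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def is_dna(seq: str) -> bool:
    return all(c in "ACGTN-" for c in seq)


def looks_protein(seq: str) -> bool:
    """Heuristic alphabet sniff: any residue outside the DNA alphabet."""
    return any(c not in "ACGTN-U" for c in seq)
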