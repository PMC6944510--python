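"""Allele bookkeeping: complements, palindromes and canonical variant keys.

A variant is identified by chromosome, 1-based GRCh37 position and its
unordered allele pair, taken modulo strand (the pair and its reverse
complement map to the same key).  rsIDs are carried as metadata only;
joins never use them because annotation vintages differ across consortia.
"""

from __future__ import annotations

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
VALID_ALLELES = frozenset(COMPLEMENT)


def complement(allele: str) -> str:
    return COMPLEMENT[allele]


def is_palindromic(a1: str, a2: str) -> bool:
    """True for A/T and C/G pairs, whose strand cannot be inferred from alleles."""
    return COMPLEMENT.get(a1) == a2


def canonical_pair(a1: str, a2: str) -> tuple[str, str]:
    """Strand-insensitive representative of an unordered allele pair."""
    fwd = tuple(sorted((a1, a2)))
    rev = tuple(sorted((COMPLEMENT[a1], COMPLEMENT[a2])))
    return min(fwd, rev)


def variant_key(chrom: str, pos: int, a1: str, a2: str) -> str:
    a, b = canonical_pair(a1, a2)
    return f"{chrom}:{int(pos)}:{a}_{b}"
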