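"""Genetic-code tables shared by the codon simulator and the Ka/Ks estimator.

Everything here is derived once, at import, from the standard nuclear code
(NCBI translation table 1) as provided by Biopython.
"""

from __future__ import annotations

from itertools import product

from Bio.Data import CodonTable

_BASES = "TCAG"

_table = CodonTable.unambiguous_dna_by_id[1]

#: codon -> one-letter amino acid, sense codons only
CODON_AA: dict[str, str] = dict(_table.forward_table)

#: stop codons of the standard code
STOP_CODONS: frozenset[str] = frozenset(_table.stop_codons)

#: all 61 sense codons, in a fixed order
SENSE_CODONS: tuple[str, ...] = tuple(
    c for c in ("".join(p) for p in product(_BASES, repeat=3)) if c not in STOP_CODONS
)


def single_base_changes(codon: str, position: int) -> list[str]:
    """The three codons reachable from `codon` by one change at `position`."""
    return [
        codon[:position] + b + codon[position + 1 :]
        for b in _BASES
        if b != codon[position]
    ]


def synonymous_site_fraction(codon: str, position: int) -> float:
    """Fraction of the three possible changes at `position` that are synonymous.

    Changes creating a stop codon count as nonsynonymous, so the synonymous
    and nonsynonymous site fractions at a position always sum to 1.
    """
    aa = CODON_AA[codon]
    syn = sum(
        1
        for alt in single_base_changes(codon, position)
        if alt not in STOP_CODONS and CODON_AA[alt] == aa
    )
    return syn / 3.0


def codon_site_counts(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of a sense codon; sums to 3."""
    s = sum(synonymous_site_fraction(codon, i) for i in range(3))
    return s, 3.0 - s


#: precomputed (S, N) site counts per sense codon
SITE_COUNTS: dict[str, tuple[float, float]] = {c: codon_site_counts(c) for c in SENSE_CODONS}


def is_synonymous_change(codon_from: str, codon_to: str) -> bool:
    """True if two sense codons differing by one base encode the same residue."""
    return CODON_AA[codon_from] == CODON_AA[codon_to]
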