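"""Global protein alignment helpers (BLOSUM62, affine gaps) used by the
catalog labeling and the greedy OGG clustering."""

from __future__ import annotations

from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def global_alignment_stats(a: str, b: str) -> tuple[float, float, int]:
    """Align two protein sequences globally and summarize the alignment.

    Returns ``(score, identity, aligned_columns)`` where identity is
    identical positions over the gapless aligned columns, and
    aligned_columns counts positions where both sequences carry a residue.
    """
    aln = _aligner().align(a, b)[0]
    matches = 0
    aligned_cols = 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        aligned_cols += a1 - a0
        for x, y in zip(a[a0:a1], b[b0:b1]):
            if x == y:
                matches += 1
    identity = matches / aligned_cols if aligned_cols else 0.0
    return float(aln.score), identity, aligned_cols
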