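"""Homology-hit filtering, ASMT/COMT subfamily labeling, copy-number
tabulation, and ranking of subfamily-diagnostic alignment columns.

The catalog stage consumes tabular evidence from a protein-domain scan and a
similarity search (both already run externally), keeps genes with a passing
hit and a plausible protein length, labels candidates by their most similar
labeled reference, and produces the per-species copy-number table that feeds
the dosage statistics.  Divergence-driving alignment columns are ranked by
the mutual information between residue identity and subfamily label, with a
label-permutation null.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._align import global_alignment_stats


@dataclass(frozen=True)
class HitRecord:
    """One row of a homology-search hit table."""

    query_id: str
    source: str  # "domain_scan" | "similarity"
    evalue: float
    bitscore: float
    subject_id: str

    def __post_init__(self):
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        if self.source not in ("domain_scan", "similarity"):
            raise ValueError(f"unknown evidence source {self.source!r}")


def filter_candidates(
    hits: list[HitRecord],
    lengths: dict[str, int],
    evalue_max: float = 1e-5,
    len_min: int = 200,
    len_max: int = 600,
    require_both: bool = False,
) -> set[str]:
    """Genes with passing homology evidence and length within bounds.

    A gene passes on a hit with E-value <= `evalue_max` from either evidence
    source (union rule; `require_both` demands a passing hit from both the
    domain scan and the similarity search) and a protein length inside the
    closed interval [`len_min`, `len_max`].  Genes without a length entry are
    excluded with a warning.
    """
    passing_sources: dict[str, set[str]] = {}
    for hit in hits:
        if hit.evalue <= evalue_max:
            passing_sources.setdefault(hit.query_id, set()).add(hit.source)

    kept: set[str] = set()
    missing: list[str] = []
    for gene, sources in passing_sources.items():
        if require_both and sources != {"domain_scan", "similarity"}:
            continue
        if gene not in lengths:
            missing.append(gene)
            continue
        if len_min <= lengths[gene] <= len_max:
            kept.add(gene)
    if missing:
        warnings.warn(
            f"{len(missing)} gene(s) had passing hits but no length entry and "
            f"were excluded: {sorted(missing)[:5]}...",
            stacklevel=2,
        )
    return kept


def assign_subfamily(
    candidates: dict[str, str],
    references: dict[str, tuple[str, str]],
) -> pd.DataFrame:
    """Label candidate proteins by their best-matching labeled reference.

    `references` maps reference id -> (sequence, subfamily label).  Each
    candidate takes the subfamily of the reference with the highest global
    alignment score; ties break by higher percent identity, then by
    lexicographically smaller reference id, so the result is independent of
    reference input order.
    """
    if not references:
        raise ValueError("reference set is empty")
    labels = {lab for _, lab in references.values()}
    if not {"ASMT", "COMT"} <= labels:
        raise ValueError("need at least one reference per subfamily (ASMT and COMT)")

    rows = []
    for gene_id in sorted(candidates):
        seq = candidates[gene_id]
        best = None  # (score, identity, -ord ref) comparison tuple
        for ref_id in sorted(references):
            ref_seq, ref_label = references[ref_id]
            score, identity, _ = global_alignment_stats(seq, ref_seq)
            key = (score, identity)
            if best is None or key > best[0]:
                best = (key, ref_id, ref_label)
        (score, identity), ref_id, ref_label = best
        rows.append(
            {
                "gene_id": gene_id,
                "subfamily": ref_label,
                "best_reference": ref_id,
                "score": score,
                "identity": identity,
            }
        )
    return pd.DataFrame(rows)


def tabulate_copy_numbers(
    genes: pd.DataFrame,
    receptor_genes: pd.DataFrame | None = None,
    roster: list[str] | None = None,
    allow_unassigned: bool = False,
) -> pd.DataFrame:
    """Per-species ASMT/COMT (and optional receptor) copy-number table.

    `genes` needs columns ``species_id`` and ``subfamily``; `receptor_genes`
    needs ``species_id``.  Species in `roster` with no hits appear with
    zeros.  Unassigned subfamilies raise unless `allow_unassigned` (they are
    then dropped from the counts).
    """
    genes = genes.copy()
    bad = ~genes["subfamily"].isin(["ASMT", "COMT"])
    if bad.any():
        if not allow_unassigned:
            raise ValueError(
                f"{int(bad.sum())} gene(s) have unassigned subfamily; pass "
                "allow_unassigned=True to drop them"
            )
        genes = genes[~bad]

    species = sorted(set(genes["species_id"]).union(roster or []))
    counts = genes.groupby(["species_id", "subfamily"]).size().unstack(fill_value=0)
    table = pd.DataFrame({"species": species}).set_index("species")
    for col in ("ASMT", "COMT"):
        table[col.lower()] = counts[col] if col in counts else 0
    table = table.fillna(0).astype(int)
    table["total"] = table["asmt"] + table["comt"]
    if receptor_genes is not None:
        rec = receptor_genes.groupby("species_id").size()
        table["receptor"] = rec.reindex(table.index).fillna(0).astype(int)
    return table.reset_index()


# ---------------------------------------------------------------------------
# divergence-driving columns
# ---------------------------------------------------------------------------


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _column_mi(column: np.ndarray, labels: np.ndarray) -> float:
    """Plug-in mutual information (bits) between residues and labels."""
    n = len(column)
    h_label = _entropy(np.unique(labels, return_counts=True)[1])
    h_col = _entropy(np.unique(column, return_counts=True)[1])
    joint = Counter(zip(column, labels))
    h_joint = _entropy(np.array(list(joint.values()), float))
    mi = h_label + h_col - h_joint
    return max(mi, 0.0)


def rank_divergence_columns(
    msa: list[str],
    labels: list[str],
    n_permutations: int = 200,
    top_k: int | None = 13,
    seed: int | None = None,
) -> pd.DataFrame:
    """Rank alignment columns by residue↔subfamily mutual information.

    Gaps are treated as a 21st residue symbol.  `null_p` is the fraction of
    label permutations whose MI meets or exceeds the observed value.  Columns
    are ranked by MI descending, ties by smaller index; the `top_k` best are
    returned (all columns when `top_k` is None).  Column indices are 1-based
    and alignment-relative.
    """
    if len(set(labels)) < 2:
        raise ValueError("need at least two classes")
    counts = Counter(labels)
    if min(counts.values()) < 2:
        raise ValueError("need at least two sequences per label")
    lengths = {len(s) for s in msa}
    if len(lengths) != 1:
        raise ValueError("all sequences must have the same aligned length")

    mat = np.array([list(s) for s in msa])
    lab = np.array(labels)
    rng = np.random.default_rng(seed)
    perms = [rng.permutation(lab) for _ in range(n_permutations)]

    rows = []
    for j in range(mat.shape[1]):
        col = mat[:, j]
        mi = _column_mi(col, lab)
        if n_permutations > 0:
            null = np.array([_column_mi(col, p) for p in perms])
            null_p = float((null >= mi).mean())
        else:
            null_p = float("nan")
        rows.append({"column_index": j + 1, "mi_bits": mi, "null_p": null_p})
    df = pd.DataFrame(rows).sort_values(
        ["mi_bits", "column_index"], ascending=[False, True], kind="mergesort"
    )
    df["rank"] = np.arange(1, len(df) + 1)
    if top_k is not None:
        df = df.head(top_k)
    return df.reset_index(drop=True)
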