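"""Synthetic-data generators with recorded ground truth.

Every generator is a pure function of its spec and seed: rerunning with the
same arguments reproduces the output bit for bit.  The generators emulate the
input classes of the downstream analyses — multi-species copy-number tables,
codon-sequence pairs with target substitution rates, multi-variety pan-genomes
with planted orthologous gene groups (OGGs), Ks values from Gaussian mixtures,
labeled protein alignments with planted diagnostic columns, and FPKM
expression matrices with a subfamily shift — so that each stage can be tested
against known truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._codon import (
    CODON_AA,
    SENSE_CODONS,
    SITE_COUNTS,
    STOP_CODONS,
    single_base_changes,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# copy-number tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CopySimSpec:
    """Conditions for a multi-species ASMT/COMT copy-number table.

    `asmt_share` is the binomial allocation probability of a copy being ASMT;
    the binomial noise model forces the slopes-sum-to-one identity that the
    subfamily-vs-total regressions exhibit.  `receptor_mean`, when set, adds a
    melatonin-receptor (CAND2-like) count column, Poisson around a low mean
    with an optional weak dependence on the total copy number.
    """

    n_species: int = 1052
    total_range: tuple[int, int] = (2, 120)
    asmt_share: float = 0.6
    noise_model: str = "binomial"
    seed: int = 0
    receptor_mean: float | None = None
    receptor_slope: float = 0.0


def simulate_copy_number_table(spec: CopySimSpec) -> pd.DataFrame:
    """Draw a per-species copy-number table with ASMT + COMT = total.

    Totals are uniform on the inclusive `total_range`; ASMT counts are
    Binomial(total, asmt_share) and COMT is the remainder.  The generating
    share is recorded in ``df.attrs["truth"]``.
    """
    if not (0.0 < spec.asmt_share < 1.0):
        raise ValueError(f"asmt_share must be in (0, 1), got {spec.asmt_share}")
    lo, hi = spec.total_range
    if lo > hi or lo < 0:
        raise ValueError(f"invalid total_range {spec.total_range}")
    if spec.n_species < 1:
        raise ValueError("n_species must be >= 1")
    if spec.noise_model != "binomial":
        raise ValueError(f"unknown noise model {spec.noise_model!r}")

    rng = np.random.default_rng(spec.seed)
    total = rng.integers(lo, hi + 1, size=spec.n_species)
    asmt = rng.binomial(total, spec.asmt_share)
    df = pd.DataFrame(
        {
            "species": [f"sp{i:04d}" for i in range(spec.n_species)],
            "asmt": asmt,
            "comt": total - asmt,
            "total": total,
        }
    )
    if spec.receptor_mean is not None:
        lam = np.maximum(spec.receptor_mean + spec.receptor_slope * total, 0.05)
        df["receptor"] = rng.poisson(lam)
    df.attrs["truth"] = {"asmt_share": spec.asmt_share}
    return df


# ---------------------------------------------------------------------------
# codon pairs with target Ka / Ks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CodonPairSpec:
    """A pair of coding sequences with target NG86 Ka and Ks values."""

    n_codons: int = 500
    target_ks: float = 0.3
    target_ka: float = 0.06
    seed: int = 0


def _p_from_d(d: float) -> float:
    """Observed difference proportion whose Jukes–Cantor correction equals d."""
    return 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))


def simulate_codon_pair(spec: CodonPairSpec) -> tuple[str, str]:
    """Generate two diverged CDS strings whose expected NG86 estimates hit the targets.

    The ancestor is drawn uniformly over sense codons.  Differences are
    planted at distinct codons (at most one substitution per codon, classified
    exactly as synonymous or nonsynonymous from the ancestor) at the observed
    proportions p = (3/4)(1 − exp(−4d/3)) so that the Jukes–Cantor-corrected
    NG86 estimator inverts to the targets in expectation.  Substitutions that
    would create a stop codon are never proposed.  Each planted difference is
    assigned to one of the two lineages at random.
    """
    if spec.n_codons < 10:
        raise ValueError("n_codons must be >= 10")
    if spec.target_ks < 0 or spec.target_ka < 0:
        raise ValueError("target rates must be >= 0")

    rng = np.random.default_rng(spec.seed)
    codons = list(rng.choice(SENSE_CODONS, size=spec.n_codons))

    s_sites = sum(SITE_COUNTS[c][0] for c in codons)
    n_sites = sum(SITE_COUNTS[c][1] for c in codons)
    p_s = _p_from_d(spec.target_ks)
    p_n = _p_from_d(spec.target_ka)
    n_syn = round(p_s * s_sites)
    n_non = round(p_n * n_sites)
    if n_syn + n_non > spec.n_codons:
        raise ValueError(
            "targets too large: the required number of planted substitutions "
            f"({n_syn + n_non}) exceeds the number of codons ({spec.n_codons}); "
            "increase n_codons or lower the targets"
        )

    def options(codon: str, synonymous: bool) -> list[str]:
        aa = CODON_AA[codon]
        out = []
        for pos in range(3):
            for alt in single_base_changes(codon, pos):
                if alt in STOP_CODONS:
                    continue
                if (CODON_AA[alt] == aa) == synonymous:
                    out.append(alt)
        return out

    order = list(rng.permutation(spec.n_codons))
    seq_a = list(codons)
    seq_b = list(codons)
    remaining = {"syn": n_syn, "non": n_non}
    for idx in order:
        if remaining["syn"] == 0 and remaining["non"] == 0:
            break
        # prefer whichever class still needs more substitutions
        for kind in sorted(remaining, key=remaining.get, reverse=True):
            if remaining[kind] == 0:
                continue
            opts = options(codons[idx], synonymous=(kind == "syn"))
            if opts:
                alt = opts[rng.integers(len(opts))]
                if rng.random() < 0.5:
                    seq_a[idx] = alt
                else:
                    seq_b[idx] = alt
                remaining[kind] -= 1
                break
    if remaining["syn"] or remaining["non"]:
        raise ValueError(
            "could not place all planted substitutions; targets too large for "
            "this sequence composition"
        )
    return "".join(seq_a), "".join(seq_b)


# ---------------------------------------------------------------------------
# pan-genomes with planted OGGs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PanSimSpec:
    """A multi-variety pan-genome with planted orthologous gene groups.

    Core OGGs are present in every variety; each dispensable OGG is present
    in each variety independently with probability `occupancy_dist` (a scalar
    or one probability per dispensable OGG).  Copies within an OGG are mutated
    down to `within_identity`; distinct OGG ancestors are independent random
    sequences, so their pairwise identity sits near the random background
    (far below `between_identity`).
    """

    n_varieties: int = 10
    n_core: int = 10
    n_dispensable: int = 10
    occupancy_dist: float | tuple[float, ...] = 0.5
    within_identity: float = 0.98
    between_identity: float = 0.80
    protein_length: int = 250
    seed: int = 0


def simulate_pangenome(
    spec: PanSimSpec,
) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Generate pan-genome protein sequences plus the truth PAV matrix.

    Returns ``(records, truth)`` where records are ``(gene_id, variety,
    sequence)`` tuples and truth is a boolean OGG × variety DataFrame of the
    planted presence/absence draws.  Dispensable OGGs that happen to draw zero
    varieties stay in the truth matrix (occupancy 0) but emit no sequences.
    """
    if not (0.0 < spec.within_identity <= 1.0):
        raise ValueError("within_identity must be in (0, 1]")
    if not spec.within_identity > spec.between_identity:
        raise ValueError("within_identity must exceed between_identity")
    occ = spec.occupancy_dist
    occ_arr = np.full(spec.n_dispensable, occ) if np.isscalar(occ) else np.asarray(occ, float)
    if len(occ_arr) != spec.n_dispensable:
        raise ValueError("occupancy_dist length must equal n_dispensable")
    if spec.n_dispensable and not ((occ_arr > 0) & (occ_arr < 1)).all():
        raise ValueError("occupancy probabilities must lie in (0, 1)")

    rng = np.random.default_rng(spec.seed)
    varieties = [f"var{v:03d}" for v in range(spec.n_varieties)]
    n_ogg = spec.n_core + spec.n_dispensable
    ogg_ids = [f"OGG{g:04d}" for g in range(n_ogg)]

    aa = np.array(list(AMINO_ACIDS))
    ancestors = ["".join(rng.choice(aa, size=spec.protein_length)) for _ in range(n_ogg)]

    presence = np.ones((n_ogg, spec.n_varieties), dtype=bool)
    if spec.n_dispensable:
        presence[spec.n_core :] = (
            rng.random((spec.n_dispensable, spec.n_varieties)) < occ_arr[:, None]
        )

    n_mut = round((1.0 - spec.within_identity) * spec.protein_length)
    records: list[tuple[str, str, str]] = []
    for g, (ogg, anc) in enumerate(zip(ogg_ids, ancestors)):
        for v, variety in enumerate(varieties):
            if not presence[g, v]:
                continue
            seq = list(anc)
            if n_mut:
                for pos in rng.choice(spec.protein_length, size=n_mut, replace=False):
                    choices = [a for a in AMINO_ACIDS if a != seq[pos]]
                    seq[pos] = choices[rng.integers(len(choices))]
            records.append((f"{ogg}|{variety}", variety, "".join(seq)))

    truth = pd.DataFrame(presence, index=ogg_ids, columns=varieties)
    truth.attrs["truth"] = {"n_core": spec.n_core, "n_dispensable": spec.n_dispensable}
    return records, truth


# ---------------------------------------------------------------------------
# Ks mixtures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KsMixtureSpec:
    """Gaussian-mixture conditions for a synonymous-substitution distribution.

    `components` are (mean, sd, weight) triples in Ks units; weights are
    renormalized to sum to one before sampling.  Draws are untruncated —
    negative values are allowed — so component-mean recovery is unbiased.
    """

    components: tuple[tuple[float, float, float], ...]
    n_draws: int = 10000
    seed: int = 0


#: the three printed Poaceae ASMT/COMT Ks components (mean, sd, weight)
POACEAE_KS_COMPONENTS: tuple[tuple[float, float, float], ...] = (
    (0.339, 0.139, 0.542),
    (0.730, 0.162, 0.238),
    (1.131, 0.204, 0.169),
)


def simulate_ks_mixture(spec: KsMixtureSpec) -> np.ndarray:
    """i.i.d. draws from the renormalized Gaussian mixture."""
    if len(spec.components) < 1:
        raise ValueError("need at least one mixture component")
    means = np.array([c[0] for c in spec.components], float)
    sds = np.array([c[1] for c in spec.components], float)
    weights = np.array([c[2] for c in spec.components], float)
    if (sds <= 0).any():
        raise ValueError("component sds must be > 0")
    if (weights <= 0).any():
        raise ValueError("component weights must be > 0")
    weights = weights / weights.sum()
    rng = np.random.default_rng(spec.seed)
    idx = rng.choice(len(means), size=spec.n_draws, p=weights)
    return rng.normal(means[idx], sds[idx])


# ---------------------------------------------------------------------------
# labeled alignments with planted diagnostic columns
# ---------------------------------------------------------------------------


def simulate_labeled_alignment(
    n_per_class: int,
    length: int,
    diagnostic_columns: set[int] | list[int],
    seed: int = 0,
    leakage: float = 0.0,
) -> tuple[list[str], list[str]]:
    """A two-class protein MSA with class-diagnostic columns planted.

    Non-diagnostic columns share one residue distribution across classes
    (a dominant residue at 70%, the rest uniform), so they carry no label
    signal.  Each diagnostic column takes one residue in class ASMT and a
    different one in class COMT (the first such column uses W/F, the residue
    pair behind the key ASMT-vs-COMT site); `leakage` is the per-sequence
    probability of carrying the other class's residue.  Columns are 1-based.
    """
    if n_per_class < 2:
        raise ValueError("n_per_class must be >= 2")
    diag = sorted(set(int(c) for c in diagnostic_columns))
    if diag and (diag[0] < 1 or diag[-1] > length):
        raise ValueError("diagnostic columns must lie within 1..length")
    if not (0.0 <= leakage < 0.5):
        raise ValueError("leakage must be in [0, 0.5)")

    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    n_total = 2 * n_per_class
    cols = np.empty((length, n_total), dtype="<U1")
    for j in range(length):
        dominant = rng.choice(aa)
        probs = np.full(len(aa), 0.3 / (len(aa) - 1))
        probs[AMINO_ACIDS.index(dominant)] = 0.7
        cols[j] = rng.choice(aa, size=n_total, p=probs)

    pair_pool = [("W", "F"), ("K", "E"), ("L", "R"), ("G", "D"), ("S", "P"),
                 ("A", "T"), ("V", "N"), ("I", "Q"), ("Y", "H"), ("C", "M"),
                 ("F", "W"), ("E", "K"), ("R", "L"), ("D", "G"), ("P", "S")]
    for i, col in enumerate(diag):
        res_a, res_b = pair_pool[i % len(pair_pool)]
        values = np.array([res_a] * n_per_class + [res_b] * n_per_class)
        flip = rng.random(n_total) < leakage
        swapped = np.where(values == res_a, res_b, res_a)
        cols[col - 1] = np.where(flip, swapped, values)

    msa = ["".join(cols[:, s]) for s in range(n_total)]
    labels = ["ASMT"] * n_per_class + ["COMT"] * n_per_class
    return msa, labels


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------


def simulate_expression_matrix(
    n_asmt: int,
    n_comt: int,
    n_samples: int,
    comt_shift: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Log-normal FPKM matrix (genes × samples) with a COMT log-scale shift.

    Gene base levels are N(1, 0.5) on the natural-log scale, sample noise is
    N(0, 1); COMT genes get `comt_shift` added to their log mean.  Returns
    the FPKM table and a gene → subfamily label Series.
    """
    if min(n_asmt, n_comt, n_samples) < 1:
        raise ValueError("all counts must be >= 1")
    rng = np.random.default_rng(seed)
    genes = [f"ASMT{i:03d}" for i in range(n_asmt)] + [f"COMT{i:03d}" for i in range(n_comt)]
    labels = pd.Series(["ASMT"] * n_asmt + ["COMT"] * n_comt, index=genes, name="subfamily")
    base = rng.normal(1.0, 0.5, size=len(genes))
    base[n_asmt:] += comt_shift
    log_fpkm = base[:, None] + rng.normal(0.0, 1.0, size=(len(genes), n_samples))
    fpkm = pd.DataFrame(
        np.exp(log_fpkm), index=genes, columns=[f"sample{j:03d}" for j in range(n_samples)]
    )
    return fpkm, labels
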