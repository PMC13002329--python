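"""Pairwise Ka/Ks by the Nei–Gojobori (1986) method, Ks mixture decomposition,
and Ks-based divergence dating.

The NG86 estimator counts synonymous and nonsynonymous sites per codon from
per-position degeneracy (changes creating stop codons count as nonsynonymous,
so S + N = 3 per codon), classifies observed differences by averaging over all
equally weighted substitution pathways (pathways through stop codons are
excluded), and corrects the difference proportions for multiple hits with the
Jukes–Cantor formula d = −(3/4)·ln(1 − (4/3)p).

Ks distributions are decomposed into Gaussian mixtures with the component
count selected by BIC; the dominant mixture peaks date whole-genome
duplication events via T = Ks / (2·rate), with the plant nuclear default
rate of 6.5 × 10⁻⁹ substitutions/site/year.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
from Bio.Seq import Seq
from sklearn.mixture import GaussianMixture

from ._codon import CODON_AA, SITE_COUNTS, STOP_CODONS


# ---------------------------------------------------------------------------
# codon alignments
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CodonAlignment:
    """Two gapped CDS strings whose gaps mirror a protein alignment."""

    cds_a: str
    cds_b: str
    n_complete_codon_pairs: int


def project_codon_alignment(
    protein_alignment: tuple[str, str], cds1: str, cds2: str
) -> CodonAlignment:
    """Thread two coding sequences onto their aligned protein pair.

    Each aligned residue maps to its codon; protein gaps become 3-base codon
    gaps.  A trailing stop codon on either CDS is trimmed.  Raises ValueError
    if a CDS length is not a multiple of 3 or its translation does not match
    the ungapped protein.
    """
    prot_a, prot_b = protein_alignment
    if len(prot_a) != len(prot_b):
        raise ValueError("aligned protein strings must have equal length")

    def codons_of(cds: str, prot_gapped: str) -> list[str]:
        cds = cds.upper()
        if len(cds) % 3 != 0:
            raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        if codons and codons[-1] in STOP_CODONS:
            codons = codons[:-1]
        prot = prot_gapped.replace("-", "")
        translated = str(Seq("".join(codons)).translate())
        if translated != prot:
            raise ValueError(
                "CDS translation does not match the ungapped aligned protein"
            )
        return codons

    codons1 = codons_of(cds1, prot_a)
    codons2 = codons_of(cds2, prot_b)

    out_a, out_b = [], []
    i = j = 0
    for res_a, res_b in zip(prot_a, prot_b):
        if res_a == "-":
            out_a.append("---")
        else:
            out_a.append(codons1[i])
            i += 1
        if res_b == "-":
            out_b.append("---")
        else:
            out_b.append(codons2[j])
            j += 1
    n_complete = sum(
        1 for a, b in zip(out_a, out_b) if "-" not in a and "-" not in b
    )
    return CodonAlignment("".join(out_a), "".join(out_b), n_complete)


# ---------------------------------------------------------------------------
# NG86
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KaKsResult:
    """Per-pair NG86 estimates; `undefined_reason` flags saturation etc."""

    ka: float | None
    ks: float | None
    ratio: float | None
    coverage: float
    s_sites: float = 0.0
    n_sites: float = 0.0
    sd: float = 0.0
    nd: float = 0.0
    undefined_reason: str | None = None


def _pathway_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Mean (synonymous, nonsynonymous) difference counts between two sense
    codons, averaged over all substitution pathways with equal weight.

    Pathways passing through a stop codon are excluded; if every pathway is
    blocked (cannot happen between sense codons of the standard code for
    <=3 differences, but guarded anyway) all pathways are used.
    """
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order: tuple[int, ...]) -> tuple[float, float] | None:
        sd = nd = 0
        cur = codon_a
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                return None
            if CODON_AA[cur] == CODON_AA[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        return sd, nd

    results = [walk(order) for order in permutations(diff_pos)]
    valid = [r for r in results if r is not None]
    if not valid:  # pragma: no cover - unreachable for sense endpoints
        valid = [walk_all for walk_all in results if walk_all is not None] or [
            (0.0, float(len(diff_pos)))
        ]
    sd = sum(r[0] for r in valid) / len(valid)
    nd = sum(r[1] for r in valid) / len(valid)
    return sd, nd


def jukes_cantor(p: float) -> float | None:
    """JC69 multiple-hit correction; None when saturated (p >= 3/4)."""
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86_kaks(aln: CodonAlignment | tuple[str, str]) -> KaKsResult:
    """Nei–Gojobori Ka/Ks for one aligned codon pair.

    Accepts a :class:`CodonAlignment` or a plain pair of equal-length gapped
    CDS strings (gaps in multiples of 3).  Codon pairs containing a gap,
    an ambiguous base, or a stop codon are skipped entirely (neither sites
    nor differences counted).  Coverage is complete codon pairs over the
    codon count of the shorter ungapped CDS.
    """
    if isinstance(aln, CodonAlignment):
        cds_a, cds_b = aln.cds_a, aln.cds_b
    else:
        cds_a, cds_b = aln
    if len(cds_a) != len(cds_b):
        raise ValueError("aligned CDS strings must have equal length")
    if len(cds_a) % 3 != 0:
        raise ValueError("aligned CDS length must be a multiple of 3")

    s_sites = n_sites = 0.0
    sd = nd = 0.0
    n_complete = 0
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i : i + 3], cds_b[i : i + 3]
        if ca not in CODON_AA or cb not in CODON_AA:
            continue
        n_complete += 1
        sa, na = SITE_COUNTS[ca]
        sb, nb = SITE_COUNTS[cb]
        s_sites += (sa + sb) / 2.0
        n_sites += (na + nb) / 2.0
        dsd, dnd = _pathway_counts(ca, cb)
        sd += dsd
        nd += dnd

    if n_complete < 1:
        raise ValueError("alignment contains no complete codon pair")
    len_a = sum(1 for i in range(0, len(cds_a), 3) if "-" not in cds_a[i : i + 3])
    len_b = sum(1 for i in range(0, len(cds_b), 3) if "-" not in cds_b[i : i + 3])
    coverage = n_complete / min(len_a, len_b)

    p_s = sd / s_sites if s_sites > 0 else 0.0
    p_n = nd / n_sites if n_sites > 0 else 0.0
    ks = jukes_cantor(p_s)
    ka = jukes_cantor(p_n)
    if ks is None or ka is None:
        return KaKsResult(
            ka, ks, None, coverage, s_sites, n_sites, sd, nd, "saturation"
        )
    if ks == 0.0:
        return KaKsResult(
            ka, ks, None, coverage, s_sites, n_sites, sd, nd, "ks_zero"
        )
    return KaKsResult(ka, ks, ka / ks, coverage, s_sites, n_sites, sd, nd, None)


# ---------------------------------------------------------------------------
# Ks mixture decomposition
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GMMFit:
    """BIC-selected 1-D Gaussian mixture fit of a Ks distribution.

    `components` are (mean, sd, weight) sorted by descending weight;
    `global_peak` is the argmax of the mixture density on a uniform grid
    over the data range — the quantity quoted as "the Ks peak", distinct
    from the nearest component mean.
    """

    components: tuple[tuple[float, float, float], ...]
    selected_k: int
    bic_by_k: tuple[float, ...]
    global_peak: float

    @property
    def means(self) -> tuple[float, ...]:
        return tuple(c[0] for c in self.components)

    @property
    def weights(self) -> tuple[float, ...]:
        return tuple(c[2] for c in self.components)


def filter_and_fit_ks(
    pairs,
    min_coverage: float = 0.75,
    k_range: tuple[int, int] = (1, 6),
    n_init: int = 10,
    seed: int | None = None,
    grid_points: int = 2001,
) -> GMMFit:
    """Filter Ks values by alignment coverage and fit Gaussian mixtures.

    `pairs` may be a list of :class:`KaKsResult` (pairs with coverage below
    `min_coverage` or an undefined Ks are dropped) or a plain array of Ks
    values (used as-is).  Mixtures with k in `k_range` are fit by EM with
    `n_init` k-means-initialized restarts; the k minimizing
    BIC = −2·logL + (3k−1)·ln(n) is selected.
    """
    if len(pairs) and isinstance(pairs[0], KaKsResult):
        ks_values = np.array(
            [
                r.ks
                for r in pairs
                if r.ks is not None and r.coverage >= min_coverage
            ],
            float,
        )
    else:
        ks_values = np.asarray(pairs, float)
    if len(ks_values) < 20:
        raise ValueError(
            f"need >= 20 retained Ks values, got {len(ks_values)}"
        )
    if np.ptp(ks_values) == 0:
        raise ValueError("all retained Ks values are identical")

    x = ks_values[:, None]
    k_lo, k_hi = k_range
    fits, bics = [], []
    for k in range(k_lo, k_hi + 1):
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            n_init=n_init,
            init_params="kmeans",
            reg_covar=1e-6,
            tol=1e-6,
            max_iter=500,
            random_state=None if seed is None else int(seed),
        )
        gm.fit(x)
        if not np.isfinite(gm.lower_bound_):
            raise RuntimeError(f"EM diverged for k={k}")
        fits.append(gm)
        bics.append(float(gm.bic(x)))

    best = int(np.argmin(bics))
    gm = fits[best]
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.reshape(-1))
    weights = gm.weights_
    order = np.argsort(weights)[::-1]
    components = tuple(
        (float(means[i]), float(sds[i]), float(weights[i])) for i in order
    )

    grid = np.linspace(ks_values.min(), ks_values.max(), grid_points)
    density = np.zeros_like(grid)
    for mu, sd, w in components:
        density += w * np.exp(-0.5 * ((grid - mu) / sd) ** 2) / (sd * math.sqrt(2 * math.pi))
    peak = float(grid[np.argmax(density)])

    return GMMFit(components, best + k_lo, tuple(bics), peak)


# ---------------------------------------------------------------------------
# divergence dating
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DivergenceTime:
    """Ks-based divergence age in million years, linear in Ks."""

    t: float
    rate: float = 6.5e-9


def divergence_time(ks: float, rate: float = 6.5e-9) -> DivergenceTime:
    """T = [Ks / (2·rate)] × 10⁻⁶ million years."""
    if ks < 0:
        raise ValueError("ks must be >= 0")
    if rate <= 0:
        raise ValueError("rate must be > 0")
    return DivergenceTime(t=ks / (2.0 * rate) * 1e-6, rate=rate)
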