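"""Pan-genome orthologous gene groups: greedy identity clustering, PAV
matrices, occupancy classes, openness curves, and the power-law fit.

Clustering follows the greedy incremental scheme of CD-HIT: sequences sorted
by length descending each seed a new cluster or join the first cluster whose
representative they match at >= 95% identity with >= 90% coverage (both
configurable).  Identity is identical positions over the gapless columns of
a global BLOSUM62 alignment; coverage is those columns over the shorter
sequence's length.  Openness is measured by the mean number of new OGGs
contributed by the N-th variety over random permutations, and modeled by the
Tettelin-style power law n = k·N^−a.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from ._align import global_alignment_stats


@dataclass
class OGG:
    """One orthologous gene group: members plus the longest representative."""

    ogg_id: str
    representative_id: str
    members: list[str]


@dataclass
class OGGSet:
    """A clustering of pan-genome sequences into OGGs."""

    clusters: list[OGG]
    sequences: dict[str, str]

    def __len__(self) -> int:
        return len(self.clusters)


def greedy_cluster(
    sequences: dict[str, str],
    identity_min: float = 0.95,
    coverage_min: float = 0.90,
    coverage_mode: str = "shorter",
    best_match: bool = False,
) -> OGGSet:
    """Greedy incremental clustering at identity/coverage thresholds.

    Sequences are processed longest first (ties by lexicographic id); each
    joins the first existing cluster whose representative it matches (or the
    best-identity match with `best_match`), otherwise it seeds a new cluster.
    The seed of each cluster is its longest member and stays representative.
    """
    if not sequences:
        raise ValueError("empty input")
    if len(set(sequences)) != len(sequences):
        raise ValueError("duplicate sequence ids")
    for sid, seq in sequences.items():
        if not seq:
            raise ValueError(f"empty sequence for {sid!r}")
    if coverage_mode not in ("shorter", "longer", "query"):
        raise ValueError(f"unknown coverage_mode {coverage_mode!r}")

    order = sorted(sequences, key=lambda s: (-len(sequences[s]), s))
    clusters: list[OGG] = []
    for sid in order:
        seq = sequences[sid]
        chosen = None
        chosen_identity = -1.0
        for cluster in clusters:
            rep = sequences[cluster.representative_id]
            _, identity, aligned_cols = global_alignment_stats(seq, rep)
            if coverage_mode == "shorter":
                denom = min(len(seq), len(rep))
            elif coverage_mode == "longer":
                denom = max(len(seq), len(rep))
            else:
                denom = len(seq)
            coverage = aligned_cols / denom
            if identity >= identity_min and coverage >= coverage_min:
                if not best_match:
                    chosen = cluster
                    break
                if identity > chosen_identity:
                    chosen, chosen_identity = cluster, identity
        if chosen is None:
            clusters.append(OGG(f"OGG{len(clusters):04d}", sid, [sid]))
        else:
            chosen.members.append(sid)
    return OGGSet(clusters, dict(sequences))


def build_pav_matrix(oggs: OGGSet, variety_of_gene: dict[str, str]) -> pd.DataFrame:
    """Boolean OGG × variety presence matrix (>=1 member from the variety)."""
    varieties = sorted(set(variety_of_gene.values()))
    data = {}
    for cluster in oggs.clusters:
        present = set()
        for member in cluster.members:
            if member not in variety_of_gene:
                raise KeyError(f"member {member!r} has no variety mapping")
            present.add(variety_of_gene[member])
        data[cluster.ogg_id] = [v in present for v in varieties]
    return pd.DataFrame.from_dict(data, orient="index", columns=varieties)


def classify_occupancy(pav: pd.DataFrame) -> pd.DataFrame:
    """Occupancy class per OGG: Core (=100%), Shell [90%,100%),
    SoftCore [10%,90%), Cloud (<10%); Dispensable = not Core."""
    if pav.shape[1] < 1:
        raise ValueError("need >= 1 variety")
    occupancy = pav.mean(axis=1)

    def classify(occ: float) -> str:
        if occ == 1.0:
            return "Core"
        if occ >= 0.9:
            return "Shell"
        if occ >= 0.1:
            return "SoftCore"
        return "Cloud"

    out = pd.DataFrame(
        {
            "occupancy": occupancy,
            "occupancy_class": occupancy.map(classify),
        }
    )
    out["dispensable"] = out["occupancy_class"] != "Core"
    return out


def openness_curve(
    pav: pd.DataFrame, n_iter: int = 100, seed: int | None = None
) -> pd.DataFrame:
    """Mean number of new OGGs first observed in the N-th sampled variety.

    Each iteration draws a uniform random permutation of the varieties
    (sampling without replacement); the value at N is the count of OGGs whose
    first occurrence along the permutation is at position N, averaged over
    iterations.
    """
    n_var = pav.shape[1]
    if n_var < 2:
        raise ValueError("need >= 2 varieties")
    presence = pav.to_numpy(bool)
    rng = np.random.default_rng(seed)
    totals = np.zeros(n_var)
    for _ in range(n_iter):
        perm = rng.permutation(n_var)
        first = np.argmax(presence[:, perm], axis=1)
        # OGGs absent everywhere would spuriously report 0; a PAV row is
        # never all-false, so argmax is the true first occurrence.
        totals += np.bincount(first, minlength=n_var)
    return pd.DataFrame(
        {"N": np.arange(1, n_var + 1), "new_oggs": totals / n_iter}
    )


@dataclass(frozen=True)
class PowerLawFit:
    """Fit of the openness law n = k·N^−a with pseudo-R² on the original scale."""

    k: float
    a: float
    r2: float


def fit_power_law(curve: pd.DataFrame, min_n: int = 1) -> PowerLawFit:
    """Nonlinear least squares of n = k·N^−a on the original scale.

    The fit is initialized from the log-log linear regression.  Points with
    nonpositive n are excluded with a warning; fewer than 3 usable points is
    an error.  Pseudo-R² = 1 − SSres/SStot on the original scale.
    """
    n_samples = np.asarray(curve["N"], float)
    new = np.asarray(curve["new_oggs"], float)
    usable = (new > 0) & (n_samples >= min_n)
    if (~usable & (n_samples >= min_n)).any():
        warnings.warn("excluding points with nonpositive new-OGG counts", stacklevel=2)
    x, y = n_samples[usable], new[usable]
    if len(x) < 3:
        raise ValueError("need >= 3 usable points to fit the power law")

    slope, intercept = np.polyfit(np.log(x), np.log(y), 1)
    k0, a0 = float(np.exp(intercept)), float(-slope)
    popt, _ = curve_fit(
        lambda n, k, a: k * n ** (-a), x, y, p0=(max(k0, 1e-9), a0), maxfev=20000
    )
    k_fit, a_fit = float(popt[0]), float(popt[1])
    resid = y - k_fit * x ** (-a_fit)
    sstot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / sstot if sstot > 0 else 1.0
    return PowerLawFit(k_fit, a_fit, r2)
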