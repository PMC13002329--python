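# dosagebal

Statistical toolkit for studying **gene-dosage balance in the plant
ASMT/COMT methyltransferase family** — the rate-limiting enzymes of
melatonin biosynthesis — through copy-number variation (CNV), pan-genome
orthologous gene groups (OGGs), and molecular-evolution statistics.

It is aimed at comparative genomicists asking how a two-subfamily enzyme
family partitions its copies: as the total ASMT+COMT copy number grows
across species, does the ancestral, less-active ASMT subfamily expand
faster than the catalytically efficient COMT subfamily, and how do
polyploidy and purifying selection shape that pattern?

## What it computes

**Dosage statistics.** For a per-species table of subfamily counts with
ASMT + COMT = total, the package fits the OLS regressions
ASMT ~ total and COMT ~ total. Because the two responses sum to the
regressor, the slopes satisfy β_ASMT + β_COMT = 1 exactly; the slope ratio
β_ASMT/β_COMT summarizes which subfamily absorbs copy-number growth.
Species are split into high/low-copy groups by one-dimensional k-means
(k = 2, deterministic extreme-value initialization — a provable threshold
rule), and subfamily proportions are compared between groups by Welch's
t-test and the Mann–Whitney U test. Receptor-vs-enzyme coordination is
measured by Spearman's ρ between CAND2-like receptor counts and the family
total.

**Pan-genome OGGs.** Proteins from many varieties are clustered by the
greedy incremental rule of CD-HIT (identity ≥ 95%, coverage ≥ 90%, longest
sequence as representative), giving an OGG × variety presence/absence
(PAV) matrix. OGGs are classified as Core (100% of varieties),
Shell [90%, 100%), SoftCore [10%, 90%), or Cloud (< 10%). Pan-genome
openness is the mean count of new OGGs contributed by the N-th variety
over random orderings, modeled by the power law *n = k·N^−a*.

**Molecular evolution.** Pairwise Ka/Ks by the Nei–Gojobori (1986) method
with Jukes–Cantor correction; Ks distributions decomposed into Gaussian
mixtures with the component count chosen by BIC; mixture peaks converted to
divergence dates by *T* = Ks / (2 × 6.5 × 10⁻⁹) × 10⁻⁶ million years.

**Synteny.** Collinear blocks chained from homologous gene pairs by
dynamic programming (monotone ranks, bounded gaps, both orientations),
duplication origins classified per gene (WGD/segmental > tandem >
proximal > dispersed > singleton), and cross-genome synteny networks with
connected-component communities.

**Synthetic data.** Every input class can be generated with recorded
ground truth — binomially allocated copy tables, codon pairs with target
Ka/Ks, pan-genomes with planted OGGs and occupancies, Gaussian-mixture Ks
draws, labeled alignments with planted diagnostic columns, and shifted
FPKM matrices — so the whole pipeline is testable without any downloads.

## Worked example

```python
from dosagebal import (
    CopySimSpec, simulate_copy_number_table, subfamily_regression,
    split_high_low, KsMixtureSpec, POACEAE_KS_COMPONENTS,
    simulate_ks_mixture, filter_and_fit_ks, divergence_time,
)

# 1052 species, copies allocated binomially with ASMT share 0.6
table = simulate_copy_number_table(CopySimSpec(n_species=1052, asmt_share=0.6, seed=1))
reg = subfamily_regression(table)
print(f"slope_asmt = {reg.slope_asmt:.3f}")    # slope_asmt = 0.595
print(f"slope_comt = {reg.slope_comt:.3f}")    # slope_comt = 0.405
print(f"slope_ratio = {reg.slope_ratio:.2f}")  # slope_ratio = 1.47

# Ks distribution from the three Poaceae mixture components, refit blind
ks = simulate_ks_mixture(KsMixtureSpec(components=POACEAE_KS_COMPONENTS,
                                       n_draws=10000, seed=1))
fit = filter_and_fit_ks(ks, seed=1)
print(fit.selected_k)                          # 3
print(f"{fit.components[0][0]:.3f}")           # 0.334  (dominant component mean)
print(f"{fit.global_peak:.3f}")                # 0.341  (mixture-density peak)
print(f"{divergence_time(fit.global_peak).t:.1f} Myr")  # 26.2 Myr
```

The regression slopes recover the generating allocation (0.6/0.4 → ratio
1.5) up to sampling noise; the blind mixture refit selects three components,
recovers their means, and dates the dominant Ks peak to ~26 million years —
the signature of a recent whole-genome-duplication-driven expansion.

A command-line interface mirrors the library
(`dosagebal simulate|catalog|cluster|pav|occupancy|openness|fitpl|kaks|kspeaks|date|dosage|synteny|run`);
`dosagebal run --config config.toml --out report.json` executes the CNV or
pan-genome workflow end to end with a single root seed and emits a JSON
report embedding its config hash.

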