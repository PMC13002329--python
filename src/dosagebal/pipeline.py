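"""Workflow orchestration: the large-scale multi-species CNV analysis and the
pan-genome ploidy comparison, wired end to end with deterministic seeding.

All randomness derives from a single root seed split per stage with
`numpy.random.SeedSequence`, so rerunning a workflow — or one stage with its
derived seed — reproduces the same numbers.  Every report embeds the
SHA-256 hash of its canonical config and serializes deterministically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
from contextlib import contextmanager

import numpy as np
import pandas as pd

from . import __version__
from .dosage import (
    ploidy_comparison,
    receptor_correlation,
    split_high_low,
    subfamily_regression,
)
from .molevol import divergence_time, filter_and_fit_ks
from .pangenome import (
    build_pav_matrix,
    classify_occupancy,
    fit_power_law,
    greedy_cluster,
    openness_curve,
)
from .simulate import (
    CopySimSpec,
    KsMixtureSpec,
    PanSimSpec,
    simulate_copy_number_table,
    simulate_ks_mixture,
    simulate_pangenome,
)

_STAGE_SEED_NAMES = (
    "synthetic_data",
    "family_catalog",
    "ogg_pangenome",
    "molecular_evolution",
    "dosage_stats",
    "synteny_duplication",
)


def stage_seeds(root_seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds spawned from one root seed (< 2^31)."""
    children = np.random.SeedSequence(root_seed).spawn(len(_STAGE_SEED_NAMES))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(_STAGE_SEED_NAMES, children)
    }


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()


@contextmanager
def _stage(name: str, verbose: bool = False):
    if verbose:
        print(f"[{name}] running", file=sys.stderr)
    try:
        yield
    except Exception as exc:
        raise RuntimeError(f"stage {name} failed: {exc}") from exc


def run_cnv_workflow(config: dict, verbose: bool = False) -> dict:
    """Copy-number table -> regressions, high/low split, receptor correlation.

    `config["synthetic"]` holds :class:`CopySimSpec` fields (the table is
    generated); alternatively `config["table"]` supplies a prebuilt table as
    a list of row dicts.  Returns a JSON-serializable report.
    """
    seed = int(config.get("seed", 0))
    seeds = stage_seeds(seed)

    with _stage("family_catalog", verbose):
        if "table" in config:
            table = pd.DataFrame(config["table"])
        else:
            syn = dict(config.get("synthetic", {}))
            syn.setdefault("seed", seeds["synthetic_data"])
            if "total_range" in syn:
                syn["total_range"] = tuple(syn["total_range"])
            table = simulate_copy_number_table(CopySimSpec(**syn))
        if len(table) == 0:
            raise ValueError("empty species roster: no copy-number rows")

    with _stage("dosage_stats", verbose):
        reg = subfamily_regression(table)
        comt_share = table["comt"].to_numpy(float) / np.maximum(
            table["total"].to_numpy(float), 1
        )
        split = split_high_low(table["total"], statistic=comt_share)
        receptor = (
            receptor_correlation(table) if "receptor" in table.columns else None
        )

    report = {
        "workflow": "cnv",
        "version": __version__,
        "config_sha256": config_hash(config),
        "seed": seed,
        "stage_seeds": seeds,
        "n_species": int(len(table)),
        "regression": dataclasses.asdict(reg),
        "group_split": {
            "n_high": int((split.labels == "high").sum()),
            "n_low": int((split.labels == "low").sum()),
            "boundary_low": split.boundary_low,
            "boundary_high": split.boundary_high,
            "t_stat": split.t_stat,
            "t_p": split.t_p,
            "u_stat": split.u_stat,
            "u_p": split.u_p,
        },
        "receptor_correlation": dataclasses.asdict(receptor) if receptor else None,
    }
    return report


def run_pangenome_workflow(config: dict, verbose: bool = False) -> dict:
    """Pan-genome OGGs -> occupancy, openness fit, Ks peaks, dating, ploidy.

    Sub-configs: `pangenome` (:class:`PanSimSpec` fields or a FASTA-derived
    sequence dict), `ks_mixture` (:class:`KsMixtureSpec` fields), and
    optionally `ploidy` with `group_a`/`group_b` CopySimSpec fields.
    """
    seed = int(config.get("seed", 0))
    seeds = stage_seeds(seed)
    report: dict = {
        "workflow": "pangenome",
        "version": __version__,
        "config_sha256": config_hash(config),
        "seed": seed,
        "stage_seeds": seeds,
    }

    with _stage("ogg_pangenome", verbose):
        pan_cfg = dict(config.get("pangenome", {}))
        pan_cfg.setdefault("seed", seeds["synthetic_data"])
        if "occupancy_dist" in pan_cfg and isinstance(pan_cfg["occupancy_dist"], list):
            pan_cfg["occupancy_dist"] = tuple(pan_cfg["occupancy_dist"])
        records, truth = simulate_pangenome(PanSimSpec(**pan_cfg))
        sequences = {gid: seq for gid, _, seq in records}
        variety_of_gene = {gid: var for gid, var, _ in records}
        oggs = greedy_cluster(sequences)
        pav = build_pav_matrix(oggs, variety_of_gene)
        occ = classify_occupancy(pav)
        curve = openness_curve(pav, n_iter=100, seed=seeds["ogg_pangenome"])
        try:
            fit = fit_power_law(curve)
        except ValueError:
            fit = None  # closed pan-genome: too few positive curve points
        report["pangenome"] = {
            "n_sequences": len(sequences),
            "n_oggs": len(oggs),
            "n_planted_oggs": int(truth.any(axis=1).sum()),
            "occupancy_counts": occ["occupancy_class"].value_counts().to_dict(),
            "openness_fit": dataclasses.asdict(fit) if fit is not None else None,
        }

    with _stage("molecular_evolution", verbose):
        ks_cfg = dict(config.get("ks_mixture", {}))
        if ks_cfg:
            ks_cfg.setdefault("seed", seeds["molecular_evolution"])
            ks_cfg["components"] = tuple(tuple(c) for c in ks_cfg["components"])
            ks = simulate_ks_mixture(KsMixtureSpec(**ks_cfg))
            gmm = filter_and_fit_ks(ks, seed=seeds["molecular_evolution"])
            dating = divergence_time(max(gmm.global_peak, 0.0))
            report["ks_analysis"] = {
                "selected_k": gmm.selected_k,
                "components": [list(c) for c in gmm.components],
                "global_peak": gmm.global_peak,
                "dominant_peak_age_myr": dating.t,
                "rate": dating.rate,
            }

    with _stage("dosage_stats", verbose):
        ploidy_cfg = config.get("ploidy")
        if ploidy_cfg:
            tables = {}
            for grp in ("group_a", "group_b"):
                syn = dict(ploidy_cfg[grp])
                syn.setdefault("seed", seeds["dosage_stats"] + (0 if grp == "group_a" else 1))
                if "total_range" in syn:
                    syn["total_range"] = tuple(syn["total_range"])
                tables[grp] = simulate_copy_number_table(CopySimSpec(**syn))
            comp = ploidy_comparison(tables["group_a"], tables["group_b"])
            report["ploidy_comparison"] = dataclasses.asdict(comp)

    return report


def serialize_report(report: dict) -> str:
    """Canonical JSON serialization (byte-identical for identical reports)."""
    return json.dumps(report, sort_keys=True, indent=2)
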