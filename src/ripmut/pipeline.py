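"""End-to-end simulation studies: simulate -> call -> annotate -> estimate.

The closure property the package is designed around: running the full
analysis on its own simulator must recover the configured mutation rate
(after FNR normalization) and reproduce the qualitative RIP signatures
(clustering, strand purity, duplicate concentration).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .duplicates import classify_site, find_duplicates_blast
from .filtering import call_mutations
from .genome import GenomeAssembly
from .rates import estimate_fnr, estimate_rates
from .rip import (
    cluster_permutation_test,
    detect_clusters,
    events_to_spore_table,
    mutation_spectrum,
    nearest_distance_stats,
)
from .simulate import (
    SimConfig,
    simulate_depth_and_calls,
    simulate_genome,
    simulate_tetrad,
)


def analyze_ascus(
    ascus, genome: GenomeAssembly, regions: pd.DataFrame,
    min_qual: float = 30.0, min_depth: int = 5, flank: int = 400,
) -> pd.DataFrame:
    """Call de novo events for one ascus and attach region classes."""
    result = call_mutations(ascus, genome, min_qual=min_qual, min_depth=min_depth)
    events = result.events
    events = events[events["status"] == "ok"].reset_index(drop=True)
    if len(events):
        events["region_class"] = classify_site(
            events["contig"].to_numpy(), events["pos"].to_numpy() - 1,
            regions, genome, flank=flank,
        )
    else:
        events["region_class"] = pd.Series(dtype=object)
    return events


def simulation_study(
    config: SimConfig,
    n_tetrads: int = 20,
    fnr_sites_2to2: int = 1000,
    fnr_sites_3to1: int = 200,
    with_fnr: bool = True,
    regions: pd.DataFrame | None = None,
    run_rip_stats: bool = False,
    permutation_m: int = 1000,
) -> dict:
    """Simulate a cross of ``n_tetrads`` asci and run the whole analysis.

    Returns a dict with the genome, truth tables, called events (with
    region classes), per-ascus FNR, the rate table, and optionally the RIP
    signature statistics over duplicate-region events.
    """
    genome = simulate_genome(config)
    if regions is None:
        regions, _ = find_duplicates_blast(genome)

    all_events, all_truth, all_fnr = [], [], []
    for tid in range(n_tetrads):
        truth = simulate_tetrad(genome, config, tetrad_id=tid)
        ascus = simulate_depth_and_calls(truth, config)
        events = analyze_ascus(ascus, genome, regions)
        events["ascus_id"] = tid
        all_events.append(events)
        t = truth.events.copy()
        t["ascus_id"] = tid
        all_truth.append(t)
        if with_fnr:
            fnr = estimate_fnr(
                ascus, genome, regions,
                n_2to2=fnr_sites_2to2, n_3to1=fnr_sites_3to1,
                seed=config.seed,
            )
            all_fnr.append(fnr)

    events = pd.concat(all_events, ignore_index=True)
    truth = pd.concat(all_truth, ignore_index=True)
    fnr = pd.concat(all_fnr, ignore_index=True) if all_fnr else None

    # region fractions measured on the annotation actually used
    from .genome import merge_intervals, total_length
    merged = merge_intervals(regions)
    flanked = merged.copy()
    if len(flanked):
        flanked["start"] = (flanked["start"] - 400).clip(lower=0)
        flanked["end"] = flanked["end"] + 400
        flanked = merge_intervals(flanked)
    within = total_length(merged) / genome.size
    near = (total_length(flanked) - total_length(merged)) / genome.size
    fractions = {
        "within_dup": within, "near_dup": near, "non_dup": 1.0 - within - near,
    }

    rates = estimate_rates(
        events, fnr, region_fractions=fractions,
        genome_size=genome.size, n_asci=n_tetrads,
    )

    out = {
        "genome": genome, "regions": regions, "events": events,
        "truth": truth, "fnr": fnr, "rates": rates,
        "region_fractions": fractions,
    }

    if run_rip_stats:
        dup_events = events[
            (events["segregation"] == "2:2")
            & (events["region_class"] == "within_dup")
        ]
        spore_table = events_to_spore_table(dup_events)
        # positions back to 0-based for cluster/permutation machinery
        spore_table = spore_table.assign(pos=spore_table["pos"] - 1)
        clusters = detect_clusters(spore_table)
        spectrum = mutation_spectrum(events, by="region_class")
        perm = cluster_permutation_test(
            spore_table, regions, genome, m=permutation_m, seed=config.seed,
        ) if len(spore_table) else None
        out.update({
            "clusters": clusters,
            "spectrum": spectrum,
            "cluster_permutation": perm,
            "nearest": nearest_distance_stats(spore_table),
        })
    return out


def rate_recovery(
    seed: int = 0,
    n_tetrads: int = 20,
    per_bp_rate: float = 2e-5,
    low_coverage_fraction: float = 0.10,
) -> dict:
    """Parameter-recovery experiment: RIP off, uniform mitotic mutations at
    a configured per-bp per-cycle rate, 10% of each sample's genome forced
    to low coverage; the FNR-normalized estimate should recover the
    configured rate within sampling error.

    Returns configured rate, FNR-corrected and uncorrected estimates with
    sem, and the z-score of the corrected estimate against the target.
    """
    config = SimConfig(
        seed=seed,
        rip_rate_per_gc_site=0.0,
        post_meiotic_rate=0.0,
        mitotic_rate_per_bp_per_division=per_bp_rate / 300.0,
        divisions=300,
        low_coverage_fraction=low_coverage_fraction,
    )
    # generous spike-in so per-(ascus, region) FNR estimates are tight:
    # 1/(1 - FNR) is convex, so a noisy FNR would bias the correction up
    study = simulation_study(config, n_tetrads=n_tetrads,
                             fnr_sites_2to2=2500, fnr_sites_3to1=200)
    row = study["rates"].query("segregation == 'all' and region_class == 'all'").iloc[0]
    raw_rates = estimate_rates(
        study["events"], None, region_fractions=study["region_fractions"],
        genome_size=study["genome"].size, n_asci=n_tetrads,
    )
    raw_row = raw_rates.query("segregation == 'all' and region_class == 'all'").iloc[0]
    z = (row["per_bp"] - per_bp_rate) / row["per_bp_sem"] if row["per_bp_sem"] else np.nan
    return {
        "configured_per_bp": per_bp_rate,
        "estimated_per_bp": float(row["per_bp"]),
        "estimated_sem": float(row["per_bp_sem"]),
        "uncorrected_per_bp": float(raw_row["per_bp"]),
        "z": float(z),
        "n_tetrads": n_tetrads,
    }


def rip_signature_study(
    seed: int = 0, n_tetrads: int = 6, permutation_m: int = 1000
) -> dict:
    """RIP-on study summarizing the classical signatures on called events:
    strand purity of duplicate-region clusters, duplicate concentration,
    C->T fraction in duplicates, and the cluster permutation p-value."""
    config = SimConfig(seed=seed)
    study = simulation_study(
        config, n_tetrads=n_tetrads, with_fnr=False, run_rip_stats=True,
        permutation_m=permutation_m,
    )
    clusters = study["clusters"]
    pure = float((clusters["strand_class"] != "mixed").mean()) if len(clusters) else np.nan
    spec = study["spectrum"]
    dup_row = spec[spec["group"] == "within_dup"]
    ct_dup = float(dup_row["ct_fraction"].iloc[0]) if len(dup_row) else np.nan
    events = study["events"]
    frac_in_dup = float((events["region_class"] == "within_dup").mean()) if len(events) else np.nan
    return {
        "n_clusters": int(len(clusters)),
        "strand_pure_fraction": pure,
        "ct_fraction_in_duplicates": ct_dup,
        "fraction_events_in_duplicates": frac_in_dup,
        "cluster_permutation": study["cluster_permutation"],
        "nearest": study["nearest"],
        "n_events": int(len(events)),
    }


def baseline_spectrum_study(seed: int = 0, n_tetrads: int = 3) -> dict:
    """RIP off, elevated mitotic rate: the C->T(+G->A) share of called
    events should sit near the unskewed 2/12 expectation."""
    config = SimConfig(
        seed=seed,
        rip_rate_per_gc_site=0.0,
        post_meiotic_rate=0.0,
        mitotic_rate_per_bp_per_division=1.25e-4 / 300.0,
        divisions=300,
    )
    study = simulation_study(config, n_tetrads=n_tetrads, with_fnr=False)
    spec = mutation_spectrum(study["events"])
    n = int(spec["n"].iloc[0])
    ct = float(spec["ct_fraction"].iloc[0])
    return {"n_events": n, "ct_fraction": ct, "expected": 2.0 / 12.0,
            "binomial_sd": float(np.sqrt((2 / 12) * (10 / 12) / n)) if n else np.nan}
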