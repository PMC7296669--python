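"""RIP signature statistics.

Mutation spectra, the dinucleotide RIP index, single-linkage mutation
clusters with strand classification, nearest-neighbour distance summaries,
and the two randomization tests: re-placement of mutations over duplicate
G:C sites (cluster excess) and shuffling of cluster intervals within
duplicates (cross-spore overlap). Permutation p-values are (n+1)/(m+1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeAssembly, merge_intervals

#: the 12 point-mutation classes
SPECTRUM_CLASSES = [
    f"{r}>{a}" for r in "ACGT" for a in "ACGT" if r != a
]
CT_CLASSES = ("C>T", "G>A")


def mutation_spectrum(
    events: pd.DataFrame, by: str | None = None
) -> pd.DataFrame:
    """12-class mutation counts and the pooled C->T (+G->A) fraction.

    With ``by`` set (e.g. 'region_class'), one row per group. The fraction
    is NaN for empty groups.
    """
    df = events.copy()
    df["mut_class"] = df["ref"].astype(str) + ">" + df["alt"].astype(str)
    groups = df.groupby(by) if by else [("all", df)]
    rows = []
    for name, sub in groups:
        counts = sub["mut_class"].value_counts()
        row = {"group": name, "n": len(sub)}
        for cls in SPECTRUM_CLASSES:
            row[cls] = int(counts.get(cls, 0))
        ct = sum(row[c] for c in CT_CLASSES)
        row["ct_fraction"] = ct / len(sub) if len(sub) else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class RipIndexResult:
    """Dinucleotide RIP-index ratios for one window.

    ``tpa_apt`` is TpA/ApT; ``composite`` is (CpA+TpG)/(ApC+GpT). Either is
    NaN when its denominator is zero; a window is 'riped' if TpA/ApT > 2 or
    the composite < 0.7, each criterion contributing only when defined.
    """

    tpa_apt: float
    composite: float
    riped: bool


def rip_index(window: str) -> RipIndexResult:
    """RIP index of a sequence window (counts on the given strand)."""
    if len(window) < 2:
        raise ValueError("window must be at least 2 bp")
    seq = window.upper()
    counts = {}
    for di in ("TA", "AT", "CA", "TG", "AC", "GT"):
        counts[di] = sum(
            1 for i in range(len(seq) - 1) if seq[i: i + 2] == di
        )
    tpa_apt = counts["TA"] / counts["AT"] if counts["AT"] else float("nan")
    denom = counts["AC"] + counts["GT"]
    composite = (counts["CA"] + counts["TG"]) / denom if denom else float("nan")
    riped = bool(
        (not np.isnan(tpa_apt) and tpa_apt > 2)
        or (not np.isnan(composite) and composite < 0.7)
    )
    return RipIndexResult(tpa_apt=tpa_apt, composite=composite, riped=riped)


# ---------------------------------------------------------------------------
# clusters
# ---------------------------------------------------------------------------


def events_to_spore_table(events: pd.DataFrame) -> pd.DataFrame:
    """Expand events to one row per (carrier haploid genome, event).

    When an ascus_id column is present it is folded into the spore id, so
    same-named spores from different asci stay distinct haploid genomes.
    """
    has_ascus = "ascus_id" in events.columns
    rows = []
    for ev in events.itertuples():
        for spore in ev.carriers:
            sid = f"{ev.ascus_id}:{spore}" if has_ascus else spore
            rows.append((sid, ev.contig, ev.pos, ev.ref, ev.alt))
    return pd.DataFrame(rows, columns=["spore_id", "contig", "pos", "ref", "alt"])


def detect_clusters(
    spore_table: pd.DataFrame, max_gap: int = 1000
) -> pd.DataFrame:
    """Single-linkage clusters of >= 2 mutations within max_gap per spore.

    Adjacent mutations <= max_gap apart on the same contig in the same
    haploid genome chain into one cluster.
    """
    rows = []
    cluster_id = 0
    for (spore, contig), sub in spore_table.groupby(["spore_id", "contig"]):
        sub = sub.sort_values("pos")
        pos = sub["pos"].to_numpy()
        if pos.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(pos) > max_gap)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks + 1, [pos.size]])
        for s, e in zip(starts, ends):
            if e - s < 2:
                continue
            members = sub.iloc[s:e]
            rows.append((
                cluster_id, spore, contig, int(pos[s]), int(pos[e - 1]) + 1,
                int(e - s),
                list(zip(members["ref"], members["alt"])),
                list(members["pos"]),
            ))
            cluster_id += 1
    df = pd.DataFrame(rows, columns=[
        "cluster_id", "spore_id", "contig", "start", "end", "n_members",
        "changes", "positions",
    ])
    if len(df):
        df["strand_class"] = [strand_class(c) for c in df["changes"]]
    else:
        df["strand_class"] = pd.Series(dtype=object)
    return df


def strand_class(changes: list[tuple[str, str]]) -> str:
    """C_run if every member is C->T, G_run if every member is G->A, else
    mixed — one round of RIP deaminates one strand at a time."""
    if all(c == ("C", "T") for c in changes):
        return "C_run"
    if all(c == ("G", "A") for c in changes):
        return "G_run"
    return "mixed"


def nearest_distance_stats(spore_table: pd.DataFrame) -> dict:
    """Per-event nearest-neighbour distance within the same spore + contig.

    Returns mean, median and the fraction of events within 100 bp of their
    nearest neighbour; NaN summaries when no distances are defined.
    """
    dists = []
    for (_, _), sub in spore_table.groupby(["spore_id", "contig"]):
        pos = np.sort(sub["pos"].to_numpy())
        if pos.size < 2:
            continue
        gaps = np.diff(pos)
        nearest = np.minimum(
            np.concatenate([[gaps[0]], gaps]),
            np.concatenate([gaps, [gaps[-1]]]),
        )
        dists.append(nearest)
    if not dists:
        return {"n": 0, "mean": float("nan"), "median": float("nan"),
                "frac_le_100bp": float("nan")}
    d = np.concatenate(dists)
    return {
        "n": int(d.size),
        "mean": float(d.mean()),
        "median": float(np.median(d)),
        "frac_le_100bp": float((d <= 100).mean()),
    }


# ---------------------------------------------------------------------------
# randomization tests
# ---------------------------------------------------------------------------


def _gc_sites_in_regions(
    genome: GenomeAssembly, regions: pd.DataFrame
) -> dict[str, np.ndarray]:
    merged = merge_intervals(regions)
    sites: dict[str, list[np.ndarray]] = {}
    for r in merged.itertuples():
        codes = genome.sequences[r.contig][r.start: r.end]
        pos = r.start + np.flatnonzero(np.isin(codes, (1, 2)))
        sites.setdefault(r.contig, []).append(pos)
    return {c: np.concatenate(parts) for c, parts in sites.items()}


def _clustered_count(pos_by_contig: list[np.ndarray], max_gap: int) -> tuple[int, int]:
    """(number of clustered mutations, number of clusters) for one spore."""
    n_mut = 0
    n_clu = 0
    for pos in pos_by_contig:
        pos = np.sort(pos)
        if pos.size < 2:
            continue
        breaks = np.flatnonzero(np.diff(pos) > max_gap)
        sizes = np.diff(np.concatenate([[0], breaks + 1, [pos.size]]))
        clustered = sizes[sizes >= 2]
        n_mut += int(clustered.sum())
        n_clu += int(clustered.size)
    return n_mut, n_clu


def cluster_permutation_test(
    spore_table: pd.DataFrame,
    duplicate_regions: pd.DataFrame,
    genome: GenomeAssembly,
    m: int = 10_000,
    seed: int = 0,
    max_gap: int = 1000,
    statistic: str = "mutations",
) -> dict:
    """Are mutations more clustered than random placement over duplicate
    G:C sites allows?

    Each randomization re-places every spore's mutations uniformly (without
    replacement) over the G:C sites of the duplicate regions, preserving
    per-spore counts, and re-counts the cluster statistic ('mutations' =
    number of mutations in clusters, or 'clusters'). p = (n+1)/(m+1) with n
    the randomizations reaching the observed value.
    """
    if statistic not in ("mutations", "clusters"):
        raise ValueError("statistic must be 'mutations' or 'clusters'")
    gc_sites = _gc_sites_in_regions(genome, duplicate_regions)
    if not gc_sites or all(v.size == 0 for v in gc_sites.values()):
        raise ValueError("duplicate regions contain no G:C sites")
    contigs = sorted(gc_sites)
    site_counts = np.array([gc_sites[c].size for c in contigs])
    total_sites = int(site_counts.sum())

    per_spore_n = spore_table.groupby("spore_id").size()
    obs_by_spore = [
        [sub["pos"].to_numpy() for _, sub in spore_table[spore_table["spore_id"] == s]
         .groupby("contig")]
        for s in per_spore_n.index
    ]
    idx = 0 if statistic == "mutations" else 1
    observed = sum(_clustered_count(p, max_gap)[idx] for p in obs_by_spore)

    rng = np.random.default_rng([int(seed), 101])

    def sample_sites(n: int) -> np.ndarray:
        # uniform without replacement; rejection sampling is much faster
        # than a full permutation when n << total_sites
        n = min(n, total_sites)
        if n > total_sites // 2:
            return rng.permutation(total_sites)[:n]
        chosen = np.unique(rng.integers(0, total_sites, size=n))
        while chosen.size < n:
            extra = rng.integers(0, total_sites, size=n - chosen.size)
            chosen = np.unique(np.concatenate([chosen, extra]))
        return chosen

    n_extreme = 0
    for _ in range(m):
        stat = 0
        for n_mut in per_spore_n.values:
            chosen = sample_sites(int(n_mut))
            # map flat site index -> (contig, position)
            chosen.sort()
            bounds = np.cumsum(site_counts)
            by_contig = []
            lo = 0
            for ci, hi in enumerate(bounds):
                sel = chosen[(chosen >= lo) & (chosen < hi)]
                if sel.size:
                    by_contig.append(gc_sites[contigs[ci]][sel - lo])
                lo = hi
            stat += _clustered_count(by_contig, max_gap)[idx]
        if stat >= observed:
            n_extreme += 1
    return {
        "observed": int(observed), "m": int(m), "n": int(n_extreme),
        "p": (n_extreme + 1) / (m + 1), "seed": int(seed),
        "statistic": statistic,
    }


def cluster_overlap_shuffle_test(
    clusters: pd.DataFrame,
    duplicate_regions: pd.DataFrame,
    m: int = 10_000,
    seed: int = 0,
) -> dict:
    """Do clusters from different spores overlap more than expected?

    Cluster intervals are re-placed uniformly within the duplicate regions
    of their own contig (lengths preserved, no cross-contig moves); the
    statistic is the number of mutations belonging to clusters that overlap
    a cluster from a different spore. p = (n+1)/(m+1).
    """
    merged = merge_intervals(duplicate_regions)

    def overlap_stat(cl: pd.DataFrame) -> int:
        total = 0
        for _contig, sub in cl.groupby("contig"):
            arr = sub[["start", "end", "n_members"]].to_numpy()
            spores = sub["spore_id"].to_numpy()
            for i in range(len(arr)):
                s, e, k = arr[i]
                hits = (
                    (arr[:, 0] < e) & (arr[:, 1] > s) & (spores != spores[i])
                )
                if hits.any():
                    total += int(k)
        return total

    observed = overlap_stat(clusters)
    placements = {}
    for contig, sub in merged.groupby("contig"):
        placements[contig] = sub[["start", "end"]].to_numpy()
    lengths = (clusters["end"] - clusters["start"]).to_numpy()
    for i, r in enumerate(clusters.itertuples()):
        regs = placements.get(r.contig, np.empty((0, 2), dtype=int))
        if len(regs) == 0 or not ((regs[:, 1] - regs[:, 0]) >= lengths[i]).any():
            raise ValueError(
                f"cluster of {lengths[i]} bp does not fit in any duplicate "
                f"region on {r.contig}"
            )
    if len(clusters) <= 1:
        return {"observed": observed, "m": m, "n": m, "p": 1.0, "seed": seed}

    rng = np.random.default_rng([int(seed), 211])

    n_extreme = 0
    for _ in range(m):
        new_rows = []
        for i, r in enumerate(clusters.itertuples()):
            regs = placements[r.contig]
            fit = regs[(regs[:, 1] - regs[:, 0]) >= lengths[i]]
            weights = fit[:, 1] - fit[:, 0] - lengths[i] + 1
            reg = fit[rng.choice(fit.shape[0], p=weights / weights.sum())]
            start = int(rng.integers(reg[0], reg[1] - lengths[i] + 1))
            new_rows.append((r.spore_id, r.contig, start, start + lengths[i],
                             r.n_members))
        shuffled = pd.DataFrame(
            new_rows, columns=["spore_id", "contig", "start", "end", "n_members"]
        )
        if overlap_stat(shuffled) >= observed:
            n_extreme += 1
    return {
        "observed": int(observed), "m": int(m), "n": int(n_extreme),
        "p": (n_extreme + 1) / (m + 1), "seed": int(seed),
    }
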