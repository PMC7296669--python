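"""Duplicate-region annotation by four operational detectors.

Four independent definitions of "duplicate" are implemented:

* Dup-Blast — native all-vs-self seed-and-extend local alignment; intervals
  with an alignable partner of >= 100 bp at > 65% identity.
* Dup-Depth — windows at ~2x the genome-wide median sequencing depth
  (collapsed-repeat signature).
* Dup-Het — regions where a haploid sample accumulates "heterozygous"
  calls, a mis-mapping signature of repeats.
* Dup-Period — windows dominated by a 10-12 bp matching period between
  repeated short words, the spacing associated with homology sensing.

Plus site classification (within / near / non duplicate with a 400 bp
flank), the per-method efficiency comparison, and region summaries.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np
import pandas as pd
from scipy import stats

from .genome import (
    GenomeAssembly,
    empty_intervals,
    gc_fraction,
    merge_intervals,
    points_in_intervals,
    total_length,
)

REGION_CLASSES = ("within_dup", "near_dup", "non_dup")


# ---------------------------------------------------------------------------
# Dup-Blast: native seed-and-extend self-alignment
# ---------------------------------------------------------------------------

_SENTINEL = 4


def _global_codes(genome: GenomeAssembly) -> tuple[np.ndarray, list[tuple[str, int, int]]]:
    """Concatenate contigs with sentinel separators; return layout."""
    parts, layout, offset = [], [], 0
    for contig, codes in genome.sequences.items():
        parts.append(codes.astype(np.int64))
        layout.append((contig, offset, offset + codes.size))
        offset += codes.size + 1
        parts.append(np.array([_SENTINEL], dtype=np.int64))
    return np.concatenate(parts[:-1]), layout


def _kmer_ids(codes: np.ndarray, k: int) -> np.ndarray:
    """Base-5 rolling k-mer ids; windows containing the sentinel get id -1."""
    n = codes.size - k + 1
    ids = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for j in range(k):
        ids = ids * 5 + codes[j: j + n]
        bad |= codes[j: j + n] == _SENTINEL
    ids[bad] = -1
    return ids


def _extend(
    codes: np.ndarray, i0: int, i1: int, j0: int, xdrop: int, max_ext: int = 6000
) -> tuple[int, int, int]:
    """Ungapped X-drop extension of the seed chain codes[i0:i1] ~ codes[j0:...].

    Returns (start_offset, end_offset, 0) relative to i0/i1 on both copies;
    sentinels never match so extension cannot cross contigs usefully, and
    the returned span is later clamped to contig bounds.
    """
    n = codes.size
    diag = j0 - i0
    # right extension from i1
    best, score, best_t = 0, 0, 0
    t = 0
    while i1 + t < n and i1 + diag + t < n and t < max_ext:
        a, b = codes[i1 + t], codes[i1 + diag + t]
        score += 1 if (a == b and a != _SENTINEL) else -2
        t += 1
        if score > best:
            best, best_t = score, t
        if best - score > xdrop:
            break
    right = best_t
    # left extension from i0 - 1
    best, score, best_t = 0, 0, 0
    t = 0
    while i0 - 1 - t >= 0 and i0 - 1 + diag - t >= 0 and t < max_ext:
        a, b = codes[i0 - 1 - t], codes[i0 - 1 + diag - t]
        score += 1 if (a == b and a != _SENTINEL) else -2
        t += 1
        if score > best:
            best, best_t = score, t
        if best - score > xdrop:
            break
    left = best_t
    return left, right, 0


def find_duplicates_blast(
    genome: GenomeAssembly,
    min_identity: float = 0.65,
    min_len: int = 100,
    k: int = 11,
    max_kmer_occ: int = 100,
    chain_gap: int = 150,
    xdrop: int = 25,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-vs-self local alignment by k-mer seeding + ungapped extension.

    Returns ``(regions, hits)``: hits are pairwise local alignments (both
    copies' coordinates, identity, length); regions are the merged per-
    contig union of all qualifying hit intervals, annotated with length, GC
    and the best identity of any contributing hit.
    """
    codes, layout = _global_codes(genome)
    ids = _kmer_ids(codes, k)

    order = np.argsort(ids, kind="stable")
    sorted_ids = ids[order]
    boundaries = np.flatnonzero(np.diff(sorted_ids)) + 1
    groups = np.split(order, boundaries)

    # seed pairs bucketed by diagonal
    diag_seeds: dict[int, list[int]] = defaultdict(list)
    for grp in groups:
        if ids[grp[0]] == -1 or not (2 <= grp.size <= max_kmer_occ):
            continue
        pos = np.sort(grp)
        for a in range(pos.size):
            for b in range(a + 1, pos.size):
                diag_seeds[int(pos[b] - pos[a])].append(int(pos[a]))

    hit_rows = []
    for diag, starts in diag_seeds.items():
        if diag == 0:
            continue
        starts = np.unique(np.array(starts))
        # chain seeds on the same diagonal into candidate segments
        seg_start = prev = int(starts[0])
        segments = []
        for s in starts[1:]:
            if s - prev <= chain_gap + k:
                prev = int(s)
            else:
                segments.append((seg_start, prev + k))
                seg_start = prev = int(s)
        segments.append((seg_start, prev + k))
        for i0, i1 in segments:
            left, right, _ = _extend(codes, i0, i1, i0 + diag, xdrop)
            a0, a1 = i0 - left, i1 + right
            span_a = codes[a0:a1]
            span_b = codes[a0 + diag: a1 + diag]
            valid = (span_a != _SENTINEL) & (span_b != _SENTINEL)
            matches = int(((span_a == span_b) & valid).sum())
            length = a1 - a0
            if length < min_len:
                continue
            identity = matches / length
            if identity <= min_identity:
                continue
            hit_rows.append((a0, a1, a0 + diag, a1 + diag, identity, length))

    hits = _hits_to_contig_coords(hit_rows, layout)
    regions = _hits_to_regions(hits, genome)
    return regions, hits


def _hits_to_contig_coords(hit_rows, layout) -> pd.DataFrame:
    cols = ["contig_a", "start_a", "end_a", "contig_b", "start_b", "end_b",
            "identity", "length"]
    rows = []
    for a0, a1, b0, b1, ident, length in hit_rows:
        ca = _locate(layout, a0, a1)
        cb = _locate(layout, b0, b1)
        if ca is None or cb is None:
            continue
        rows.append((*ca, *cb, ident, length))
    return pd.DataFrame(rows, columns=cols)


def _locate(layout, g0, g1):
    """Map a global span back to (contig, start, end), clamped to one contig."""
    for contig, off, end in layout:
        if g0 < end and g1 > off:
            s = max(g0, off) - off
            e = min(g1, end) - off
            if e - s > 0:
                return contig, int(s), int(e)
    return None


def _hits_to_regions(hits: pd.DataFrame, genome: GenomeAssembly) -> pd.DataFrame:
    if len(hits) == 0:
        return empty_intervals(["method", "length", "gc", "best_identity"])
    intervals = pd.concat([
        hits[["contig_a", "start_a", "end_a", "identity"]]
        .rename(columns={"contig_a": "contig", "start_a": "start", "end_a": "end"}),
        hits[["contig_b", "start_b", "end_b", "identity"]]
        .rename(columns={"contig_b": "contig", "start_b": "start", "end_b": "end"}),
    ], ignore_index=True)
    merged = merge_intervals(intervals)
    best_ident, gcs = [], []
    for r in merged.itertuples():
        sub = intervals[
            (intervals["contig"] == r.contig)
            & (intervals["start"] < r.end) & (intervals["end"] > r.start)
        ]
        best_ident.append(float(sub["identity"].max()))
        gcs.append(gc_fraction(genome.sequences[r.contig][r.start:r.end]))
    merged["method"] = "blast"
    merged["length"] = merged["end"] - merged["start"]
    merged["gc"] = gcs
    merged["best_identity"] = best_ident
    return merged


# ---------------------------------------------------------------------------
# Dup-Depth / Dup-Het / Dup-Period
# ---------------------------------------------------------------------------


def find_duplicates_depth(
    depth_windows: pd.DataFrame,
    ratio_low: float = 1.75,
    ratio_high: float = 2.5,
) -> pd.DataFrame:
    """Regions at ~2x the genome-wide median windowed depth.

    ``depth_windows`` needs columns contig/start/end/depth (one sample, or
    an already-averaged profile). Consecutive in-band windows are merged.
    """
    med = float(np.median(depth_windows["depth"]))
    if med == 0:
        raise ValueError("genome-wide median depth is zero")
    ratio = depth_windows["depth"] / med
    hit = depth_windows[(ratio >= ratio_low) & (ratio <= ratio_high)]
    out = merge_intervals(hit[["contig", "start", "end"]])
    out["method"] = "depth"
    return out


def find_duplicates_het(
    raw_calls: pd.DataFrame,
    min_het: int = 2,
    merge_gap: int = 1000,
    pad: int = 500,
) -> pd.DataFrame:
    """Regions where haploid samples carry clustered 'heterozygous' calls.

    >= min_het het calls within merge_gap of each other in one sample define
    a region, padded +-pad bp; regions are unioned across samples.
    """
    het = raw_calls[raw_calls["zygosity"] == "het"]
    rows = []
    for (_, contig), sub in het.groupby(["sample_id", "contig"]):
        pos = np.sort(sub["pos"].to_numpy())
        if pos.size == 0:
            continue
        cluster_start = pos[0]
        count = 1
        prev = pos[0]
        for p in pos[1:]:
            if p - prev <= merge_gap:
                count += 1
            else:
                if count >= min_het:
                    rows.append((contig, max(0, cluster_start - 1 - pad), prev + pad))
                cluster_start, count = p, 1
            prev = p
        if count >= min_het:
            rows.append((contig, max(0, cluster_start - 1 - pad), prev + pad))
    if not rows:
        return empty_intervals(["method"]).assign(method=pd.Series(dtype=object))
    out = merge_intervals(pd.DataFrame(rows, columns=["contig", "start", "end"]))
    out["method"] = "het"
    return out


def _window_period_dominance(
    codes: np.ndarray, period_min: int, period_max: int, max_offset: int
) -> float:
    """Fraction of successive same-3-mer offsets (<= max_offset) that fall in
    the target period band."""
    n = codes.size - 2
    ids = codes[:n] * 16 + codes[1:n + 1] * 4 + codes[2:n + 2]
    order = np.argsort(ids, kind="stable")
    sid = ids[order]
    offsets = np.diff(order.astype(np.int64))
    same = np.diff(sid) == 0
    offs = offsets[same]
    offs = offs[(offs > 0) & (offs <= max_offset)]
    if offs.size == 0:
        return 0.0
    in_band = ((offs >= period_min) & (offs <= period_max)).sum()
    return float(in_band / offs.size)


def find_duplicates_period(
    genome: GenomeAssembly,
    period_min: int = 10,
    period_max: int = 12,
    window: int = 500,
    step: int = 250,
    dominance: float = 0.5,
    max_offset: int = 50,
    exclude: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Windows dominated by a 10-12 bp matching period of repeated 3-mers.

    For each window, offsets between successive occurrences of the same
    3-mer (capped at max_offset) are tabulated; windows where the
    period_min..period_max band accounts for more than ``dominance`` of the
    offsets are reported. Windows already covered by ``exclude`` (typically
    the Dup-Blast set) are dropped.
    """
    rows = []
    for contig, codes in genome.sequences.items():
        for start in range(0, max(1, codes.size - window + 1), step):
            frac = _window_period_dominance(
                codes[start:start + window], period_min, period_max, max_offset
            )
            if frac > dominance:
                rows.append((contig, start, min(start + window, codes.size)))
    if not rows:
        out = empty_intervals()
        out["method"] = pd.Series(dtype=object)
        return out
    out = merge_intervals(pd.DataFrame(rows, columns=["contig", "start", "end"]))
    if exclude is not None and len(exclude):
        merged_ex = merge_intervals(exclude)
        keep = []
        for r in out.itertuples():
            mid = (r.start + r.end) // 2
            inside = points_in_intervals(
                np.array([r.contig]), np.array([mid]), merged_ex
            )[0]
            if not inside:
                keep.append((r.contig, r.start, r.end))
        out = pd.DataFrame(keep, columns=["contig", "start", "end"])
    out["method"] = "period"
    return out


# ---------------------------------------------------------------------------
# site classification and method comparison
# ---------------------------------------------------------------------------


def classify_site(
    contigs: np.ndarray | list[str],
    positions: np.ndarray | list[int],
    regions: pd.DataFrame,
    genome: GenomeAssembly,
    flank: int = 400,
) -> np.ndarray:
    """Classify 0-based sites as within_dup / near_dup / non_dup.

    Precedence: within > near > non. Raises for positions outside the
    genome.
    """
    contigs = np.asarray(contigs, dtype=object)
    positions = np.asarray(positions, dtype=int)
    lengths = genome.contig_lengths()
    for c, p in zip(contigs, positions):
        if c not in lengths or not (0 <= p < lengths[c]):
            raise ValueError(f"position {c}:{p} outside genome")
    merged = merge_intervals(regions)
    within = points_in_intervals(contigs, positions, merged)
    flanked = merged.copy()
    if len(flanked):
        flanked["start"] = (flanked["start"] - flank).clip(lower=0)
        flanked["end"] = flanked["end"] + flank
        flanked = merge_intervals(flanked)
    near = points_in_intervals(contigs, positions, flanked) & ~within
    out = np.full(len(positions), "non_dup", dtype=object)
    out[near] = "near_dup"
    out[within] = "within_dup"
    return out


def method_efficiency(
    events: pd.DataFrame,
    region_sets: dict[str, pd.DataFrame],
    genome: GenomeAssembly,
) -> pd.DataFrame:
    """Per-method (and union) genome coverage vs 2:2 mutations enclosed.

    ``events`` needs contig/pos (0-based)/segregation columns. Fractions are
    NaN when there are no 2:2 events.
    """
    two_two = events[events["segregation"] == "2:2"]
    rows = []
    sets = dict(region_sets)
    if len(sets) > 1:
        sets["union"] = pd.concat(
            [df[["contig", "start", "end"]] for df in region_sets.values()],
            ignore_index=True,
        )
    for method, regions in sets.items():
        merged = merge_intervals(regions)
        cov = total_length(merged) / genome.size * 100.0
        if len(two_two):
            inside = points_in_intervals(
                two_two["contig"].to_numpy(), two_two["pos"].to_numpy(), merged
            )
            frac = float(inside.mean()) * 100.0
        else:
            frac = float("nan")
        rows.append((method, cov, frac))
    return pd.DataFrame(
        rows, columns=["method", "genome_pct", "mutations_2to2_pct"]
    )


def summarize_regions(
    regions: pd.DataFrame,
    cds_track: pd.DataFrame,
    genome: GenomeAssembly,
    hic_windows: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, np.ndarray | None]:
    """Length/GC summaries for CDS-overlapping vs non-CDS duplicates, plus
    the 2x2 interacting-window contingency table if a Hi-C table is given.

    ``hic_windows`` needs boolean columns interacting / cds / duplicate; the
    contingency is over interacting windows:
    rows = (non-CDS, CDS), cols = (duplicate, non-duplicate).
    """
    regs = regions.copy()
    if len(regs):
        merged_cds = merge_intervals(cds_track) if len(cds_track) else empty_intervals()
        overlaps = np.zeros(len(regs), dtype=bool)
        for i, r in enumerate(regs.itertuples()):
            if len(merged_cds) == 0:
                break
            sub = merged_cds[merged_cds["contig"] == r.contig]
            overlaps[i] = bool(
                ((sub["start"] < r.end) & (sub["end"] > r.start)).any()
            )
        regs["cds_overlap"] = overlaps
        regs["length"] = regs["end"] - regs["start"]
        regs["gc"] = [
            gc_fraction(genome.sequences[r.contig][r.start:r.end])
            for r in regs.itertuples()
        ]
        summary = (
            regs.groupby("cds_overlap")
            .agg(
                n=("length", "size"),
                mean_length=("length", "mean"),
                sem_length=("length", lambda x: stats.sem(x) if len(x) > 1 else 0.0),
                mean_gc=("gc", "mean"),
                sem_gc=("gc", lambda x: stats.sem(x) if len(x) > 1 else 0.0),
            )
            .reset_index()
        )
    else:
        summary = pd.DataFrame(
            columns=["cds_overlap", "n", "mean_length", "sem_length", "mean_gc", "sem_gc"]
        )

    contingency = None
    if hic_windows is not None:
        inter = hic_windows[hic_windows["interacting"].astype(bool)]
        non_cds = inter[~inter["cds"].astype(bool)]
        cds = inter[inter["cds"].astype(bool)]
        contingency = np.array([
            [int(non_cds["duplicate"].sum()), int((~non_cds["duplicate"].astype(bool)).sum())],
            [int(cds["duplicate"].sum()), int((~cds["duplicate"].astype(bool)).sum())],
        ])
    return summary, contingency
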