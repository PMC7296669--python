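"""False-negative-corrected mutation-rate estimation and chi-squared tools.

The false-negative rate (FNR) is measured by spike-in: synthetic 2:2 and
3:1 mutations are injected into the real call sets at random genomic sites
with the sample's own local read depth and pushed through the identical
filter + segregation-classification pipeline; the fraction lost is the FNR,
tallied per ascus and per region class (duplicate mapping quality differs
from unique sequence). Observed counts are then normalized as
raw / (1 - FNR) before conversion to per-genome and per-bp rates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .duplicates import REGION_CLASSES, classify_site
from .filtering import classify_segregation, filter_variant_calls
from .genome import GenomeAssembly
from .simulate import AscusCalls, SPORES

#: region-class genome fractions of the reference (duplicates / near / non)
DEFAULT_REGION_FRACTIONS = {
    "within_dup": 0.163,
    "near_dup": 0.068,
    "non_dup": 0.769,
}
REFERENCE_GENOME_SIZE = 40.46e6


# ---------------------------------------------------------------------------
# FNR spike-in
# ---------------------------------------------------------------------------


def _qual_for_depth(depth: np.ndarray) -> np.ndarray:
    # matches the call simulator: confident homozygous calls at depth >= 5
    return 20.0 + 4.0 * np.asarray(depth, dtype=float)


def estimate_fnr(
    ascus: AscusCalls,
    genome: GenomeAssembly,
    duplicate_regions: pd.DataFrame,
    n_2to2: int = 5000,
    n_3to1: int = 1000,
    seed: int = 0,
    min_qual: float = 30.0,
    min_depth: int = 5,
    flank: int = 400,
) -> pd.DataFrame:
    """Spike-in FNR per region class for one ascus.

    Synthetic mutation sites are drawn uniformly over the genome (avoiding
    existing call positions), assigned 2 random carrier spores (2:2) or one
    (3:1), injected as homozygous calls whose depth is the carrier's actual
    local depth, and recovered through filter_variant_calls +
    classify_segregation. FNR = 1 - recovered/generated. Region classes with
    no eligible sites get NaN.
    """
    rng = np.random.default_rng([int(seed), 401, int(ascus.ascus_id)])
    lengths = ascus.contig_lengths
    contigs = list(lengths)
    sizes = np.array([lengths[c] for c in contigs], dtype=float)
    existing = set(map(tuple, ascus.calls[["contig", "pos"]].itertuples(index=False)))

    total = n_2to2 + n_3to1
    rows = []
    site_meta = []
    taken = set()
    attempts = 0
    while len(site_meta) < total and attempts < 50 * total:
        attempts += 1
        ci = rng.choice(len(contigs), p=sizes / sizes.sum())
        contig = contigs[ci]
        pos0 = int(rng.integers(0, lengths[contig]))
        key = (contig, pos0 + 1)
        if key in existing or key in taken:
            continue
        taken.add(key)
        ref = genome.sequence(contig, pos0, pos0 + 1)
        alt = "ACGT"[(("ACGT".index(ref)) + int(rng.integers(1, 4))) % 4]
        kind = "2:2" if len(site_meta) < n_2to2 else "3:1"
        carriers = tuple(
            sorted(rng.choice(SPORES, size=2 if kind == "2:2" else 1, replace=False))
        )
        site_meta.append((contig, pos0 + 1, ref, alt, kind, carriers))
        for spore in carriers:
            depth = int(ascus.depth_at(spore, contig, np.array([pos0 + 1]))[0])
            rows.append((
                spore, contig, pos0 + 1, ref, alt,
                float(_qual_for_depth(np.array([depth]))[0]), depth, "hom",
            ))
    if len(site_meta) < total:
        raise RuntimeError("could not place the requested synthetic sites")

    injected = pd.DataFrame(
        rows, columns=["sample_id", "contig", "pos", "ref", "alt", "qual",
                       "depth", "zygosity"],
    )
    synth_ascus = AscusCalls(
        ascus_id=ascus.ascus_id,
        calls=pd.concat([ascus.calls, injected], ignore_index=True),
        depth=ascus.depth,
        contig_lengths=lengths,
    )
    candidates = filter_variant_calls(synth_ascus, min_qual, min_depth, genome)
    events = classify_segregation(candidates, synth_ascus, min_depth)
    recovered_keys = set(
        (r.contig, r.pos, r.alt, r.segregation, r.carriers)
        for r in events[events["status"] == "ok"].itertuples()
    )

    meta = pd.DataFrame(
        site_meta, columns=["contig", "pos", "ref", "alt", "kind", "carriers"]
    )
    meta["region_class"] = classify_site(
        meta["contig"].to_numpy(), meta["pos"].to_numpy() - 1,
        duplicate_regions, genome, flank=flank,
    )
    meta["recovered"] = [
        (r.contig, r.pos, r.alt, r.kind, r.carriers) in recovered_keys
        for r in meta.itertuples()
    ]

    out_rows = []
    for kind in ("2:2", "3:1"):
        for region in REGION_CLASSES:
            sub = meta[(meta["kind"] == kind) & (meta["region_class"] == region)]
            n_gen = len(sub)
            n_rec = int(sub["recovered"].sum())
            fnr = 1.0 - n_rec / n_gen if n_gen else float("nan")
            out_rows.append((ascus.ascus_id, kind, region, n_gen, n_rec, fnr))
    return pd.DataFrame(out_rows, columns=[
        "ascus_id", "kind", "region_class", "n_generated", "n_recovered", "fnr",
    ])


def sanger_fnr(n_missed: int, n_found: int) -> float:
    """Resequencing-based FNR: missed / (found + missed), as a fraction."""
    if n_missed < 0 or n_found < 0:
        raise ValueError("counts must be non-negative")
    total = n_missed + n_found
    if total == 0:
        raise ValueError("no Sanger observations")
    return n_missed / total


# ---------------------------------------------------------------------------
# rate estimation
# ---------------------------------------------------------------------------


def normalize_count(raw: float, fnr: float) -> float:
    """FNR-corrected count: raw / (1 - FNR)."""
    if not 0 <= fnr < 1:
        raise ValueError(f"fnr={fnr} must be in [0, 1)")
    return raw / (1.0 - fnr)


def per_bp_rate(per_genome: float, genome_size: float = REFERENCE_GENOME_SIZE) -> float:
    """Per-genome per-cycle count -> per-bp per-cycle rate."""
    return per_genome / genome_size


def per_ascus_rate(total_count: float, n_asci: int) -> float:
    if n_asci <= 0:
        raise ValueError("n_asci must be positive")
    return total_count / n_asci


def estimate_rates(
    events: pd.DataFrame,
    fnr: pd.DataFrame | None,
    region_fractions: dict[str, float] | None = None,
    genome_size: float = REFERENCE_GENOME_SIZE,
    n_asci: int | None = None,
    parent_assigned: bool = False,
) -> pd.DataFrame:
    """Regional FNR-normalized mutation rates across asci.

    ``events`` needs ascus_id / region_class / segregation columns (status
    'ok' rows only). ``fnr`` is the estimate_fnr output (joined on ascus_id,
    kind = segregation and region_class); None means no correction. Counts
    pooled over both parents are divided by 2 source parents to give a
    per-genome rate; parent-assigned counts are not halved.

    Returns one row per (segregation, region_class) plus 'all' totals with
    mean per-genome counts, sem across asci, and per-bp rates computed on
    the regional base counts.
    """
    if n_asci is None:
        n_asci = events["ascus_id"].nunique()
    if n_asci == 0:
        raise ValueError("no asci")
    region_fractions = region_fractions or DEFAULT_REGION_FRACTIONS

    fnr_lookup = {}
    if fnr is not None:
        for r in fnr.itertuples():
            fnr_lookup[(r.ascus_id, r.kind, r.region_class)] = r.fnr

    # asci with zero events still count toward the across-asci mean/sem
    asci = sorted(events["ascus_id"].unique())
    n_blank = max(0, n_asci - len(asci))
    rows = []
    seg_levels = ["2:2", "3:1"]
    per_ascus_norm: dict[tuple[str, str], np.ndarray] = {}
    for seg in seg_levels:
        for region in REGION_CLASSES:
            norm = np.zeros(len(asci) + n_blank)
            for i, ascus in enumerate(asci):
                raw = len(events[
                    (events["ascus_id"] == ascus)
                    & (events["segregation"] == seg)
                    & (events["region_class"] == region)
                ])
                f = fnr_lookup.get((ascus, seg, region), 0.0)
                if np.isnan(f) or f >= 1.0:
                    f = 0.0  # undefined / fully-missed class: no correction
                norm[i] = normalize_count(raw, f)
            per_ascus_norm[(seg, region)] = norm

    divisor = 1.0 if parent_assigned else 2.0

    def add_row(seg, region, norm):
        per_genome = norm.mean() / divisor
        sem = norm.std(ddof=1) / np.sqrt(len(norm)) / divisor if len(norm) > 1 else 0.0
        frac = region_fractions.get(region, 1.0) if region != "all" else 1.0
        rows.append((
            seg, region, float(norm.sum()), per_genome, sem,
            per_genome / (frac * genome_size),
            sem / (frac * genome_size),
        ))

    for seg in seg_levels:
        for region in REGION_CLASSES:
            add_row(seg, region, per_ascus_norm[(seg, region)])
        add_row(seg, "all", sum(per_ascus_norm[(seg, r)] for r in REGION_CLASSES))
    add_row(
        "all", "all",
        sum(per_ascus_norm[(s, r)] for s in seg_levels for r in REGION_CLASSES),
    )
    return pd.DataFrame(rows, columns=[
        "segregation", "region_class", "normalized_total", "per_genome",
        "per_genome_sem", "per_bp", "per_bp_sem",
    ])


# ---------------------------------------------------------------------------
# RIP attribution
# ---------------------------------------------------------------------------


def asexual_cycle_rate(
    daily_rate: float, cycle_days: float = 20.0
) -> float:
    """Extrapolate a per-day asexual rate to one sexual-cycle equivalent."""
    return daily_rate * cycle_days


def per_division_rate(daily_rate: float, divisions_per_day: float = 15.0) -> float:
    return daily_rate / divisions_per_day


def rip_attribution(
    rate_proficient: float, rate_deficient: float, rate_total: float
) -> float:
    """Fraction of mutations attributable to RIP:
    (proficient - deficient) / total, on any common scale.

    A negative result (deficient exceeds proficient) is returned as-is.
    """
    if rate_total == 0:
        raise ValueError("total rate is zero")
    return (rate_proficient - rate_deficient) / rate_total


# ---------------------------------------------------------------------------
# Yates-corrected chi-squared
# ---------------------------------------------------------------------------


def yates_chi2(
    table: np.ndarray | list | None = None,
    observed: np.ndarray | list | None = None,
    expected: np.ndarray | list | None = None,
) -> tuple[float, int, float]:
    """Chi-squared with Yates' continuity correction.

    Either a 2x2 ``table`` (shortcut n(|ad-bc|-n/2)^2 / (R1 R2 C1 C2), df=1)
    or ``observed`` vs ``expected`` k-vectors (sum (|O-E|-0.5)^2 / E,
    df=k-1; ``expected`` may be proportions). Returns (statistic, df, p).
    """
    if table is not None:
        t = np.asarray(table, dtype=float)
        if t.shape != (2, 2):
            raise ValueError("table must be 2x2")
        if (t < 0).any():
            raise ValueError("negative counts")
        a, b, c, d = t.ravel()
        n = t.sum()
        r1, r2 = t.sum(axis=1)
        c1, c2 = t.sum(axis=0)
        if min(r1, r2, c1, c2) == 0:
            raise ValueError("a marginal total is zero")
        stat = n * (max(abs(a * d - b * c) - n / 2.0, 0.0)) ** 2 / (r1 * r2 * c1 * c2)
        df = 1
    else:
        obs = np.asarray(observed, dtype=float)
        exp = np.asarray(expected, dtype=float)
        if obs.shape != exp.shape:
            raise ValueError("observed and expected must have the same shape")
        if (obs < 0).any():
            raise ValueError("negative counts")
        if not np.isclose(exp.sum(), obs.sum()):
            exp = exp / exp.sum() * obs.sum()  # proportions -> expected counts
        if (exp <= 0).any():
            raise ValueError("expected counts must be positive")
        stat = float((((np.abs(obs - exp) - 0.5).clip(min=0.0)) ** 2 / exp).sum())
        df = obs.size - 1
    p = float(chi2_dist.sf(stat, df))
    return float(stat), int(df), p
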