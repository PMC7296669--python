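"""De novo mutation identification from parent + four-spore call sets.

Implements the haploid trio-style filter (homozygous, quality >= 30, depth
>= 5 in spore and parents, different from both parental alleles), octad
segregation classification from the four sampled non-sister spores
(2 carriers -> 2:2; 1 or 3 carriers -> 3:1), parent-of-origin assignment
from flanking parental SNPs, and a windowed-depth screen for spontaneous
duplications.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeAssembly
from .simulate import AscusCalls, PARENTS, SPORES

REJECT_REASONS = (
    "heterozygous", "quality", "depth", "parent_depth", "inherited",
    "homopolymer",
)


def _homopolymer_mask(genome: GenomeAssembly, min_run: int = 6, margin: int = 3) -> dict[str, np.ndarray]:
    """Per-contig boolean mask of sites within `margin` bp of a homopolymer
    run of length >= min_run in the reference."""
    masks = {}
    for contig, codes in genome.sequences.items():
        mask = np.zeros(codes.size, dtype=bool)
        change = np.flatnonzero(np.diff(codes) != 0)
        starts = np.concatenate([[0], change + 1])
        ends = np.concatenate([change + 1, [codes.size]])
        for s, e in zip(starts, ends):
            if e - s >= min_run:
                mask[max(0, s - margin): min(codes.size, e + margin)] = True
        masks[contig] = mask
    return masks


def filter_variant_calls(
    ascus: AscusCalls,
    min_qual: float = 30.0,
    min_depth: int = 5,
    genome: GenomeAssembly | None = None,
) -> pd.DataFrame:
    """Filter spore calls down to candidate de novo sites.

    Returns the spore-call table with boolean ``passed`` and a ``reason``
    code for every rejected call. Missing parent information at a site is a
    rejection reason, never an exception.
    """
    calls = ascus.calls
    spore_calls = calls[calls["sample_id"].isin(SPORES)].copy()
    if len(spore_calls) == 0:
        spore_calls["passed"] = pd.Series(dtype=bool)
        spore_calls["reason"] = pd.Series(dtype=object)
        return spore_calls

    # parental allele lookup: parent call alt if called there, else reference
    parent_alleles = {}
    for parent in PARENTS:
        sub = calls[(calls["sample_id"] == parent) & (calls["zygosity"] == "hom")]
        parent_alleles[parent] = {
            (r.contig, r.pos): r.alt for r in sub.itertuples()
        }

    reasons = np.full(len(spore_calls), "", dtype=object)
    passed = np.ones(len(spore_calls), dtype=bool)

    def reject(mask, reason):
        newly = mask & passed
        reasons[newly] = reason
        passed[newly] = False

    reject((spore_calls["zygosity"] != "hom").to_numpy(), "heterozygous")
    reject((spore_calls["qual"] < min_qual).to_numpy(), "quality")
    reject((spore_calls["depth"] < min_depth).to_numpy(), "depth")

    # parent depth >= min_depth at the site, for both parents
    pdepth_ok = np.ones(len(spore_calls), dtype=bool)
    for parent in PARENTS:
        for contig, sub in spore_calls.groupby("contig"):
            d = ascus.depth_at(parent, contig, sub["pos"].to_numpy())
            idx = spore_calls.index.get_indexer(sub.index)
            pdepth_ok[idx] &= d >= min_depth
    reject(~pdepth_ok, "parent_depth")

    # must differ from both parents' alleles at the site (de novo, not inherited)
    inherited = np.zeros(len(spore_calls), dtype=bool)
    for i, r in enumerate(spore_calls.itertuples()):
        for parent in PARENTS:
            allele = parent_alleles[parent].get((r.contig, r.pos), r.ref)
            if r.alt == allele:
                inherited[i] = True
    reject(inherited, "inherited")

    if genome is not None:
        masks = _homopolymer_mask(genome)
        hp = np.array([
            bool(masks[r.contig][r.pos - 1]) for r in spore_calls.itertuples()
        ])
        reject(hp, "homopolymer")

    spore_calls["passed"] = passed
    spore_calls["reason"] = reasons
    return spore_calls


def classify_segregation(
    candidates: pd.DataFrame,
    ascus: AscusCalls,
    min_depth: int = 5,
) -> pd.DataFrame:
    """Group passing candidate calls into mutation events with 2:2/3:1 labels.

    Carriers are the spores with a passing call at the site. Every
    non-carrier spore must be confirmed covered (depth >= min_depth) for the
    event to be resolvable; otherwise it is held out with status
    'unresolvable' and excluded from rate numerators (the FNR normalisation
    covers that coverage loss). Carrier counts of 0 or 4 are rejected as
    indistinguishable from parental-call failure.
    """
    cols = [
        "ascus_id", "contig", "pos", "ref", "alt", "carriers", "n_carriers",
        "segregation", "status", "is_CtoT",
    ]
    passing = candidates[candidates["passed"]]
    if len(passing) == 0:
        return pd.DataFrame(columns=cols)

    sites = (
        passing.groupby(["contig", "pos", "ref", "alt"], sort=True)["sample_id"]
        .agg(lambda s: tuple(sorted(set(s))))
        .reset_index(name="carriers")
    )
    # spore coverage at every site, vectorized per contig
    covered = {}
    for spore in SPORES:
        ok = np.zeros(len(sites), dtype=bool)
        for contig, sub in sites.groupby("contig"):
            idx = sites.index.get_indexer(sub.index)
            ok[idx] = ascus.depth_at(spore, contig, sub["pos"].to_numpy()) >= min_depth
        covered[spore] = ok
    # non-carrier spores with a *failed* call at the site are ambiguous
    failed = set(
        map(tuple, candidates.loc[~candidates["passed"],
                                  ["contig", "pos", "sample_id"]].itertuples(index=False))
    )

    rows = []
    for i, r in enumerate(sites.itertuples()):
        carriers = r.carriers
        others = [s for s in SPORES if s not in carriers]
        n = len(carriers)
        all_covered = all(covered[s][i] for s in others)
        ambiguous = any((r.contig, r.pos, s) in failed for s in others)
        if n == 0 or n == 4:
            status, segregation = "rejected", "none"
        elif not all_covered or ambiguous:
            status = "unresolvable"
            segregation = "2:2" if n == 2 else "3:1"
        else:
            status = "ok"
            segregation = "2:2" if n == 2 else "3:1"
        rows.append((
            ascus.ascus_id, r.contig, r.pos, r.ref, r.alt, carriers, n,
            segregation, status, (r.ref, r.alt) in (("C", "T"), ("G", "A")),
        ))
    return pd.DataFrame(rows, columns=cols)


def assign_parent_origin(
    events: pd.DataFrame,
    ascus: AscusCalls,
    window_bp: int = 50_000,
) -> pd.DataFrame:
    """Attach parent of origin from the nearest flanking parental SNPs.

    A parental SNP is a homozygous parent_a call (the reference plays the
    role of parent_A). Carrier spores that agree with parent_a's allele at
    both flanking SNPs inherited the mutation on the parent_a chromosome and
    vice versa; discordant flanks (a recombination breakpoint) or SNP
    deserts yield 'unassigned'.
    """
    calls = ascus.calls
    snps = calls[(calls["sample_id"] == "parent_a") & (calls["zygosity"] == "hom")]
    snp_pos = {c: sub["pos"].to_numpy() for c, sub in snps.groupby("contig")}
    spore_alt_sites = {
        s: set(
            map(tuple, calls[(calls["sample_id"] == s) & (calls["zygosity"] == "hom")]
                [["contig", "pos"]].itertuples(index=False))
        )
        for s in SPORES
    }

    def haplotype_at(spore: str, contig: str, pos: int) -> str:
        return "a" if (contig, pos) in spore_alt_sites[spore] else "A"

    origins = []
    for ev in events.itertuples():
        pos_arr = snp_pos.get(ev.contig, np.array([], dtype=int))
        left = pos_arr[(pos_arr < ev.pos) & (pos_arr >= ev.pos - window_bp)]
        right = pos_arr[(pos_arr > ev.pos) & (pos_arr <= ev.pos + window_bp)]
        flanks = [int(left[-1])] if left.size else []
        flanks += [int(right[0])] if right.size else []
        if not flanks:
            origins.append("unassigned")
            continue
        votes = {
            haplotype_at(spore, ev.contig, f)
            for spore in ev.carriers
            for f in flanks
        }
        origins.append(votes.pop() if len(votes) == 1 else "unassigned")
    out = events.copy()
    out["parent_of_origin"] = origins
    return out


def windowed_depth(
    ascus: AscusCalls, window: int = 1000
) -> pd.DataFrame:
    """Median depth per (sample, contig, window) for the duplication screen."""
    rows = []
    for sample, per_contig in ascus.depth.items():
        for contig, arr in per_contig.items():
            n_win = arr.size // window
            trimmed = arr[: n_win * window].reshape(n_win, window)
            medians = np.median(trimmed, axis=1)
            for i, m in enumerate(medians):
                rows.append((sample, contig, i * window, (i + 1) * window, float(m)))
    return pd.DataFrame(rows, columns=["sample_id", "contig", "start", "end", "depth"])


def screen_spontaneous_duplications(
    depth_windows: pd.DataFrame,
    ratio_low: float = 1.75,
    ratio_high: float = 2.5,
) -> pd.DataFrame:
    """Windows at ~2x copy number in exactly 2 of 4 spores but not parents.

    Depth is normalised per sample by its genome-wide median before ratios
    are taken against the mean of the two parents; windows with zero
    parental depth are skipped. Consecutive candidate windows are merged.
    """
    df = depth_windows.copy()
    med = df.groupby("sample_id")["depth"].transform("median")
    df["norm"] = df["depth"] / med.replace(0, np.nan)
    wide = df.pivot_table(
        index=["contig", "start", "end"], columns="sample_id", values="norm"
    )
    parent_mean = wide[list(PARENTS)].mean(axis=1)
    valid = parent_mean > 0
    ratios = wide[list(SPORES)].div(parent_mean, axis=0)
    in_band = (ratios >= ratio_low) & (ratios <= ratio_high)
    parent_dup = (wide[list(PARENTS)] >= ratio_low).any(axis=1)
    hit = valid & (in_band.sum(axis=1) == 2) & ~parent_dup
    cand = wide.index[hit].to_frame(index=False)
    if len(cand) == 0:
        return pd.DataFrame(columns=["contig", "start", "end", "carrier_spores"])
    carrier_map = {
        idx: tuple(ratios.columns[in_band.loc[idx]])
        for idx in wide.index[hit]
    }
    # merge consecutive windows sharing the same carrier pair
    out = []
    cand = cand.sort_values(["contig", "start"])
    cur = None
    for r in cand.itertuples():
        key = (r.contig, r.start, r.end)
        spores = carrier_map[key]
        if cur and cur[0] == r.contig and cur[2] == r.start and cur[3] == spores:
            cur = (cur[0], cur[1], r.end, spores)
        else:
            if cur:
                out.append(cur)
            cur = (r.contig, r.start, r.end, spores)
    out.append(cur)
    return pd.DataFrame(out, columns=["contig", "start", "end", "carrier_spores"])


@dataclass
class CallingResult:
    candidates: pd.DataFrame
    events: pd.DataFrame  # resolvable de novo events with origin


def call_mutations(
    ascus: AscusCalls,
    genome: GenomeAssembly | None = None,
    min_qual: float = 30.0,
    min_depth: int = 5,
    origin_window_bp: int = 50_000,
) -> CallingResult:
    """Convenience pipeline: filter -> classify -> assign origin."""
    candidates = filter_variant_calls(ascus, min_qual, min_depth, genome)
    events = classify_segregation(candidates, ascus, min_depth)
    events = assign_parent_origin(events, ascus, origin_window_bp)
    return CallingResult(candidates=candidates, events=events)
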