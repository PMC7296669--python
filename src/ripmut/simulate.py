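"""Synthetic genomes, tetrads and read-depth profiles.

The generator emulates the statistical structure a haploid tetrad-sequencing
experiment assumes: a multi-contig genome carrying long AT-rich TE-like
duplicate pairs and short GC-rich CDS-like duplicate pairs; premeiotic RIP
mutations laid down as clustered, strand-exclusive C->T (or G->A) runs over
the G:C sites of duplicate copies; a low-rate mitotic background with an
unskewed 12-class spectrum; post-meiotic events carried by a single spore;
and per-site negative-binomial read depth with low-coverage patches that
create realistic false negatives downstream.

Ground truth (event labels, segregation, parent of origin) is returned with
every simulation so each downstream stage can be tested without external
data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import (
    GenomeAssembly,
    decode,
    empty_intervals,
    merge_intervals,
)

SPORES = ("spore_1", "spore_2", "spore_3", "spore_4")
PARENTS = ("parent_A", "parent_a")

# base codes: A=0 C=1 G=2 T=3
_C, _G, _T, _A = 1, 2, 3, 0


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass
class SimConfig:
    """Parameters of one simulated cross.

    Lengths are bp, rates are per-site probabilities per sexual cycle unless
    stated otherwise. Defaults mirror the architecture of the *N. crassa*
    study system at ~1/100 genome scale: ~16% of the genome in duplicates,
    TE-like duplicates of mean length 2030 bp at GC 0.374, CDS-like
    duplicates of mean length 338 bp at GC 0.546, CDS fraction 0.375.
    """

    seed: int = 0
    n_contigs: int = 2
    contig_length: int = 200_000
    n_te_duplicates: int = 15
    te_dup_length_mean: float = 2030.0
    te_dup_gc: float = 0.374
    n_cds_duplicates: int = 8
    cds_dup_length_mean: float = 338.0
    cds_dup_gc: float = 0.546
    dup_divergence: float = 0.08  # substitutions between the two copies
    background_gc: float = 0.50
    cds_fraction: float = 0.375
    centromere_length: int = 10_000
    centromere_gc: float = 0.30
    parental_snp_rate: float = 0.005
    # contigs are ~1/30-scale chromosomes, so well under one crossover each
    crossovers_per_contig: float = 0.3
    # RIP model: per duplicate G:C site marginal mutation probability per
    # cycle; runs of geometric length rip_run_mean over consecutive same-
    # strand C (or G) sites, leaking into +-rip_flank_leak_bp of flank with
    # probability rip_flank_leak_prob.
    rip_rate_per_gc_site: float = 1e-3
    rip_run_mean: float = 8.0
    rip_flank_leak_bp: int = 400
    rip_flank_leak_prob: float = 0.1
    # mitotic background (premeiotic, per parent lineage)
    mitotic_rate_per_bp_per_division: float = 6.03e-10
    divisions: int = 300
    # post-meiotic events, per bp per spore per cycle
    post_meiotic_rate: float = 8e-7
    # read-depth model
    depth_mean: float = 37.0
    parent_depth_mean: float = 76.0
    depth_dispersion: float = 8.0
    low_coverage_fraction: float = 0.05
    low_coverage_patch_bp: int = 2000
    depth_floor: int = 0  # clip depth draws from below (0 = no floor)
    # optional call-level noise to exercise the filters
    noise_het_per_dup_kb: float = 0.0
    noise_lowqual_per_genome: float = 0.0

    def validate(self) -> None:
        fractions = {
            "te_dup_gc": self.te_dup_gc,
            "cds_dup_gc": self.cds_dup_gc,
            "background_gc": self.background_gc,
            "cds_fraction": self.cds_fraction,
            "centromere_gc": self.centromere_gc,
            "dup_divergence": self.dup_divergence,
            "low_coverage_fraction": self.low_coverage_fraction,
            "rip_flank_leak_prob": self.rip_flank_leak_prob,
            "parental_snp_rate": self.parental_snp_rate,
        }
        for name, value in fractions.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name}={value} must be in [0, 1]")
        if not 0.0 <= self.rip_rate_per_gc_site <= 1.0:
            raise ConfigurationError("rip_rate_per_gc_site must be in [0, 1]")
        positive = {
            "n_contigs": self.n_contigs,
            "contig_length": self.contig_length,
            "te_dup_length_mean": self.te_dup_length_mean,
            "cds_dup_length_mean": self.cds_dup_length_mean,
            "depth_mean": self.depth_mean,
            "depth_dispersion": self.depth_dispersion,
            "rip_run_mean": self.rip_run_mean,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ConfigurationError(f"{name}={value} must be positive")
        for name in ("n_te_duplicates", "n_cds_duplicates", "divisions"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        dup_bp = 2 * (
            self.n_te_duplicates * self.te_dup_length_mean
            + self.n_cds_duplicates * self.cds_dup_length_mean
        )
        budget = self.n_contigs * (self.contig_length - self.centromere_length)
        if dup_bp > 0.5 * budget:
            raise ConfigurationError(
                f"requested duplicate sequence ({dup_bp:.0f} bp) exceeds half of "
                f"the placeable genome ({budget} bp); increase contig_length or "
                f"reduce duplicate counts/lengths"
            )

    @property
    def genome_size(self) -> int:
        return self.n_contigs * self.contig_length

    def expected_mitotic_per_bp(self) -> float:
        """Expected premeiotic mitotic mutations per bp per haploid genome
        per cycle (closed form; RIP and post-meiotic events not included)."""
        return self.mitotic_rate_per_bp_per_division * self.divisions

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# genome simulation
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p).astype(np.uint8)


def _mutate_copy(rng: np.random.Generator, seq: np.ndarray, divergence: float) -> np.ndarray:
    out = seq.copy()
    hits = np.flatnonzero(rng.random(seq.size) < divergence)
    out[hits] = (out[hits] + rng.integers(1, 4, size=hits.size)) % 4
    return out.astype(np.uint8)


def _place(
    rng: np.random.Generator,
    occupied: dict[str, list[tuple[int, int]]],
    contig_length: int,
    length: int,
    contigs: list[str],
    buffer: int = 200,
) -> tuple[str, int]:
    for _ in range(500):
        contig = contigs[rng.integers(len(contigs))]
        start = int(rng.integers(0, contig_length - length))
        if all(
            start + length + buffer <= s or start >= e + buffer
            for s, e in occupied[contig]
        ):
            occupied[contig].append((start, start + length))
            return contig, start
    raise ConfigurationError(
        f"could not place a {length} bp interval: contigs of {contig_length} bp "
        f"are too short/full for the requested duplicate load"
    )


def simulate_genome(config: SimConfig) -> GenomeAssembly:
    """Build a genome with truth duplicate, CDS and centromere tracks.

    Duplicate pairs are planted as copy/diverged-copy at random non-
    overlapping loci; identity between copies is 1 - dup_divergence >= 0.65
    by construction. CDS-like duplicates are guaranteed to be covered by the
    CDS track, TE-like ones are excluded from it.
    """
    config.validate()
    rng = np.random.default_rng([int(config.seed), 11])
    contigs = [f"contig_{i+1}" for i in range(config.n_contigs)]
    seqs = {
        c: _random_seq(rng, config.contig_length, config.background_gc)
        for c in contigs
    }

    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in contigs}
    cen_rows = []
    for c in contigs:
        mid = config.contig_length // 2
        start = mid - config.centromere_length // 2
        end = start + config.centromere_length
        seqs[c][start:end] = _random_seq(
            rng, config.centromere_length, config.centromere_gc
        )
        occupied[c].append((start, end))
        cen_rows.append((c, start, end))

    dup_rows = []
    pair_id = 0
    for kind, n, mean, gc in (
        ("te", config.n_te_duplicates, config.te_dup_length_mean, config.te_dup_gc),
        ("cds", config.n_cds_duplicates, config.cds_dup_length_mean, config.cds_dup_gc),
    ):
        for _ in range(n):
            length = max(120, int(round(rng.normal(mean, 0.12 * mean))))
            source = _random_seq(rng, length, gc)
            copies = [source, _mutate_copy(rng, source, config.dup_divergence)]
            for copy_idx, copy_seq in enumerate(copies):
                # duplicates are dispersed: copies sit > 1 kb apart even after
                # flank leak, so clusters never span two distinct copies
                contig, start = _place(
                    rng, occupied, config.contig_length, length, contigs,
                    buffer=2000,
                )
                seqs[contig][start: start + length] = copy_seq
                dup_rows.append(
                    (contig, start, start + length, f"pair_{pair_id}", kind, copy_idx)
                )
            pair_id += 1
    duplicates = pd.DataFrame(
        dup_rows, columns=["contig", "start", "end", "pair_id", "kind", "copy"]
    ) if dup_rows else empty_intervals(["pair_id", "kind", "copy"])

    # CDS track: cover the cds-kind duplicates, then add random gene-sized
    # intervals outside TE duplicates/centromeres until cds_fraction is hit.
    cds_rows = [
        (r.contig, max(0, r.start - 100), min(config.contig_length, r.end + 100))
        for r in duplicates.itertuples()
        if r.kind == "cds"
    ]
    target = config.cds_fraction * config.genome_size
    covered = sum(e - s for _, s, e in cds_rows)
    attempts = 0
    while covered < target and attempts < 20_000:
        attempts += 1
        length = max(300, int(rng.normal(1500, 400)))
        contig = contigs[rng.integers(len(contigs))]
        start = int(rng.integers(0, config.contig_length - length))
        clash = any(
            not (start + length <= s or start >= e)
            for s, e in occupied[contig]
        )
        if clash:
            continue
        cds_rows.append((contig, start, start + length))
        covered += length
    cds = merge_intervals(pd.DataFrame(cds_rows, columns=["contig", "start", "end"])) \
        if cds_rows else empty_intervals()

    return GenomeAssembly(
        sequences=seqs,
        duplicates=duplicates,
        cds=cds,
        centromeres=pd.DataFrame(cen_rows, columns=["contig", "start", "end"]),
    )


# ---------------------------------------------------------------------------
# tetrad simulation
# ---------------------------------------------------------------------------

EVENT_COLUMNS = [
    "contig", "pos", "ref", "alt", "stage", "parent", "carriers",
    "segregation", "run_id",
]


@dataclass
class TetradTruth:
    """Ground truth for one ascus: de novo events, parental SNPs, and the
    meiotic segment structure that maps positions to carrier spores."""

    tetrad_id: int
    genome: GenomeAssembly
    events: pd.DataFrame  # EVENT_COLUMNS; pos 0-based; carriers: tuple of spore names
    snps: pd.DataFrame  # contig, pos (0-based), ref, alt (parent_a vs reference)
    segments: dict[str, tuple[np.ndarray, list[frozenset]]]
    # per contig: (breakpoint positions, A-carrier spore set per segment)

    def a_carriers(self, contig: str, pos: np.ndarray) -> list[frozenset]:
        """Which two spores carry the parent_A haplotype at each position."""
        breaks, pairs = self.segments[contig]
        idx = np.searchsorted(breaks, pos, side="right")
        return [pairs[i] for i in idx]

    def spore_carries_a_haplotype(self, spore: str, contig: str, pos: np.ndarray) -> np.ndarray:
        return np.array([spore in s for s in self.a_carriers(contig, pos)])

    def spore_variants(self, spore: str) -> pd.DataFrame:
        """All sites where a spore differs from the reference (parent_A):
        inherited parent_a SNPs plus carried de novo events."""
        rows = []
        for contig, sub in self.snps.groupby("contig"):
            pos = sub["pos"].to_numpy()
            has_a = self.spore_carries_a_haplotype(spore, contig, pos)
            inherited = sub.loc[~has_a]
            for r in inherited.itertuples():
                rows.append((r.contig, r.pos, r.ref, r.alt, "snp"))
        for r in self.events.itertuples():
            if spore in r.carriers:
                rows.append((r.contig, r.pos, r.ref, r.alt, "de_novo"))
        df = pd.DataFrame(rows, columns=["contig", "pos", "ref", "alt", "source"])
        return df.sort_values(["contig", "pos"]).reset_index(drop=True)


def _meiotic_segments(
    rng: np.random.Generator, contig_length: int, mean_crossovers: float = 1.0
) -> tuple[np.ndarray, list[frozenset]]:
    n_co = rng.poisson(mean_crossovers)
    breaks = np.sort(rng.integers(1, contig_length, size=n_co))
    pairs = []
    current = set(rng.choice(4, size=2, replace=False))
    pairs.append(frozenset(SPORES[i] for i in current))
    for _ in range(n_co):
        # a crossover exchanges one chromatid between the two parental sets
        leave = rng.choice(sorted(current))
        join = rng.choice(sorted(set(range(4)) - current))
        current = (current - {leave}) | {join}
        pairs.append(frozenset(SPORES[i] for i in current))
    return breaks, pairs


def _strand_site_positions(codes: np.ndarray, start: int, end: int, base: int) -> np.ndarray:
    return start + np.flatnonzero(codes[start:end] == base)


def simulate_tetrad(
    genome: GenomeAssembly, config: SimConfig, tetrad_id: int = 0
) -> TetradTruth:
    """Simulate one cross/ascus on a genome with truth duplicate annotations.

    Premeiotic RIP runs mutate only C (or only G) sites on one strand of one
    duplicate copy of one parent; mitotic background events are uniform with
    an unskewed spectrum; both kinds segregate 2:2. Post-meiotic events are
    carried by exactly one of the four sampled spores (3:1).
    """
    config.validate()
    if len(genome.duplicates) == 0 and config.rip_rate_per_gc_site > 0:
        raise ConfigurationError(
            "rip_rate_per_gc_site > 0 requires truth duplicate annotations"
        )
    rng = np.random.default_rng([int(config.seed), 23, int(tetrad_id)])
    lengths = genome.contig_lengths()

    segments = {
        c: _meiotic_segments(rng, n, config.crossovers_per_contig)
        for c, n in lengths.items()
    }

    # parental SNPs (parent_a relative to the reference parent_A)
    snp_rows = []
    for contig, codes in genome.sequences.items():
        n = rng.binomial(codes.size, config.parental_snp_rate)
        pos = np.sort(rng.choice(codes.size, size=n, replace=False))
        ref = codes[pos]
        alt = (ref + rng.integers(1, 4, size=n)) % 4
        for p, r, a in zip(pos, ref, alt):
            snp_rows.append((contig, int(p), decode(np.array([r], np.uint8)),
                             decode(np.array([a], np.uint8))))
    snps = pd.DataFrame(snp_rows, columns=["contig", "pos", "ref", "alt"])
    snp_index = {
        (r.contig, r.pos) for r in snps.itertuples()
    }

    truth = TetradTruth(
        tetrad_id=tetrad_id, genome=genome, events=pd.DataFrame(columns=EVENT_COLUMNS),
        snps=snps, segments=segments,
    )

    events: list[tuple] = []
    used: set[tuple[str, int]] = set(snp_index)
    run_id = itertools.count()

    def add_event(contig, pos, ref_code, alt_code, stage, parent, carriers, seg, run):
        key = (contig, int(pos))
        if key in used:
            return
        used.add(key)
        events.append((
            contig, int(pos),
            decode(np.array([ref_code], np.uint8)),
            decode(np.array([alt_code], np.uint8)),
            stage, parent, carriers, seg, run,
        ))

    # --- premeiotic RIP runs over duplicate copies, per parent lineage ---
    if config.rip_rate_per_gc_site > 0:
        for parent in PARENTS:
            for dup in genome.duplicates.itertuples():
                codes = genome.sequences[dup.contig]
                n_gc = int(np.isin(codes[dup.start:dup.end], (_C, _G)).sum())
                if n_gc == 0:
                    continue
                lam = config.rip_rate_per_gc_site * n_gc
                attack_p = min(1.0, lam / config.rip_run_mean)
                if rng.random() >= attack_p:
                    continue
                strand_base = _C if rng.random() < 0.5 else _G
                alt_code = _T if strand_base == _C else _A
                lo, hi = dup.start, dup.end
                if rng.random() < config.rip_flank_leak_prob:
                    lo = max(0, lo - config.rip_flank_leak_bp)
                    hi = min(codes.size, hi + config.rip_flank_leak_bp)
                sites = _strand_site_positions(codes, lo, hi, strand_base)
                if sites.size == 0:
                    continue
                k = min(int(rng.geometric(1.0 / config.rip_run_mean)), sites.size)
                anchor = int(rng.integers(0, sites.size))
                start_i = min(anchor, sites.size - k)
                chosen = sites[start_i: start_i + k]
                rid = next(run_id)
                a_sets = truth.a_carriers(dup.contig, chosen)
                for pos, a_set in zip(chosen, a_sets):
                    carriers = (
                        tuple(sorted(a_set)) if parent == "parent_A"
                        else tuple(sorted(set(SPORES) - a_set))
                    )
                    add_event(dup.contig, pos, strand_base, alt_code,
                              "premeiotic_RIP", parent, carriers, "2:2", rid)

    # --- premeiotic mitotic background, unskewed spectrum ---
    mito_rate = config.expected_mitotic_per_bp()
    for parent in PARENTS:
        for contig, codes in genome.sequences.items():
            n = rng.poisson(mito_rate * codes.size)
            pos = rng.integers(0, codes.size, size=n)
            for p in pos:
                ref = codes[p]
                alt = (ref + rng.integers(1, 4)) % 4
                a_set = truth.a_carriers(contig, np.array([p]))[0]
                carriers = (
                    tuple(sorted(a_set)) if parent == "parent_A"
                    else tuple(sorted(set(SPORES) - a_set))
                )
                add_event(contig, p, ref, alt, "premeiotic_mitotic", parent,
                          carriers, "2:2", next(run_id))

    # --- post-meiotic events: one spore each ---
    for spore in SPORES:
        for contig, codes in genome.sequences.items():
            n = rng.poisson(config.post_meiotic_rate * codes.size)
            pos = rng.integers(0, codes.size, size=n)
            for p in pos:
                ref = codes[p]
                alt = (ref + rng.integers(1, 4)) % 4
                add_event(contig, p, ref, alt, "post_meiotic", "none",
                          (spore,), "3:1", next(run_id))

    truth.events = (
        pd.DataFrame(events, columns=EVENT_COLUMNS)
        .sort_values(["contig", "pos"])
        .reset_index(drop=True)
    )
    return truth


# ---------------------------------------------------------------------------
# depth and call-set simulation
# ---------------------------------------------------------------------------


@dataclass
class AscusCalls:
    """Per-sample variant calls and read-depth profiles for one ascus."""

    ascus_id: int
    calls: pd.DataFrame  # sample_id, contig, pos (1-based), ref, alt, qual, depth, zygosity
    depth: dict[str, dict[str, np.ndarray]]  # sample -> contig -> per-site depth
    contig_lengths: dict[str, int] = field(default_factory=dict)

    @property
    def spores(self) -> tuple[str, ...]:
        return SPORES

    @property
    def parents(self) -> tuple[str, ...]:
        return PARENTS

    def depth_at(self, sample: str, contig: str, pos1: np.ndarray) -> np.ndarray:
        return self.depth[sample][contig][np.asarray(pos1, dtype=int) - 1]

    def write_vcfs(self, outdir: str | Path) -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = []
        for sample in PARENTS + SPORES:
            path = outdir / f"ascus{self.ascus_id}_{sample}.vcf"
            sub = self.calls[self.calls["sample_id"] == sample]
            write_vcf(sub, sample, self.contig_lengths, path)
            paths.append(path)
        return paths


def write_vcf(
    calls: pd.DataFrame, sample: str, contig_lengths: dict[str, int], path: str | Path
) -> None:
    """Write a minimal haploid VCF v4.2 (GT 1 for hom, 0/1 for het artifacts)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for contig, length in contig_lengths.items():
            fh.write(f"##contig=<ID={contig},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample + "\n"
        )
        sub = calls.sort_values(["contig", "pos"])
        for r in sub.itertuples():
            gt = "1" if r.zygosity == "hom" else "0/1"
            fh.write(
                f"{r.contig}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t{r.qual:.0f}\t.\t.\t"
                f"GT:DP\t{gt}:{int(r.depth)}\n"
            )


def _depth_profile(
    rng: np.random.Generator, length: int, mean: float, dispersion: float,
    low_frac: float, patch_bp: int, floor: int = 0,
) -> np.ndarray:
    p = dispersion / (dispersion + mean)
    depth = rng.negative_binomial(dispersion, p, size=length).astype(np.int32)
    if floor > 0:
        np.maximum(depth, floor, out=depth)
    if low_frac > 0:
        n_patches = max(1, int(round(low_frac * length / patch_bp)))
        for _ in range(n_patches):
            start = int(rng.integers(0, max(1, length - patch_bp)))
            depth[start:start + patch_bp] = rng.poisson(2.0, size=min(patch_bp, length - start))
    return depth


def _qual_model(depth: np.ndarray) -> np.ndarray:
    # homozygous haploid calls: quality grows with supporting depth;
    # depth >= 5 implies qual >= 40, depth <= 2 falls below the 30 cutoff
    return 20.0 + 4.0 * np.asarray(depth, dtype=float)


def simulate_depth_and_calls(
    truth: TetradTruth, config: SimConfig
) -> AscusCalls:
    """Turn tetrad truth into per-sample call sets with drawn depths.

    Every true variant with local depth >= 3 appears as a homozygous call;
    sites inside low-coverage patches fall below the depth-5 filter and
    become false negatives downstream. Optional noise injects haploid
    'heterozygous' artifact calls inside duplicates and low-quality calls.
    """
    config.validate()
    rng = np.random.default_rng([int(config.seed), 37, int(truth.tetrad_id)])
    genome = truth.genome
    lengths = genome.contig_lengths()

    depth: dict[str, dict[str, np.ndarray]] = {}
    for sample in PARENTS + SPORES:
        mean = config.parent_depth_mean if sample in PARENTS else config.depth_mean
        depth[sample] = {
            c: _depth_profile(
                rng, n, mean, config.depth_dispersion,
                config.low_coverage_fraction, config.low_coverage_patch_bp,
                config.depth_floor,
            )
            for c, n in lengths.items()
        }

    rows = []

    def emit(sample, contig, pos0, ref, alt, zygosity="hom", qual=None):
        d = int(depth[sample][contig][pos0])
        if d < 3:  # too few reads for the caller to emit anything
            return
        q = _qual_model(d) if qual is None else qual
        rows.append((sample, contig, int(pos0) + 1, ref, alt, float(q), d, zygosity))

    # parent_a: SNP calls against the reference
    for r in truth.snps.itertuples():
        emit("parent_a", r.contig, r.pos, r.ref, r.alt)

    # spores: inherited SNPs plus carried de novo events
    for spore in SPORES:
        variants = truth.spore_variants(spore)
        for r in variants.itertuples():
            emit(spore, r.contig, r.pos, r.ref, r.alt)

    # optional noise
    if config.noise_het_per_dup_kb > 0 and len(genome.duplicates):
        merged = merge_intervals(genome.duplicates)
        for spore in SPORES:
            for reg in merged.itertuples():
                lam = config.noise_het_per_dup_kb * (reg.end - reg.start) / 1000.0
                for _ in range(rng.poisson(lam)):
                    pos0 = int(rng.integers(reg.start, reg.end))
                    ref = genome.sequence(reg.contig, pos0, pos0 + 1)
                    alt = decode(np.array([(genome.sequences[reg.contig][pos0]
                                            + rng.integers(1, 4)) % 4], np.uint8))
                    emit(spore, reg.contig, pos0, ref, alt, zygosity="het")
    if config.noise_lowqual_per_genome > 0:
        for spore in SPORES:
            n = rng.poisson(config.noise_lowqual_per_genome)
            for _ in range(n):
                contig = list(lengths)[rng.integers(len(lengths))]
                pos0 = int(rng.integers(0, lengths[contig]))
                ref = genome.sequence(contig, pos0, pos0 + 1)
                alt = decode(np.array([(genome.sequences[contig][pos0]
                                        + rng.integers(1, 4)) % 4], np.uint8))
                emit(spore, contig, pos0, ref, alt, qual=float(rng.uniform(5, 29)))

    calls = pd.DataFrame(
        rows,
        columns=["sample_id", "contig", "pos", "ref", "alt", "qual", "depth", "zygosity"],
    ).sort_values(["sample_id", "contig", "pos"]).reset_index(drop=True)
    return AscusCalls(
        ascus_id=truth.tetrad_id, calls=calls, depth=depth, contig_lengths=lengths
    )
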