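"""Duplicate detectors: self-alignment, depth, het, periodicity, classes."""

import numpy as np
import pandas as pd
import pytest

from ripmut.duplicates import (
    classify_site,
    find_duplicates_blast,
    find_duplicates_depth,
    find_duplicates_het,
    find_duplicates_period,
    method_efficiency,
    summarize_regions,
)
from ripmut.genome import (
    GenomeAssembly,
    decode,
    encode,
    merge_intervals,
    points_in_intervals,
    total_length,
)
from ripmut.rates import yates_chi2

from conftest import toy_genome


def _random_genome(rng, length, gc=0.5):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(4, size=length, p=p).astype(np.uint8)


def _planted_pair(seed=0, length=6000, copy_len=200, divergence=0.0,
                  at1=1000, at2=4000):
    rng = np.random.default_rng(seed)
    codes = _random_genome(rng, length)
    segment = _random_genome(rng, copy_len)
    copy = segment.copy()
    n_mut = int(round(divergence * copy_len))
    if n_mut:
        sites = rng.choice(copy_len, size=n_mut, replace=False)
        copy[sites] = (copy[sites] + rng.integers(1, 4, size=n_mut)) % 4
    codes[at1:at1 + copy_len] = segment
    codes[at2:at2 + copy_len] = copy
    return GenomeAssembly(sequences={"chr1": codes})


class TestDupBlast:
    def test_verbatim_200bp_copy_found_both_loci_identity_one(self):
        g = _planted_pair(copy_len=200)
        regions, hits = find_duplicates_blast(g)
        assert len(hits) >= 1
        assert np.isclose(hits["identity"].max(), 1.0)
        covered = merge_intervals(regions)
        for start in (1000, 4000):
            inside = points_in_intervals(
                np.array(["chr1", "chr1"], dtype=object),
                np.array([start + 10, start + 190]), covered,
            )
            assert inside.all()

    def test_99bp_perfect_repeat_excluded(self):
        g = _planted_pair(copy_len=99)
        regions, hits = find_duplicates_blast(g)
        hit99 = hits[(hits["length"] >= 90) & (hits["length"] < 100)]
        assert len(hit99) == 0
        assert not points_in_intervals(
            np.array(["chr1"], dtype=object), np.array([1050]),
            merge_intervals(regions),
        )[0]

    def test_low_identity_pair_excluded(self):
        # ~36% divergence leaves identity near 0.64, under the >65% cutoff
        g = _planted_pair(copy_len=150, divergence=0.36, seed=5)
        regions, _ = find_duplicates_blast(g)
        found = points_in_intervals(
            np.array(["chr1"], dtype=object), np.array([1075]),
            merge_intervals(regions),
        )[0]
        assert not found

    def test_diverged_but_qualifying_pair_found(self):
        g = _planted_pair(copy_len=300, divergence=0.10, seed=6)
        regions, hits = find_duplicates_blast(g)
        assert len(hits) >= 1
        assert (hits["identity"] > 0.65).all()
        assert (hits["length"] >= 100).all()

    def test_truth_recovery_on_simulated_genome(self, genome):
        regions, _ = find_duplicates_blast(genome)
        truth = merge_intervals(genome.duplicates)
        called = merge_intervals(regions)
        recovered = 0
        for r in truth.itertuples():
            pos = np.arange(r.start, r.end)
            mask = points_in_intervals(
                np.array([r.contig] * pos.size, dtype=object), pos, called
            )
            recovered += int(mask.sum())
        assert recovered >= 0.95 * total_length(truth)


class TestDupDepth:
    def _windows(self, depths, contig="chr1"):
        return pd.DataFrame({
            "contig": contig, "start": np.arange(len(depths)) * 1000,
            "end": (np.arange(len(depths)) + 1) * 1000, "depth": depths,
        })

    def test_flat_depth_gives_empty(self):
        out = find_duplicates_depth(self._windows([40.0] * 20))
        assert len(out) == 0

    def test_2x_window_reported_and_merged(self):
        depths = [40.0] * 20
        depths[5] = depths[6] = 80.0
        out = find_duplicates_depth(self._windows(depths))
        assert len(out) == 1
        assert (out.iloc[0]["start"], out.iloc[0]["end"]) == (5000, 7000)

    def test_1_2x_window_below_band_excluded(self):
        depths = [40.0] * 20
        depths[5] = 48.0
        assert len(find_duplicates_depth(self._windows(depths))) == 0

    def test_zero_median_raises(self):
        with pytest.raises(ValueError, match="median"):
            find_duplicates_depth(self._windows([0.0] * 20))


class TestDupHet:
    def _calls(self, positions, sample="spore_1", contig="chr1"):
        return pd.DataFrame({
            "sample_id": sample, "contig": contig, "pos": positions,
            "ref": "A", "alt": "G", "qual": 60.0, "depth": 40,
            "zygosity": "het",
        })

    def test_no_het_calls_gives_empty(self):
        calls = self._calls([100, 400, 900]).assign(zygosity="hom")
        assert len(find_duplicates_het(calls)) == 0

    def test_three_close_het_calls_make_one_region(self):
        out = find_duplicates_het(self._calls([100, 400, 900]))
        assert len(out) == 1
        assert out.iloc[0]["start"] <= 99 - 500 + 500  # padded
        assert out.iloc[0]["end"] >= 900 + 500

    def test_distant_het_calls_split_into_regions(self):
        out = find_duplicates_het(self._calls([100, 400, 3000, 3400]))
        assert len(out) == 2


class TestDupPeriod:
    def test_period_11_repeat_reported(self):
        rng = np.random.default_rng(2)
        unit = decode(_random_genome(rng, 11))
        seq = decode(_random_genome(rng, 2000)) + unit * 60 + \
            decode(_random_genome(rng, 2000))
        g = toy_genome(seq)
        out = find_duplicates_period(g)
        assert len(out) == 1
        assert out.iloc[0]["start"] < 2000 + 660 < out.iloc[0]["end"]

    def test_random_sequence_not_reported(self):
        rng = np.random.default_rng(3)
        g = toy_genome(decode(_random_genome(rng, 6000)))
        assert len(find_duplicates_period(g)) == 0

    def test_blast_covered_windows_excluded(self):
        rng = np.random.default_rng(4)
        unit = decode(_random_genome(rng, 11))
        seq = decode(_random_genome(rng, 2000)) + unit * 60 + \
            decode(_random_genome(rng, 2000))
        g = toy_genome(seq)
        blast_like = pd.DataFrame(
            [("chr1", 1900, 2800)], columns=["contig", "start", "end"]
        )
        out = find_duplicates_period(g, exclude=blast_like)
        assert len(out) == 0


class TestClassifySite:
    @pytest.fixture()
    def regions(self):
        return pd.DataFrame([("chr1", 2000, 3000)],
                            columns=["contig", "start", "end"])

    def _genome(self):
        return toy_genome("A" * 10_000)

    @pytest.mark.parametrize("pos, expected", [
        (2500, "within_dup"),
        (2999, "within_dup"),
        (3399, "near_dup"),   # 400 bp past the edge, still flanking
        (3400, "non_dup"),    # 401 bp past the edge
        (1600, "near_dup"),
        (100, "non_dup"),
    ])
    def test_flank_boundaries(self, regions, pos, expected):
        out = classify_site(["chr1"], [pos], regions, self._genome())
        assert out[0] == expected

    def test_precedence_within_beats_near(self, regions):
        two = pd.concat([
            regions,
            pd.DataFrame([("chr1", 3100, 3200)], columns=["contig", "start", "end"]),
        ])
        out = classify_site(["chr1"], [3150], two, self._genome())
        assert out[0] == "within_dup"

    def test_position_outside_genome_raises(self, regions):
        with pytest.raises(ValueError, match="outside"):
            classify_site(["chr1"], [20_000], regions, self._genome())

    def test_three_classes_partition_genome(self, regions):
        g = self._genome()
        pos = np.arange(0, 10_000, 97)
        out = classify_site(["chr1"] * pos.size, pos, regions, g)
        assert set(out) == {"within_dup", "near_dup", "non_dup"}


class TestEfficiencyAndSummaries:
    def test_whole_genome_method_scores_100_100(self):
        g = toy_genome("ACGT" * 2500)
        events = pd.DataFrame({
            "contig": "chr1", "pos": [10, 500, 900],
            "segregation": ["2:2"] * 3,
        })
        whole = pd.DataFrame([("chr1", 0, 10_000)],
                             columns=["contig", "start", "end"])
        table = method_efficiency(events, {"whole": whole}, g)
        row = table[table["method"] == "whole"].iloc[0]
        assert row["genome_pct"] == 100.0
        assert row["mutations_2to2_pct"] == 100.0

    def test_disjoint_methods_union_coverage_adds(self):
        g = toy_genome("ACGT" * 2500)
        events = pd.DataFrame({"contig": [], "pos": [], "segregation": []})
        a = pd.DataFrame([("chr1", 0, 1000)], columns=["contig", "start", "end"])
        b = pd.DataFrame([("chr1", 5000, 6000)], columns=["contig", "start", "end"])
        table = method_efficiency(events, {"a": a, "b": b}, g).set_index("method")
        assert np.isclose(
            table.loc["union", "genome_pct"],
            table.loc["a", "genome_pct"] + table.loc["b", "genome_pct"],
        )
        assert np.isnan(table.loc["union", "mutations_2to2_pct"])

    def test_blast_regions_enclose_rip_truth_events(self, genome, config):
        from ripmut.simulate import simulate_tetrad
        regions, _ = find_duplicates_blast(genome)
        cfg_events = simulate_tetrad(genome, config, tetrad_id=20).events
        rip = cfg_events[cfg_events["stage"] == "premeiotic_RIP"]
        events = pd.DataFrame({
            "contig": rip["contig"], "pos": rip["pos"],
            "segregation": rip["segregation"],
        })
        table = method_efficiency(events, {"blast": regions}, genome)
        assert table.iloc[0]["mutations_2to2_pct"] >= 90.0

    def test_interacting_window_contingency_matches_yates(self):
        g = toy_genome("A" * 1000)
        hic = pd.DataFrame({
            "interacting": [True] * 2376,
            "cds": [False] * 456 + [True] * 1920,
            "duplicate": [True] * 443 + [False] * 13
            + [True] * 454 + [False] * 1466,
        })
        _, table = summarize_regions(
            pd.DataFrame(columns=["contig", "start", "end"]), g.cds, g, hic
        )
        assert table.tolist() == [[443, 13], [454, 1466]]
        stat, df, p = yates_chi2(table=table)
        assert round(stat, 2) == 844.04

    def test_identical_lengths_have_zero_sem_and_at_only_gc_zero(self):
        g = toy_genome("A" * 4000)
        regs = pd.DataFrame(
            [("chr1", 0, 100), ("chr1", 1000, 1100), ("chr1", 2000, 2100)],
            columns=["contig", "start", "end"],
        )
        summary, _ = summarize_regions(
            regs, pd.DataFrame(columns=["contig", "start", "end"]), g
        )
        row = summary.iloc[0]
        assert row["mean_length"] == 100
        assert row["sem_length"] == 0.0
        assert row["mean_gc"] == 0.0
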