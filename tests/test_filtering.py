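"""Mutation identification: filters, segregation, origin, duplication screen."""

import numpy as np
import pandas as pd
import pytest

from ripmut.filtering import (
    assign_parent_origin,
    call_mutations,
    classify_segregation,
    filter_variant_calls,
    screen_spontaneous_duplications,
)
from ripmut.simulate import (
    PARENTS,
    SPORES,
    simulate_depth_and_calls,
    simulate_tetrad,
)

from conftest import make_ascus, small_config


def _reasons(ascus, **kw):
    out = filter_variant_calls(ascus, **kw)
    return dict(zip(zip(out["sample_id"], out["pos"]), out["reason"]))


class TestFilterVariantCalls:
    @pytest.mark.parametrize(
        "row, expected_reason",
        [
            (("spore_1", "chr1", 100, "A", "G", 29.0, 50, "hom"), "quality"),
            (("spore_1", "chr1", 100, "A", "G", 60.0, 4, "hom"), "depth"),
            (("spore_1", "chr1", 100, "A", "G", 60.0, 50, "het"), "heterozygous"),
        ],
    )
    def test_single_call_rejections(self, row, expected_reason):
        ascus = make_ascus([row])
        out = filter_variant_calls(ascus)
        assert not out["passed"].iloc[0]
        assert out["reason"].iloc[0] == expected_reason

    def test_inherited_parental_snp_rejected(self):
        # site is a parental SNP: spore matches parent_a allele, differs from
        # parent_A (reference) -> not de novo
        ascus = make_ascus([
            ("parent_a", "chr1", 500, "A", "G"),
            ("spore_1", "chr1", 500, "A", "G"),
        ])
        out = filter_variant_calls(ascus)
        spore = out[out["sample_id"] == "spore_1"]
        assert not spore["passed"].iloc[0]
        assert spore["reason"].iloc[0] == "inherited"

    def test_genuine_de_novo_passes(self):
        ascus = make_ascus([
            ("spore_1", "chr1", 250, "A", "T"),
            ("spore_3", "chr1", 250, "A", "T"),
        ])
        out = filter_variant_calls(ascus)
        assert out["passed"].all()

    def test_low_parent_depth_is_reason_not_exception(self):
        ascus = make_ascus([("spore_2", "chr1", 250, "A", "T")])
        ascus.depth["parent_A"]["chr1"][:] = 2
        out = filter_variant_calls(ascus)
        assert out["reason"].iloc[0] == "parent_depth"

    def test_raising_min_depth_never_retains_more(self, ascus):
        kept = [
            filter_variant_calls(ascus, min_depth=d)["passed"].sum()
            for d in (1, 5, 10, 20, 40)
        ]
        assert all(a >= b for a, b in zip(kept, kept[1:]))


class TestClassifySegregation:
    def _events(self, rows):
        ascus = make_ascus(rows)
        candidates = filter_variant_calls(ascus)
        return classify_segregation(candidates, ascus)

    def test_two_carriers_is_2to2(self):
        ev = self._events([
            ("spore_1", "chr1", 300, "C", "T"),
            ("spore_3", "chr1", 300, "C", "T"),
        ])
        assert list(ev["segregation"]) == ["2:2"]
        assert ev["status"].iloc[0] == "ok"
        assert ev["is_CtoT"].iloc[0]

    @pytest.mark.parametrize("carriers", [("spore_2",),
                                          ("spore_1", "spore_2", "spore_4")])
    def test_one_or_three_carriers_is_3to1(self, carriers):
        ev = self._events([(s, "chr1", 300, "A", "G") for s in carriers])
        assert list(ev["segregation"]) == ["3:1"]

    def test_all_four_carriers_rejected(self):
        ev = self._events([(s, "chr1", 300, "A", "G") for s in SPORES])
        assert list(ev["status"]) == ["rejected"]

    def test_uncovered_noncarrier_makes_event_unresolvable(self):
        ascus = make_ascus([
            ("spore_1", "chr1", 300, "A", "G"),
            ("spore_2", "chr1", 300, "A", "G"),
        ])
        ascus.depth["spore_4"]["chr1"][:] = 1
        candidates = filter_variant_calls(ascus)
        ev = classify_segregation(candidates, ascus)
        assert list(ev["status"]) == ["unresolvable"]

    def test_classification_invariant_to_spore_relabelling(self):
        rows = [
            ("spore_1", "chr1", 300, "A", "G"),
            ("spore_2", "chr1", 300, "A", "G"),
            ("spore_3", "chr1", 900, "C", "T"),
        ]
        ev1 = self._events(rows)
        perm = dict(zip(SPORES, ("spore_3", "spore_4", "spore_1", "spore_2")))
        ev2 = self._events([(perm[s], c, p, r, a) for s, c, p, r, a in rows])
        assert list(ev1["segregation"]) == list(ev2["segregation"])
        assert list(ev1["n_carriers"]) == list(ev2["n_carriers"])


class TestParentOrigin:
    def test_origin_recovered_on_simulated_cross(self, genome, config):
        truth = simulate_tetrad(genome, config, tetrad_id=9)
        ascus = simulate_depth_and_calls(truth, config)
        events = call_mutations(ascus, genome).events
        merged = events.merge(
            truth.events.assign(pos=truth.events["pos"] + 1),
            on=["contig", "pos", "ref", "alt"],
        )
        assigned = merged[merged["parent_of_origin"] != "unassigned"]
        premeiotic = assigned[assigned["parent"].isin(PARENTS)]
        assert len(premeiotic) > 0
        expected = premeiotic["parent"].map(
            {"parent_A": "A", "parent_a": "a"}
        )
        assert (premeiotic["parent_of_origin"] == expected).all()

    def test_isogenic_cross_gives_unassigned(self, genome):
        cfg = small_config(parental_snp_rate=0.0)
        truth = simulate_tetrad(genome, cfg, tetrad_id=10)
        ascus = simulate_depth_and_calls(truth, cfg)
        events = call_mutations(ascus, genome).events
        assert (events["parent_of_origin"] == "unassigned").all()

    def test_no_snp_within_window_gives_unassigned(self):
        ascus = make_ascus([
            ("parent_a", "chr1", 9000, "A", "G"),
            ("spore_1", "chr1", 100, "C", "T"),
            ("spore_2", "chr1", 100, "C", "T"),
        ])
        candidates = filter_variant_calls(ascus)
        events = classify_segregation(candidates, ascus)
        out = assign_parent_origin(events, ascus, window_bp=1000)
        assert list(out["parent_of_origin"]) == ["unassigned"]


class TestExactRecovery:
    def test_noise_off_precision_is_one_and_recall_high(self, genome, config):
        truth = simulate_tetrad(genome, config, tetrad_id=11)
        ascus = simulate_depth_and_calls(truth, config)
        events = call_mutations(ascus, genome).events
        ok = events[events["status"] == "ok"]
        truth_keys = set(zip(truth.events["contig"], truth.events["pos"] + 1,
                             truth.events["alt"]))
        called_keys = set(zip(ok["contig"], ok["pos"], ok["alt"]))
        assert called_keys <= truth_keys  # precision 1.0
        assert len(called_keys) >= 0.95 * len(truth_keys)

    def test_injected_noise_is_filtered_out(self, config):
        cfg = small_config(noise_het_per_dup_kb=0.5, noise_lowqual_per_genome=20)
        from ripmut.simulate import simulate_genome
        g = simulate_genome(cfg)
        truth = simulate_tetrad(g, cfg, tetrad_id=12)
        ascus = simulate_depth_and_calls(truth, cfg)
        events = call_mutations(ascus, g).events
        ok = events[events["status"] == "ok"]
        truth_keys = set(zip(truth.events["contig"], truth.events["pos"] + 1,
                             truth.events["alt"]))
        called_keys = set(zip(ok["contig"], ok["pos"], ok["alt"]))
        assert called_keys <= truth_keys


class TestDuplicationScreen:
    def _windows(self, spore_ratio_map, contig="chr1", n_windows=10):
        rows = []
        for sample in PARENTS + SPORES:
            for i in range(n_windows):
                depth = 40.0
                if sample in spore_ratio_map and i in spore_ratio_map[sample]:
                    depth *= spore_ratio_map[sample][i]
                rows.append((sample, contig, i * 1000, (i + 1) * 1000, depth))
        return pd.DataFrame(
            rows, columns=["sample_id", "contig", "start", "end", "depth"]
        )

    def test_uniform_depth_gives_no_candidates(self):
        out = screen_spontaneous_duplications(self._windows({}))
        assert len(out) == 0

    def test_2x_in_two_spores_reported(self):
        win = self._windows({
            "spore_1": {3: 2.0, 4: 2.0}, "spore_2": {3: 2.0, 4: 2.0},
        })
        out = screen_spontaneous_duplications(win)
        assert len(out) == 1
        r = out.iloc[0]
        assert (r["start"], r["end"]) == (3000, 5000)
        assert set(r["carrier_spores"]) == {"spore_1", "spore_2"}

    def test_parental_2x_window_excluded(self):
        win = self._windows({
            "spore_1": {3: 2.0}, "spore_2": {3: 2.0}, "parent_A": {3: 2.0},
        })
        out = screen_spontaneous_duplications(win)
        assert len(out) == 0
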