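import itertools

import numpy as np
import pandas as pd
import pytest

from snppanel.genotype import MISSING
from snppanel.intervals import FeatureSet, Gene, read_gff3_genes
from snppanel.panel import (
    CandidateSite,
    GenomicWindow,
    assign_priorities,
    build_panel,
    classify_site_region,
    detection_rate,
    make_windows,
    panel_report,
    qc_compare_groups,
    sample_call_rates,
    sd2_spacing,
    select_window_sites,
)


def cand(pos, category="common", chrom="1", maf=0.3, priority=None):
    from snppanel.panel import CATEGORY_PRIORITY

    return CandidateSite(chrom, pos, category,
                         priority if priority is not None else CATEGORY_PRIORITY[category],
                         maf)


class TestAssignPriorities:
    def test_category_tier_mapping(self):
        df = pd.DataFrame(
            {
                "chrom": "1",
                "pos": [100, 200, 300, 400],
                "category": ["breed_specific", "trait_related", "common", "wgs_polymorphic"],
                "maf": [0.1, 0.1, 0.1, 0.3],
            }
        )
        sites, rejected = assign_priorities(df)
        tiers = {s.category: s.priority for s in sites}
        assert tiers == {"breed_specific": 1, "trait_related": 1,
                         "common": 2, "wgs_polymorphic": 3}
        assert rejected == 0

    def test_duplicate_site_keeps_highest_priority(self):
        df = pd.DataFrame(
            {
                "chrom": ["1", "1"],
                "pos": [500, 500],
                "category": ["common", "trait_related"],
            }
        )
        sites, _ = assign_priorities(df)
        assert len(sites) == 1
        assert sites[0].priority == 1

    def test_wgs_polymorphic_maf_gate(self):
        df = pd.DataFrame(
            {
                "chrom": "1",
                "pos": [100, 200],
                "category": "wgs_polymorphic",
                "maf": [0.15, 0.25],
            }
        )
        sites, rejected = assign_priorities(df)
        assert len(sites) == 1 and sites[0].pos == 200
        assert rejected == 1

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError, match="category"):
            assign_priorities(pd.DataFrame({"chrom": ["1"], "pos": [1], "category": ["bogus"]}))


class TestMakeWindows:
    @pytest.mark.parametrize(
        "length,expected_n,last_width",
        [(150_000, 3, 50_000), (120_000, 3, 20_000), (49_999, 1, 49_999)],
    )
    def test_tiling(self, length, expected_n, last_width):
        wins = make_windows({"1": length})
        assert len(wins) == expected_n
        assert wins[-1].end - wins[-1].start == last_width
        # disjoint cover of [0, length)
        assert wins[0].start == 0 and wins[-1].end == length
        for a, b in zip(wins, wins[1:]):
            assert a.end == b.start

    def test_bad_width(self):
        with pytest.raises(ValueError):
            make_windows({"1": 1000}, width=0)


class TestSd2Spacing:
    @pytest.mark.parametrize(
        "args,expected",
        [((0, 100, 25, 75), 1562.5), ((0, 50_000, 10_000, 40_000), 425_000_000.0)],
    )
    def test_direct_evaluation(self, args, expected):
        S, E, Ni, Nj = args
        assert sd2_spacing(S, E, Ni, Nj) == pytest.approx(expected)

    def test_equals_population_variance(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            S, E = 0, int(rng.integers(100, 100000))
            ni, nj = sorted(rng.integers(1, E, size=2))
            if ni == nj:
                continue
            assert sd2_spacing(S, E, ni, nj) == pytest.approx(
                np.var([S, ni, nj, E]), rel=1e-12
            )

    def test_central_pair_minimises(self):
        # the variance of {S,Ni,Nj,E} shrinks as Ni,Nj approach the centre
        vals = [sd2_spacing(0, 100, 50 - e, 50 + e) for e in (40, 20, 10, 1)]
        assert vals == sorted(vals, reverse=True)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sd2_spacing(0, 100, 30, 30)
        with pytest.raises(ValueError):
            sd2_spacing(0, 100, -5, 30)


class TestSelectWindowSites:
    win = GenomicWindow("1", 0, 50_000)

    def test_single_candidate_kept(self):
        sel, audit = select_window_sites(self.win, [cand(30_000)])
        assert [c.pos for c in sel] == [30_000]
        assert audit.rule == "kept_single"

    def test_sd2_pair_with_tie_leftmost(self):
        sel, audit = select_window_sites(
            self.win, [cand(10_000), cand(25_000), cand(40_000)]
        )
        assert [c.pos for c in sel] == [10_000, 25_000]
        assert audit.rule == "sd2_pair"
        assert audit.sd2 == pytest.approx(354_687_500.0)

    def test_tie_break_prefers_higher_priority_pair(self):
        # same geometry both sides; priorities differ
        cands = [cand(10_000, "common"), cand(25_000, "common"),
                 cand(40_000, "trait_related")]
        sel, _ = select_window_sites(self.win, cands)
        assert [c.pos for c in sel] == [25_000, 40_000]  # pair sum 2+1 beats 2+2

    def test_fill_prefers_priority_then_maf(self):
        pool = [cand(10_000, "wgs_polymorphic", maf=0.25),
                cand(20_000, "wgs_polymorphic", maf=0.45)]
        sel, audit = select_window_sites(self.win, [], pool)
        assert audit.rule == "filled"
        assert sel[0].maf == 0.45

    def test_empty_everything(self):
        sel, audit = select_window_sites(self.win, [], [])
        assert sel == [] and audit.rule == "empty"

    def test_matches_exhaustive_minimisation(self):
        """Oracle: pair choice equals brute-force SD² minimisation."""
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(2, 21))
            positions = np.sort(rng.choice(np.arange(1, 50_001), size=n, replace=False))
            cands = [cand(int(p)) for p in positions]
            sel, audit = select_window_sites(self.win, cands)
            best = min(
                sd2_spacing(0, 50_000, a, b)
                for a, b in itertools.combinations(positions.tolist(), 2)
            )
            assert audit.sd2 == pytest.approx(best)
            assert sd2_spacing(0, 50_000, sel[0].pos, sel[1].pos) == pytest.approx(best)


class TestBuildPanel:
    def test_one_candidate_per_window_all_kept(self):
        lengths = {"1": 5_000_000}  # 100 windows
        cands = [cand(i * 50_000 + 25_000) for i in range(100)]
        panel = build_panel(None, cands, lengths)
        assert panel.total == 100
        assert all(a.rule == "kept_single" for a in panel.audit)

    def test_disjoint_category_sets_conserved(self):
        # a,b,c,d sites placed <= 2 per window: all retained
        sizes = {"breed_specific": 7, "trait_related": 11, "common": 13, "wgs_polymorphic": 9}
        labels = [catg for catg, n in sizes.items() for _ in range(n)]
        cands = [
            cand((i // 2) * 50_000 + 10_000 + (i % 2) * 20_000, catg)
            for i, catg in enumerate(labels)
        ]
        lengths = {"1": 50_000 * (len(labels) // 2 + 1)}
        panel = build_panel(None, cands, lengths)
        assert panel.total == sum(sizes.values())
        counts = panel.category_counts()
        assert counts == sizes

    def test_two_per_window_cap(self):
        cands = [cand(p) for p in range(1_000, 49_000, 1_000)]
        panel = build_panel(None, cands, {"1": 50_000})
        assert panel.total == 2

    def test_cap_over_randomised_fixtures(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            n = int(rng.integers(1, 200))
            pos = np.sort(rng.choice(np.arange(1, 500_001), size=n, replace=False))
            panel = build_panel(None, [cand(int(p)) for p in pos], {"1": 500_000})
            per_window = {}
            for c in panel.selected:
                per_window[(c.pos - 1) // 50_000] = per_window.get((c.pos - 1) // 50_000, 0) + 1
            assert max(per_window.values(), default=0) <= 2
            # conservation: every selected site came from the candidate set
            assert {c.pos for c in panel.selected} <= set(pos.tolist())
            assert len(panel.selected) == len({c.pos for c in panel.selected})

    def test_unknown_chromosome_named_in_error(self):
        with pytest.raises(ValueError, match="chr99"):
            build_panel(None, [cand(100, chrom="chr99")], {"1": 100_000})

    def test_deterministic_output(self):
        rng = np.random.default_rng(5)
        pos = np.sort(rng.choice(np.arange(1, 200_001), size=40, replace=False))
        cands = [cand(int(p)) for p in pos]
        t1 = build_panel(None, cands, {"1": 200_000}).panel_frame()
        t2 = build_panel(None, list(cands), {"1": 200_000}).panel_frame()
        assert t1.to_csv() == t2.to_csv()

    def test_supplement_fill_from_matrix(self, gm_factory):
        # no candidates anywhere; one QC-passing polymorphic site available
        codes = np.array([0, 1, 2, 1, 0, 1, 2, 1, 0, 1]).reshape(10, 1)
        gm = gm_factory(codes, positions=[25_000])
        panel = build_panel(gm, [], {"1": 50_000})
        assert panel.total == 1
        assert panel.audit[0].rule == "filled"

    def test_cap_exempt_priority1_keeps_all(self):
        cands = [cand(p, "trait_related") for p in (5_000, 10_000, 15_000, 20_000)]
        literal = build_panel(None, cands, {"1": 50_000})
        exempt = build_panel(None, cands, {"1": 50_000}, cap_exempt_priority1=True)
        assert literal.total == 2
        assert exempt.total == 4


class TestDetectionRate:
    def test_percentage(self):
        assert detection_rate(40_477, 42_686) == pytest.approx(94.83, abs=0.005)

    def test_bad_denominator(self):
        with pytest.raises(ValueError):
            detection_rate(1, 0)


GFF = """\
##gff-version 3
1\tsrc\tgene\t10000\t20000\t.\t+\t.\tID=geneA
1\tsrc\tmRNA\t10000\t20000\t.\t+\t.\tID=mrnaA;Parent=geneA
1\tsrc\texon\t10000\t11000\t.\t+\t.\tID=exA1;Parent=mrnaA
1\tsrc\texon\t19000\t20000\t.\t+\t.\tID=exA2;Parent=mrnaA
1\tsrc\tgene\t50000\t60000\t.\t-\t.\tID=geneB
1\tsrc\texon\t50000\t60000\t.\t-\t.\tID=exB1;Parent=geneB
"""


class TestClassifyRegion:
    @pytest.fixture
    def annotation(self, tmp_path):
        path = tmp_path / "genes.gff3"
        path.write_text(GFF)
        return read_gff3_genes(path)

    @pytest.mark.parametrize(
        "pos,expected",
        [
            (10_500, "exonic"),
            (15_000, "intronic"),
            (8_000, "upstream"),      # 2 kb before + strand gene start
            (22_000, "downstream"),   # 2 kb past + strand gene end
            (62_000, "upstream"),     # past a - strand gene's right end
            (48_000, "downstream"),
            (1_000_000, "intergenic"),
        ],
    )
    def test_precedence_and_strand(self, annotation, pos, expected):
        assert classify_site_region("1", pos, annotation) == expected

    def test_absent_chromosome_is_intergenic(self, annotation):
        assert classify_site_region("99", 1000, annotation) == "intergenic"

    def test_report_region_counts(self, annotation):
        cands = [cand(10_500), cand(15_000), cand(1_000_000)]
        from snppanel.panel import PanelDesign

        panel = PanelDesign(selected=cands, audit=[])
        rep = panel_report(panel, annotation=annotation)
        assert rep["region_counts"] == {"exonic": 1, "intronic": 1, "intergenic": 1}
        assert sum(rep["per_chrom"].values()) == 3

    def test_maf_histogram_single_bin(self):
        from snppanel.panel import PanelDesign

        panel = PanelDesign(selected=[cand(100, maf=0.25), cand(200, maf=0.25)], audit=[])
        rep = panel_report(panel)
        assert rep["maf_hist"]["[0.2,0.3)"] == 2
        assert sum(rep["maf_hist"].values()) == 2


class TestQcCompare:
    def test_identical_groups_p_one(self):
        values = np.array([0.99] * 10 + [0.99] * 10)
        groups = np.array(["a"] * 10 + ["b"] * 10)
        out = qc_compare_groups(values, groups)
        assert out.loc[0, "p_value"] == pytest.approx(1.0)

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(12)
        values = np.concatenate([
            rng.normal(0.99, 1e-4, 20), rng.normal(0.95, 1e-4, 20)
        ])
        groups = np.array(["f"] * 20 + ["m"] * 20)
        out = qc_compare_groups(values, groups)
        assert out.loc[0, "p_value"] < 1e-3
        assert bool(out.loc[0, "significant"])

    def test_three_groups_three_tests(self):
        values = np.arange(9, dtype=float)
        groups = np.array(["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        assert len(qc_compare_groups(values, groups)) == 3

    def test_small_group_excluded(self):
        values = np.arange(5, dtype=float)
        groups = np.array(["a", "a", "a", "a", "b"])
        assert len(qc_compare_groups(values, groups)) == 0

    def test_sample_call_rates(self, gm_factory):
        codes = np.array([[0, 1, MISSING, 2], [0, 0, 0, 0]])
        gm = gm_factory(codes)
        rates = sample_call_rates(gm)
        assert rates.loc[0, "missing_rate"] == pytest.approx(0.25)
        assert rates.loc[1, "call_rate"] == 1.0
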