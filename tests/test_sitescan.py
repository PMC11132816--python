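import pytest

from convscan.asr import joint_reconstructions
from convscan.phylo_io import AA_INDEX, ForegroundSpec, Msa, read_tree
from convscan.sitescan import (
    candidate_sites,
    classify_reconstruction,
    classify_site,
    degap,
    scan_sites,
)

from conftest import make_pattern


def states_of(tree, labels: dict[str, str]) -> dict[int, int]:
    """Full node-id -> state map from a {label: amino acid} dict.

    Internal nodes are addressed by their newick labels.
    """
    by_label = {}
    for n in tree.nodes:
        if n.label is None:
            raise ValueError("all nodes must be labeled in classifier fixtures")
        by_label[n.label] = n.id
    return {by_label[k]: AA_INDEX[v] for k, v in labels.items()}


class TestDegap:
    def test_gap_column_removed_and_mapped(self):
        msa = Msa((("A", "MK-C"), ("B", "MKAC")))
        out, cmap = degap(msa, "A")
        assert out.sequence("A") == "MKC"
        assert cmap.alignment_columns == (1, 2, 4)
        assert cmap.alignment_column(3) == 4

    def test_ambiguity_column_removed(self):
        msa = Msa((("A", "MKXC"), ("B", "MKAC")))
        out, _ = degap(msa, "A")
        assert out.n_columns == 3

    def test_gap_free_is_identity(self):
        msa = Msa((("A", "MKC"), ("B", "MRC")))
        out, cmap = degap(msa, "A")
        assert out.records == msa.records
        assert cmap.alignment_columns == (1, 2, 3)
        assert cmap.reference_positions == (1, 2, 3)

    def test_reference_coordinates_skip_reference_gaps(self):
        # reference has a gap at column 2: retained col 4 is ref residue 3
        msa = Msa((("R", "M-KC"), ("B", "MAKC"), ("C", "MAKC")))
        out, cmap = degap(msa, "R")
        assert cmap.alignment_columns == (1, 3, 4)
        assert cmap.reference_positions == (1, 2, 3)

    def test_all_columns_removed_returns_none(self):
        msa = Msa((("A", "--"), ("B", "AA")))
        out, cmap = degap(msa, "A")
        assert out is None
        assert cmap.alignment_columns == ()


class TestCandidateSites:
    FG = ForegroundSpec(frozenset({"a", "b"}), frozenset({"c", "d"}), "a")

    def test_foreground_fixed_background_absent(self):
        msa = Msa((("a", "C"), ("b", "C"), ("c", "A"), ("d", "V")))
        assert candidate_sites(msa, self.FG) == [(1, "C")]

    def test_background_sharing_derived_state_disqualifies(self):
        msa = Msa((("a", "C"), ("b", "C"), ("c", "C"), ("d", "V")))
        assert candidate_sites(msa, self.FG) == []

    def test_foreground_disagreement_disqualifies(self):
        msa = Msa((("a", "C"), ("b", "S"), ("c", "A"), ("d", "V")))
        assert candidate_sites(msa, self.FG) == []

    def test_background_need_not_agree(self):
        msa = Msa((("a", "CC"), ("b", "CC"), ("c", "AA"), ("d", "AV")))
        assert candidate_sites(msa, self.FG) == [(1, "C"), (2, "C")]


# a fully labeled tree for classifier scenarios: three separate foreground
# tips, each with its own background sister
SCENARIO_NEWICK = (
    "((f1:0.1,x1:0.1)A:0.1,((f2:0.1,x2:0.1)B:0.1,(f3:0.1,x3:0.1)C:0.1)D:0.1)R;"
)


class TestClassifyReconstruction:
    def setup_method(self):
        self.tree = read_tree(SCENARIO_NEWICK)

    def test_convergent_scenario(self):
        # three independent origins of C: two from ancestral A, one from V
        fg = ForegroundSpec(frozenset({"f1", "f2", "f3"}),
                            frozenset({"x1", "x2", "x3"}), "f1")
        full = states_of(self.tree, {
            "f1": "C", "f2": "C", "f3": "C",
            "x1": "A", "x2": "A", "x3": "V",
            "A": "A", "B": "A", "C": "V", "D": "A", "R": "A",
        })
        assert classify_reconstruction(self.tree, full, fg, "C") == "convergent"

    def test_parallel_scenario(self):
        # two independent origins of C, both from ancestral A
        fg = ForegroundSpec(frozenset({"f1", "f2"}),
                            frozenset({"x1", "x2", "x3", "f3"}), "f1")
        full = states_of(self.tree, {
            "f1": "C", "f2": "C", "f3": "A",
            "x1": "A", "x2": "A", "x3": "A",
            "A": "A", "B": "A", "C": "A", "D": "A", "R": "A",
        })
        assert classify_reconstruction(self.tree, full, fg, "C") == "parallel"

    def test_lineage_specific_scenario(self):
        # derived V inherited from the foreground common ancestor D; the
        # background pair below C diverged away (V -> C) afterwards
        fg = ForegroundSpec(frozenset({"f2", "f3"}),
                            frozenset({"f1", "x1", "x2", "x3"}), "f2")
        full = states_of(self.tree, {
            "f1": "A", "x1": "A", "A": "A", "R": "A",
            "D": "V", "B": "V", "C": "V", "f2": "V", "f3": "V",
            "x2": "C", "x3": "C",
        })
        # x2 and x3 diverged away from V; single foreground run rooted at D
        assert classify_reconstruction(self.tree, full, fg, "V") == "lineage_specific"

    def test_root_run_is_lineage_specific(self):
        # derived state already at the tree root: inheritance criterion holds
        fg = ForegroundSpec(frozenset({"f1", "f2", "f3"}),
                            frozenset({"x1", "x2", "x3"}), "f1")
        full = states_of(self.tree, {
            "f1": "C", "f2": "C", "f3": "C",
            "x1": "A", "x2": "A", "x3": "V",
            "A": "C", "B": "C", "C": "C", "D": "C", "R": "C",
        })
        assert classify_reconstruction(self.tree, full, fg, "C") == "lineage_specific"

    def test_root_run_alongside_other_runs_is_other(self):
        fg = ForegroundSpec(frozenset({"f1", "f2"}),
                            frozenset({"x1", "x2", "x3", "f3"}), "f1")
        full = states_of(self.tree, {
            "f1": "C", "f2": "C", "f3": "A",
            "x1": "A", "x2": "A", "x3": "A",
            "A": "C", "R": "C",          # run contains root, holds f1
            "B": "A", "C": "A", "D": "A",  # f2 is its own run
        })
        assert classify_reconstruction(self.tree, full, fg, "C") == "other"

    def test_precondition_enforced(self):
        fg = ForegroundSpec(frozenset({"f1", "f2"}),
                            frozenset({"x1", "x2", "x3", "f3"}), "f1")
        full = states_of(self.tree, {
            "f1": "C", "f2": "A", "f3": "A",
            "x1": "A", "x2": "A", "x3": "A",
            "A": "A", "B": "A", "C": "A", "D": "A", "R": "A",
        })
        with pytest.raises(ValueError, match="precondition"):
            classify_reconstruction(self.tree, full, fg, "C")

    def test_invariant_to_child_order(self):
        # same topology written with rotated children: ids differ, class same
        tree2 = read_tree(
            "(((x3:0.1,f3:0.1)C:0.1,(x2:0.1,f2:0.1)B:0.1)D:0.1,(x1:0.1,f1:0.1)A:0.1)R;"
        )
        fg = ForegroundSpec(frozenset({"f1", "f2", "f3"}),
                            frozenset({"x1", "x2", "x3"}), "f1")
        labels = {
            "f1": "C", "f2": "C", "f3": "C",
            "x1": "A", "x2": "A", "x3": "V",
            "A": "A", "B": "A", "C": "V", "D": "A", "R": "A",
        }
        assert classify_reconstruction(self.tree, states_of(self.tree, labels), fg, "C") \
            == classify_reconstruction(tree2, states_of(tree2, labels), fg, "C")


class TestClassifySite:
    def test_mass_accounting_sums_to_one(self, poisson, planted_fixture):
        tree, fg, msa, truth = planted_fixture
        degapped, cmap = degap(msa, fg.reference)
        for site, d in candidate_sites(degapped, fg)[:5]:
            pat = make_pattern(tree, degapped.column(site))
            rs = joint_reconstructions(tree, poisson, pat)
            pc, pp, pl, pr, cat = classify_site(tree, rs, pat, fg, d)
            assert pc + pp + pl + pr == pytest.approx(1.0, abs=1e-9)
            assert pr >= 0

    def test_truncated_mass_goes_to_residual(self, poisson, planted_fixture):
        tree, fg, msa, truth = planted_fixture
        degapped, _ = degap(msa, fg.reference)
        site, d = candidate_sites(degapped, fg)[0]
        pat = make_pattern(tree, degapped.column(site))
        rs = joint_reconstructions(tree, poisson, pat, mass_target=1.0, k_max=3)
        pc, pp, pl, pr, _ = classify_site(tree, rs, pat, fg, d)
        assert pr >= 1.0 - rs.cumulative_mass - 1e-12

    def test_aggregation_beats_rank1(self, poisson, planted_fixture):
        # several distinct reconstructions implying the same category add up
        tree, fg, msa, truth = planted_fixture
        degapped, cmap = degap(msa, fg.reference)
        inv = {cmap.alignment_column(i): i for i, _ in
               enumerate(cmap.alignment_columns, start=1)}
        parallel_col = next(r.start for r in truth.of_kind("substitution")
                            if r.category == "parallel")
        site = inv[parallel_col]
        cands = dict(candidate_sites(degapped, fg))
        d = cands[site]
        pat = make_pattern(tree, degapped.column(site))
        rs = joint_reconstructions(tree, poisson, pat)
        pc, pp, pl, pr, cat = classify_site(tree, rs, pat, fg, d)
        assert cat == "parallel"
        assert pp > rs.reconstructions[0].posterior

    def test_agreement_with_full_enumeration(self, poisson6):
        # aggregating over the complete labeling enumeration equals
        # classify_site at mass_target=1 (small tree, 6-state alphabet)
        from convscan.asr import enumerate_reconstructions_bruteforce

        tree = read_tree("((f1:0.2,f2:0.3):0.25,(b1:0.4,b2:0.15):0.3);")
        fg = ForegroundSpec(frozenset({"f1", "f2"}), frozenset({"b1", "b2"}), "f1")
        pat = make_pattern(tree, {"f1": "C", "f2": "C", "b1": "A", "b2": "R"})
        d = "C"
        rs = joint_reconstructions(tree, poisson6, pat, mass_target=1.0, k_max=10**9)
        got = classify_site(tree, rs, pat, fg, d)

        tips = {tree.tip_ids[s]: i for s, i in pat.states.items()}
        totals = {"convergent": 0.0, "parallel": 0.0, "lineage_specific": 0.0}
        for rec in enumerate_reconstructions_bruteforce(tree, poisson6, pat):
            full = dict(tips)
            full.update(rec.assignment)
            c = classify_reconstruction(tree, full, fg, d)
            if c in totals:
                totals[c] += rec.posterior
        assert got[0] == pytest.approx(totals["convergent"], abs=1e-9)
        assert got[1] == pytest.approx(totals["parallel"], abs=1e-9)
        assert got[2] == pytest.approx(totals["lineage_specific"], abs=1e-9)


class TestScanSites:
    def test_background_contaminated_sites_never_called(self, poisson):
        # a background species sharing the foreground state blocks the site
        tree = read_tree("((f1:0.1,f2:0.1):0.3,(b1:0.1,b2:0.1):0.3);")
        fg = ForegroundSpec(frozenset({"f1", "f2"}), frozenset({"b1", "b2"}), "f1")
        msa = Msa((("f1", "CC"), ("f2", "CC"), ("b1", "CA"), ("b2", "AA")))
        calls = scan_sites(msa, tree, poisson, fg, "g")
        assert [c.degapped_site for c in calls] == [2]

    def test_call_fields_consistent(self, poisson, planted_fixture, planted_scan):
        tree, fg, msa, truth = planted_fixture
        site_calls, _ = planted_scan
        tie_order = ("lineage_specific", "parallel", "convergent")
        for c in site_calls:
            assert c.p_convergent + c.p_parallel + c.p_lineage + c.p_residual \
                == pytest.approx(1.0, abs=1e-9)
            posts = dict(zip(tie_order, (c.p_lineage, c.p_parallel, c.p_convergent)))
            expected = max(tie_order,
                           key=lambda k: (posts[k], -tie_order.index(k)))
            assert c.category == expected
            assert c.flagged == (
                max(c.p_convergent, c.p_parallel, c.p_lineage) > 0.95
                and c.quality_label == "well aligned fragments"
            )
            # site_pattern holds the column states in alignment record order
            assert len(c.site_pattern) == len(msa.records)
            assert "-" not in c.site_pattern
            col = msa.column(c.alignment_column)
            assert c.site_pattern == "".join(col[s] for s, _ in msa.records)
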