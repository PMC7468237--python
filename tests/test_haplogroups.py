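"""Motif classification, sub-branch discovery, origin proportions."""

import itertools

import numpy as np
import pytest

from uniparent.errors import DegenerateInputError
from uniparent.haplogroups import (MotifNode, MotifTree, classify,
                                   classify_alignment, discover_subbranches,
                                   origin_proportions, packaged_tree,
                                   parse_variants)
from uniparent.sequence_io import HaploidAlignment

from conftest import make_alignment, make_table


def sequence_with(tree: MotifTree, variants, absent=()) -> tuple[np.ndarray, np.ndarray]:
    """(positions, alleles) carrying exactly the given derived variants.

    The background allele at every motif position is chosen to differ from
    every derived allele defined there, so nothing matches by accident.
    """
    all_pos = sorted({
        p for node in tree.nodes.values()
        for p, _ in node.required + node.forbidden
    })
    derived_at = {}
    for node in tree.nodes.values():
        for p, a in node.required + node.forbidden:
            derived_at.setdefault(p, set()).add(a)
    row = []
    want = dict(variants)
    for p in all_pos:
        if p in want:
            row.append(want[p])
        else:
            row.append(next(a for a in "GATC" if a not in derived_at[p]))
    return np.asarray(all_pos), np.array(row, dtype="U1")


def motif_union(tree: MotifTree, name: str) -> dict[int, str]:
    return dict(tree.cumulative_required(name))


MT = packaged_tree("mtDNA")


class TestClassify:
    @pytest.mark.parametrize(
        "background, extra, expected",
        [
            ("M5a1b", {3954: "T", 9833: "C"}, "M5a1b1a"),
            ("M5a1b1a", {16298: "C"}, "M5a1b1a1"),
            ("M5a1b1a", {15902: "C"}, "M5a1b1a2"),
            ("H", {1271: "G", 3621: "C", 16223: "T"}, "H107"),
        ],
    )
    def test_named_sublineage_motifs(self, background, extra, expected):
        variants = motif_union(MT, background) | extra
        call = classify(sequence_with(MT, variants), MT, "s")
        assert call.haplogroup == expected

    def test_sister_clade_forbidden_variant(self):
        # carrying 16298C forces the M5a1b1a1 side even with 15902C present
        variants = motif_union(MT, "M5a1b1a") | {15902: "C", 16298: "C"}
        call = classify(sequence_with(MT, variants), MT, "s")
        assert call.haplogroup == "M5a1b1a1"

    def test_unmatched_sequence_calls_root_unassigned(self):
        call = classify(sequence_with(MT, {}), MT, "s")
        assert call.haplogroup == MT.root
        assert call.origin == "unassigned"

    def test_origin_labels_follow_tree(self):
        v = motif_union(MT, "M5a1b1a1")
        assert classify(sequence_with(MT, v), MT).origin == "South Asian"
        v = motif_union(MT, "H107")
        assert classify(sequence_with(MT, v), MT).origin == "European"

    def test_msy_published_subbranch_variant(self):
        Y = packaged_tree("MSY")
        v = motif_union(Y, "H1a1a4b2d3")
        call = classify(sequence_with(Y, v), Y)
        assert call.haplogroup == "H1a1a4b2d3"
        assert (26618569, "C") in call.matched

    def test_classification_is_monotone_in_depth(self):
        # adding a child-defining variant never yields a shallower call
        for name in ("M", "M5a1b", "M5a1b1a", "M5a1b1a1"):
            shallow = classify(sequence_with(MT, motif_union(MT, name)), MT)
            for child in MT.children[name]:
                deep = classify(sequence_with(MT, motif_union(MT, child)), MT)
                assert MT.depth(deep.haplogroup) >= MT.depth(shallow.haplogroup)


def brute_force_branches(aln: HaploidAlignment, calls, min_carriers):
    """Independent enumeration of (carrier set -> exclusive variants)."""
    call_of = {c.sample_id: c.haplogroup for c in calls}
    found = {}
    for j, pos in enumerate(aln.positions):
        for allele in "ACGT":
            carriers = frozenset(
                aln.sample_ids[i] for i in range(aln.n_samples)
                if aln.matrix[i, j] == allele
            )
            if not (min_carriers <= len(carriers) < aln.n_samples):
                continue
            hgs = {call_of[s] for s in carriers}
            if len(hgs) != 1:
                continue
            found.setdefault((hgs.pop(), carriers), set()).add((int(pos), allele))
    return found


class TestDiscoverSubbranches:
    def _toy_tree(self):
        return MotifTree([
            MotifNode("root", None, ()),
            MotifNode("X", "root", parse_variants("1A"), origin="South Asian"),
            MotifNode("Y", "root", parse_variants("1C"), origin="European"),
        ])

    def test_exclusive_shared_variants_form_one_branch(self):
        #      pos: 123456
        aln = make_alignment({
            "s1": "ATTGGC",
            "s2": "ATTGGC",
            "s3": "ATTGGC",
            "s4": "AGGGGC",
            "s5": "CGGGGC",
        })
        tree = self._toy_tree()
        calls = classify_alignment(aln, tree)
        branches = discover_subbranches(aln, calls, min_carriers=3)
        shared = [b for b in branches if set(b.carriers) == {"s1", "s2", "s3"}]
        assert len(shared) == 1
        assert shared[0].variants == ((2, "T"), (3, "T"))

    def test_identical_samples_yield_no_branches(self):
        aln = make_alignment({f"s{i}": "AAAA" for i in range(4)})
        tree = MotifTree([MotifNode("root", None, ())])
        calls = classify_alignment(aln, tree)
        assert discover_subbranches(aln, calls) == []

    def test_nested_branches_report_parent_link(self, rng):
        # a 6-sample clade with 6 exclusive SNPs nested inside a 13-sample
        # branch with 4 exclusive SNPs, inside one haplogroup of 16 samples
        n, L = 20, 60
        mat = np.full((n, L), "A", dtype="U1")
        mat[16:, 0] = "C"          # the other haplogroup
        hap_members = list(range(16))
        outer = hap_members[:13]
        inner = outer[:6]
        for k, col in enumerate(range(10, 14)):    # 4 outer SNPs
            mat[outer, col] = "G"
        for k, col in enumerate(range(20, 26)):    # 6 inner SNPs
            mat[inner, col] = "T"
        ids = [f"s{i}" for i in range(n)]
        aln = HaploidAlignment(ids, np.arange(1, L + 1), mat)
        tree = self._toy_tree()
        calls = classify_alignment(aln, tree)
        branches = discover_subbranches(aln, calls, min_carriers=2)

        outer_b = [b for b in branches if len(b.carriers) == 13]
        inner_b = [b for b in branches if len(b.carriers) == 6]
        assert len(outer_b) == 1 and len(inner_b) == 1
        assert len(outer_b[0].variants) == 4
        assert len(inner_b[0].variants) == 6
        assert branches[inner_b[0].parent] == outer_b[0]

    def test_matches_brute_force_enumeration(self, rng):
        from conftest import random_alignment

        aln = random_alignment(rng, 12, 80, alphabet="AC")
        tree = self._toy_tree()
        calls = classify_alignment(aln, tree)
        got = {
            (b.haplogroup, frozenset(b.carriers)): set(b.variants)
            for b in discover_subbranches(aln, calls, min_carriers=2)
        }
        expected = brute_force_branches(aln, calls, min_carriers=2)
        assert got == {k: set(v) for k, v in expected.items()}

    def test_reference_panel_vetoes_shared_variants(self):
        aln = make_alignment({"s1": "ATG", "s2": "ATG", "s3": "AAG"})
        panel = make_alignment({"p1": "ATG"})
        tree = MotifTree([MotifNode("root", None, ())])
        calls = classify_alignment(aln, tree)
        with_panel = discover_subbranches(aln, calls, 2, reference_panel=panel)
        without = discover_subbranches(aln, calls, 2)
        assert without and not with_panel


class TestOriginProportions:
    def test_printed_style_fraction(self):
        # 19 of 76 mtDNA lineages of founder origin -> 25.0%
        origins = ["South Asian"] * 19 + ["European"] * 57
        aln_ids = [f"s{i}" for i in range(76)]
        calls = [
            classify(sequence_with(MT, motif_union(
                MT, "M5a1b" if o == "South Asian" else "H")), MT, sid)
            for sid, o in zip(aln_ids, origins)
        ]
        table = make_table(aln_ids, ["X:Y"] * 76, marker="mtDNA")
        out = origin_proportions(calls, table)
        sa = out[(out["marker"] == "mtDNA") & (out["origin"] == "South Asian")]
        assert sa["count"].item() == 19
        assert sa["fraction"].item() == pytest.approx(0.25)

    def test_single_origin_fraction_one(self):
        calls = [classify(sequence_with(MT, motif_union(MT, "H")), MT, f"s{i}")
                 for i in range(5)]
        out = origin_proportions(calls)
        assert out["fraction"].tolist() == [1.0]

    def test_fractions_sum_to_one_per_marker(self, rng):
        names = ["M5a1b", "H", "U", "mt-MRCA"]
        calls = [
            classify(sequence_with(MT, motif_union(MT, rng.choice(names))), MT, f"s{i}")
            for i in range(30)
        ]
        out = origin_proportions(calls)
        assert out.groupby("marker")["fraction"].sum().to_numpy() == pytest.approx(1.0)

    def test_empty_input_rejected(self):
        with pytest.raises(DegenerateInputError):
            origin_proportions([])
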