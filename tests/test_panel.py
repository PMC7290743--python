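"""Diagnostic-locus discovery, flank checks, submission sequences and
decision-tree construction."""

import numpy as np
import pandas as pd
import pytest

from kaspdiag import (
    GenotypeMatrix,
    build_decision_tree,
    check_flanks,
    extract_submission_sequence,
    find_diagnostic_loci,
    profile_locus,
    simulate_genotype_matrix,
)
from kaspdiag.core import InvalidSpecError, Leaf
from kaspdiag.panel import read_matrix_vcf
from kaspdiag.simulate import write_matrix_vcf

from conftest import SIX_GROUPS, oracle_diagnostic_loci, random_matrix


class TestProfileLocus:
    def test_fixed_difference_profile(self, cohort_matrix):
        matrix, truth = cohort_matrix
        prof = profile_locus(matrix, truth.sample_to_group, "BTS99-319", SIX_GROUPS)
        assert prof.groups["SSA-ECA"].allele == "A"
        assert prof.groups["SSA-WA"].allele == "A"
        for g in ("SSA-ESA", "SSA-CA", "SSA2", "SSA4"):
            assert prof.groups[g].allele == "G"
        assert prof.all_fixed

    def test_single_het_breaks_fixation(self, cohort_matrix):
        matrix, truth = cohort_matrix
        calls = matrix.calls.copy()
        calls.at["SSAECA_001", "BTS99-319"] = "A/G"
        perturbed = GenotypeMatrix(calls=calls, loci=matrix.loci)
        prof = profile_locus(perturbed, truth.sample_to_group, "BTS99-319", SIX_GROUPS)
        assert prof.groups["SSA-ECA"].status == "mixed"

    def test_empty_group_flagged_not_fixed(self, cohort_matrix):
        matrix, truth = cohort_matrix
        prof = profile_locus(
            matrix, truth.sample_to_group, "BTS99-319", SIX_GROUPS + ["ghost"]
        )
        assert prof.groups["ghost"].status == "no_samples"
        assert not prof.all_fixed

    def test_low_call_rate_breaks_fixation(self):
        calls = pd.DataFrame(
            {"L0": ["A/A", "./.", "./.", "G/G"]},
            index=pd.Index([f"s{i}" for i in range(4)], name="sample"),
        )
        loci = pd.DataFrame(
            [{"locus": "L0", "contig": "c", "pos": 1, "ref": "A", "alt": "G"}]
        ).set_index("locus")
        matrix = GenotypeMatrix(calls, loci)
        labels = {"s0": "a", "s1": "a", "s2": "a", "s3": "b"}
        prof = profile_locus(matrix, labels, "L0", ["a", "b"], min_call_rate=0.8)
        assert prof.groups["a"].status == "mixed"  # call rate 1/3 < 0.8
        assert prof.groups["b"].status == "fixed"

    def test_profiles_match_direct_tally(self):
        matrix, labels = random_matrix(seed=123, n_samples=15, n_loci=40)
        scope = sorted(set(labels.values()))
        for locus in matrix.locus_ids:
            prof = profile_locus(matrix, labels, locus, scope)
            for g in scope:
                members = [s for s in matrix.sample_ids if labels[s] == g]
                calls = [matrix.calls.at[s, locus] for s in members]
                present = [c for c in calls if c != "./."]
                assert prof.groups[g].call_rate == pytest.approx(len(present) / len(calls))


class TestFindDiagnosticLoci:
    def test_full_scope_recovers_table1_full_scope_markers(self, cohort_matrix):
        matrix, truth = cohort_matrix
        found = find_diagnostic_loci(matrix, truth.sample_to_group, SIX_GROUPS)
        ids = {m.marker_id for m in found}
        assert ids == {"BTS99-319", "BTS141", "BTS55-473", "BTS613"}
        by_id = {m.marker_id: m for m in found}
        assert by_id["BTS99-319"].partition["XX"] == frozenset({"SSA-ECA", "SSA-WA"})
        assert by_id["BTS141"].partition["XX"] == frozenset({"SSA2", "SSA4"})
        assert by_id["BTS55-473"].partition["XX"] == frozenset({"SSA2"})
        assert by_id["BTS613"].partition["XX"] == frozenset({"SSA-ESA", "SSA-CA"})

    def test_scope_restricted_marker_found_only_in_scope(self, cohort_matrix):
        matrix, truth = cohort_matrix
        sub = find_diagnostic_loci(matrix, truth.sample_to_group, ["SSA-ECA", "SSA-WA"])
        assert {m.marker_id for m in sub} == {"BTS22-762"}
        full = find_diagnostic_loci(matrix, truth.sample_to_group, SIX_GROUPS)
        assert "BTS22-762" not in {m.marker_id for m in full}

    def test_matches_bruteforce_oracle_on_random_matrices(self):
        for seed in range(25):
            matrix, labels = random_matrix(seed, n_samples=12, n_loci=30)
            scope = sorted(set(labels.values()))
            found = {m.marker_id for m in find_diagnostic_loci(matrix, labels, scope)}
            assert found == oracle_diagnostic_loci(matrix, labels, scope), f"seed {seed}"

    def test_sorted_by_contig_position(self, cohort_matrix):
        matrix, truth = cohort_matrix
        found = find_diagnostic_loci(matrix, truth.sample_to_group, SIX_GROUPS)
        keys = [(m.contig, m.pos) for m in found]
        assert keys == sorted(keys)

    def test_scope_needs_two_groups(self, cohort_matrix):
        matrix, truth = cohort_matrix
        with pytest.raises(InvalidSpecError):
            find_diagnostic_loci(matrix, truth.sample_to_group, ["SSA-ECA"])

    def test_recovery_robust_to_missing_data(self, table1_spec):
        from conftest import COHORT_SIZES

        matrix, truth = simulate_genotype_matrix(
            COHORT_SIZES, 50, table1_spec, missing_rate=0.05, seed=11
        )
        found = {m.marker_id for m in find_diagnostic_loci(matrix, truth.sample_to_group, SIX_GROUPS)}
        assert found == {"BTS99-319", "BTS141", "BTS55-473", "BTS613"}


class TestFlanks:
    LOCI = pd.DataFrame(
        [{"locus": "M", "contig": "c1", "pos": 51, "ref": "A", "alt": "G"}]
    ).set_index("locus")

    def _marker(self, pos, contig="c1"):
        from kaspdiag.core import DiagnosticMarker

        return DiagnosticMarker(
            marker_id="M",
            contig=contig,
            pos=pos,
            allele_x="A",
            allele_y="G",
            scope=frozenset({"a", "b"}),
            partition={"XX": frozenset({"a"}), "YY": frozenset({"b"})},
        )

    def test_boundary_exactly_satisfied(self):
        ref = {"c1": "T" * 50 + "A" + "T" * 50}  # 101 bp, SNP at 51
        ok, reasons = check_flanks(ref, self._marker(51), self.LOCI, flank=50)
        assert ok and reasons == []

    def test_short_left_flank(self):
        ref = {"c1": "T" * 29 + "A" + "T" * 100}
        ok, reasons = check_flanks(ref, self._marker(30), self.LOCI.iloc[:0], flank=50)
        assert not ok
        assert "left flank short" in reasons

    def test_neighbouring_variant_disqualifies(self):
        ref = {"c1": "T" * 200}
        loci = pd.DataFrame(
            [
                {"locus": "M", "contig": "c1", "pos": 100, "ref": "A", "alt": "G"},
                {"locus": "N", "contig": "c1", "pos": 120, "ref": "C", "alt": "T"},
            ]
        ).set_index("locus")
        ok, reasons = check_flanks(ref, self._marker(100), loci, flank=50)
        assert not ok and any("N" in r for r in reasons)

    def test_matches_interval_oracle_on_random_layouts(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            length = int(rng.integers(60, 400))
            pos = int(rng.integers(1, length + 1))
            flank = int(rng.integers(5, 80))
            others = sorted(set(int(p) for p in rng.integers(1, length + 1, size=3)) - {pos})
            ref = {"c1": "T" * (pos - 1) + "A" + "T" * (length - pos)}
            loci = pd.DataFrame(
                [{"locus": f"o{k}", "contig": "c1", "pos": p, "ref": "C", "alt": "T"}
                 for k, p in enumerate(others)]
            ).set_index("locus") if others else self.LOCI.iloc[:0]
            ok, _ = check_flanks(ref, self._marker(pos), loci, flank=flank)
            expected = (
                pos - 1 >= flank
                and length - pos >= flank
                and all(abs(p - pos) > flank for p in others)
            )
            assert ok == expected

    def test_position_outside_contig_errors(self):
        with pytest.raises(ValueError):
            check_flanks({"c1": "ACGT"}, self._marker(10), self.LOCI.iloc[:0], 2)


class TestSubmissionSequence:
    def _marker(self, pos):
        from kaspdiag.core import DiagnosticMarker

        return DiagnosticMarker(
            marker_id="M", contig="c1", pos=pos, allele_x="A", allele_y="G",
            scope=frozenset({"a", "b"}),
            partition={"XX": frozenset({"a"}), "YY": frozenset({"b"})},
        )

    def test_centred_window_with_bracket(self):
        ref = {"c1": "T" * 50 + "A" + "C" * 50}
        seq = extract_submission_sequence(ref, self._marker(51), window=101)
        assert seq == "T" * 50 + "[A/G]" + "C" * 50
        assert len(seq) == 101 + 4

    def test_window_200_length(self):
        ref = {"c1": "T" * 500 + "A" + "T" * 500}
        seq = extract_submission_sequence(ref, self._marker(501), window=200)
        assert len(seq) == 204  # 199 context bases + 5-char bracket

    def test_bracket_order_fixed_by_marker_not_reference(self):
        # Reference carries allele Y at the site; bracket stays [X/Y].
        ref = {"c1": "T" * 50 + "G" + "T" * 50}
        seq = extract_submission_sequence(ref, self._marker(51), window=101)
        assert "[A/G]" in seq

    def test_reference_allele_mismatch_errors(self):
        ref = {"c1": "T" * 50 + "C" + "T" * 50}
        with pytest.raises(ValueError, match="matches neither allele"):
            extract_submission_sequence(ref, self._marker(51), window=101)

    def test_truncation_warns(self):
        ref = {"c1": "T" * 10 + "A" + "T" * 10}
        with pytest.warns(UserWarning, match="truncated"):
            seq = extract_submission_sequence(ref, self._marker(11), window=101)
        assert seq == "T" * 10 + "[A/G]" + "T" * 10


class TestBuildDecisionTree:
    def test_canonical_markers_reproduce_published_tree(self, panel):
        markers = list(panel.markers.values())  # published table row order
        tree = build_decision_tree(markers, sorted(panel.groups), root_marker="BTS99-319")
        root = tree.root
        assert root.marker == "BTS99-319"
        assert root.edges["XX"].marker == "BTS22-762"
        assert {l.name for l in root.edges["XX"].edges.values()} == {"SSA-ECA", "SSA-WA"}
        non_ecawa = root.edges["YY"]
        assert non_ecawa.marker == "BTS141"
        assert non_ecawa.confirmations == ["BTS613"]
        assert non_ecawa.edges["XX"].marker == "BTS55-473"
        esa_ca = non_ecawa.edges["YY"]
        assert esa_ca.marker == "BTS46-203"
        assert "BTS1161" in esa_ca.confirmations

    def test_order_tiebreak_without_pin_still_resolves_all_groups(self, panel):
        tree = build_decision_tree(list(panel.markers.values()), sorted(panel.groups))
        assert sorted(tree.leaves()) == sorted(panel.groups)
        assert tree.root.marker == "BTS99-319"  # first listed among balanced splits

    def test_unresolvable_groups_error_names_pair(self, panel):
        markers = [m for m in panel.markers.values() if m.marker_id not in ("BTS46-203", "BTS1161")]
        with pytest.raises(InvalidSpecError, match="SSA-CA\\|SSA-ESA"):
            build_decision_tree(markers, sorted(panel.groups))

    def test_every_group_profile_reaches_its_leaf(self, panel):
        # Exhaustive leaf-path check: walking the tree with each group's
        # canonical genotype states ends at that group's leaf.
        tree = build_decision_tree(list(panel.markers.values()), sorted(panel.groups))
        for group in panel.groups:
            node = tree.root
            while not isinstance(node, Leaf):
                m = panel.marker(node.marker)
                state = "XX" if group in m.partition["XX"] else "YY"
                node = node.edges[state]
            assert node.name == group

    def test_depth_bounded_by_marker_count(self, panel):
        tree = build_decision_tree(list(panel.markers.values()), sorted(panel.groups))
        assert tree.depth() <= len(panel.markers)


def test_vcf_round_trip(tmp_path, cohort_matrix):
    matrix, _ = cohort_matrix
    sub = GenotypeMatrix(
        calls=matrix.calls.iloc[:10, :12].copy(), loci=matrix.loci.iloc[:12].copy()
    )
    path = tmp_path / "m.vcf"
    write_matrix_vcf(sub, path)
    back = read_matrix_vcf(path)
    assert set(back.locus_ids) == set(sub.locus_ids)
    for s in sub.sample_ids:
        for l in sub.locus_ids:
            assert back.calls.at[s, l] == sub.calls.at[s, l]
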