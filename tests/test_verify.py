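"""Haplotype-concordance verification: conflicting pairs, individual
attribution, informative sets, misplaced branches and the reliability
indices."""

from __future__ import annotations

from itertools import combinations

import pytest

from matriline.forest import build_forest
from matriline.pedigree_io import Pedigree
from matriline.synth import SynthConfig, generate, inject_conflict
from matriline.verify import (
    conflict_counts,
    find_conflicting_pairs,
    find_informative_individuals,
    find_misplaced,
    flag_conflicting_individuals,
    verify_pedigree,
)

from conftest import rec


class TestConflictingPairs:
    def test_mixed_line_pairs(self, conflict_line):
        f = build_forest(conflict_line)
        assert find_conflicting_pairs(f, conflict_line) == {("x", "z"), ("y", "z")}

    def test_concordant_line_is_empty(self):
        p = Pedigree([rec("F"), rec("x", dam="F", hap="A"), rec("y", dam="F", hap="A")])
        f = build_forest(p)
        assert find_conflicting_pairs(f, p) == set()

    def test_cross_line_differences_excluded(self):
        p = Pedigree([rec("F", hap="A"), rec("G", hap="B")])
        f = build_forest(p)
        assert find_conflicting_pairs(f, p) == set()

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_counts_match_brute_force_pairs(self, seed):
        p, _ = generate(SynthConfig(seed=seed, n_conflicts_injected=2, n_haplotypes=4))
        f = build_forest(p)
        pairs = find_conflicting_pairs(f, p)
        counts = conflict_counts(f, p)
        brute: dict[str, int] = {}
        for i, j in pairs:
            brute[i] = brute.get(i, 0) + 1
            brute[j] = brute.get(j, 0) + 1
        assert counts == brute


class TestFlagging:
    def test_majority_flags_minority(self, conflict_line):
        f = build_forest(conflict_line)
        pairs = find_conflicting_pairs(f, conflict_line)
        counts = conflict_counts(f, conflict_line)
        assert counts == {"x": 1, "y": 1, "z": 2}
        assert flag_conflicting_individuals(pairs, counts, "strict") == {"z"}
        assert flag_conflicting_individuals(pairs, counts, "both") == {"z"}

    def test_tie_rule(self):
        p = Pedigree([rec("F"), rec("x", dam="F", hap="A"), rec("z", dam="F", hap="B")])
        f = build_forest(p)
        pairs = find_conflicting_pairs(f, p)
        counts = conflict_counts(f, p)
        assert flag_conflicting_individuals(pairs, counts, "both") == {"x", "z"}
        assert flag_conflicting_individuals(pairs, counts, "strict") == set()

    def test_no_pairs_no_flags(self):
        assert flag_conflicting_individuals(set(), {}, "both") == set()


class TestInformative:
    def test_path_through_unhaplotyped_mother(self):
        p = Pedigree([rec("g", hap="A"), rec("m", dam="g"), rec("c", dam="m", hap="A")])
        f = build_forest(p)
        assert find_informative_individuals(f, p) == {"g", "m", "c"}

    def test_single_haplotyped_line_contributes_nothing(self):
        p = Pedigree([rec("F"), rec("d", dam="F", hap="A"), rec("e", dam="d")])
        f = build_forest(p)
        assert find_informative_individuals(f, p) == set()

    def test_star_path_via_mrca(self):
        p = Pedigree([rec("F"), rec("d1", dam="F", hap="A"), rec("d2", dam="F", hap="A")])
        f = build_forest(p)
        assert find_informative_individuals(f, p) == {"d1", "F", "d2"}

    def test_off_path_branches_excluded(self):
        p = Pedigree(
            [
                rec("F"),
                rec("d1", dam="F", hap="A"),
                rec("d2", dam="F", hap="A"),
                rec("side", dam="F"),  # not on any path between haplotyped members
            ]
        )
        f = build_forest(p)
        assert "side" not in find_informative_individuals(f, p)

    @pytest.mark.parametrize("seed", [0, 6])
    def test_matches_pairwise_path_union_oracle(self, seed):
        p, _ = generate(SynthConfig(seed=seed, n_founder_dams=3, generations=3))
        f = build_forest(p)
        hap = [r.id for r in p if r.haplotype is not None]
        expected: set[str] = set()
        for i, j in combinations(hap, 2):
            if f.line_of[i] != f.line_of[j]:
                continue
            # union of root paths minus the shared prefix above the MRCA
            pi, pj = [], []
            v = i
            while v is not None:
                pi.append(v)
                v = f.parent_of[v]
            v = j
            while v is not None:
                pj.append(v)
                v = f.parent_of[v]
            shared = set(pi) & set(pj)
            top = min(shared, key=lambda x: -f.depth[x])
            path = [v for v in pi if f.depth[v] >= f.depth[top]]
            path += [v for v in pj if f.depth[v] >= f.depth[top]]
            expected.update(path)
            expected.add(top)
        assert find_informative_individuals(f, p) == expected


class TestMisplaced:
    def fixture_branch(self) -> Pedigree:
        """Host line with haplotype A; subtree rooted at b carries foreign B:
        b and its three haplotyped descendants are all conflicting, and the
        descendants match their nearest haplotyped ancestor (b or below)."""
        return Pedigree(
            [
                rec("F", hap="A"),
                rec("a1", dam="F", hap="A"),
                rec("a2", dam="F", hap="A"),
                rec("a3", dam="F", hap="A"),
                rec("a4", dam="F", hap="A"),
                rec("a5", dam="F", hap="A"),
                rec("u", dam="F", hap="B"),
                rec("b", dam="u", hap="B"),
                rec("c1", dam="b", hap="B"),
                rec("c2", dam="b", hap="B"),
                rec("c3", dam="c1", hap="B"),
            ]
        )

    def test_misplaced_requires_matching_ancestor(self):
        p = self.fixture_branch()
        f = build_forest(p)
        report = verify_pedigree(p)
        # u conflicts but its predecessor F has a different haplotype
        assert "u" not in report.misplaced_individuals
        assert report.misplaced_individuals == {"b", "c1", "c2", "c3"}

    def test_single_outermost_branch(self):
        p = self.fixture_branch()
        report = verify_pedigree(p)
        assert report.misplaced_branches == [("b", 4)]

    def test_unhaplotyped_ancestors_not_misplaced(self):
        p = Pedigree(
            [
                rec("F"),
                rec("x", dam="F", hap="A"),
                rec("y", dam="F", hap="A"),
                rec("z", dam="F", hap="B"),
            ]
        )
        f = build_forest(p)
        misplaced, branches = find_misplaced(f, p, {"z"})
        assert misplaced == set() and branches == []

    def test_pruning_counts_branch_once(self):
        p = self.fixture_branch()
        report = verify_pedigree(p)
        # flagged: u + {b, c1, c2, c3}; the branch collapses to one error
        assert report.conflicting_individuals == {"u", "b", "c1", "c2", "c3"}
        assert report.pruned_conflicts == 5 - (4 - 1)


class TestIndices:
    def test_hc_ratio(self, conflict_line):
        report = verify_pedigree(conflict_line)
        # 1 conflicting of 4 haplotyped (x, y, z, g1)
        assert report.hc_index == pytest.approx(100 * 1 / 4)

    def test_ic_ratio(self, conflict_line):
        report = verify_pedigree(conflict_line)
        assert report.informative_individuals == {"x", "y", "z", "F"}
        assert report.ic_index == pytest.approx(100 * 1 / 4)

    def test_zero_conflicts(self):
        p = Pedigree([rec("F"), rec("x", dam="F", hap="A"), rec("y", dam="F", hap="A")])
        report = verify_pedigree(p)
        assert report.hc_index == 0.0 and report.ic_index == 0.0
        assert report.misplaced_index is None
        assert "misplaced" in report.undefined

    def test_no_haplotypes_undefined(self):
        p = Pedigree([rec("F"), rec("x", dam="F")])
        report = verify_pedigree(p)
        assert report.hc_index is None and "hc" in report.undefined

    def test_indices_invariant_under_record_order(self, conflict_line):
        rev = Pedigree(
            list(reversed(conflict_line.records)),
            has_haplotype=True,
        )
        a, b = verify_pedigree(conflict_line), verify_pedigree(rev)
        assert (a.hc_index, a.ic_index, a.pruned_conflicts) == (
            b.hc_index,
            b.ic_index,
            b.pruned_conflicts,
        )
        assert a.conflicting_individuals == b.conflicting_individuals


class TestOnSyntheticPedigrees:
    @pytest.mark.parametrize("seed", range(5))
    def test_conflict_free_generation_verifies_clean(self, seed):
        p, _ = generate(SynthConfig(seed=seed))
        report = verify_pedigree(p)
        assert not report.has_conflicts
        assert report.hc_index == 0.0
        assert report.pruned_conflicts == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_single_injection_recovered_exactly(self, seed):
        p, truth = generate(SynthConfig(seed=seed, n_conflicts_injected=1))
        victim = truth.injected_conflicts[0].individual
        report = verify_pedigree(p, tie_rule="strict")
        assert report.conflicting_individuals == {victim}

    def test_injection_raises_hc_numerator_by_one(self):
        p, truth = generate(SynthConfig(seed=11))
        clean = verify_pedigree(p, tie_rule="strict")
        import numpy as np

        mutated, truth2 = inject_conflict(p, truth, "single_individual", np.random.default_rng(0))
        report = verify_pedigree(mutated, tie_rule="strict")
        assert len(report.conflicting_individuals) == len(clean.conflicting_individuals) + 1

    def test_injection_reversal_restores_clean_report(self):
        import numpy as np
        from dataclasses import replace as drep

        p, truth = generate(SynthConfig(seed=13))
        mutated, truth2 = inject_conflict(p, truth, "single_individual", np.random.default_rng(1))
        inj = truth2.injected_conflicts[0]
        restored = Pedigree(
            [
                drep(r, haplotype=inj.original_haplotype) if r.id == inj.individual else r
                for r in mutated.records
            ],
            has_haplotype=True,
            has_available=mutated.has_available,
        )
        assert verify_pedigree(restored).conflicting_individuals == set()
        assert restored.records == p.records
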