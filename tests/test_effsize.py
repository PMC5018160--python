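"""Probability of identity and uniparental effective sizes: closed forms,
pseudo-haplotype handling, symmetry, and brute-force oracle equivalence."""

from __future__ import annotations

import math

import pytest

from matriline.effsize import (
    INFINITE,
    delta_pi,
    effective_size,
    haplotype_effective_size,
    haplotype_frequencies,
    maternal_effective_size,
    maternal_frequencies,
    paternal_effective_size,
    pi,
)
from matriline.errors import UndefinedResultError
from matriline.forest import build_forest
from matriline.pedigree_io import Gender, Pedigree
from matriline.stats import impute_haplotypes, reference_population
from matriline.pedigree_io import ReferenceWindow
from matriline.synth import SynthConfig, generate

from conftest import rec


class TestPi:
    def test_uniform_is_one_over_k(self):
        assert pi({f"d{i}": 0.25 for i in range(4)}) == pytest.approx(0.25)

    def test_single_label_is_one(self):
        assert pi({"d": 1.0}) == 1.0

    def test_direct_arithmetic(self):
        assert pi({"a": 0.75, "b": 0.25}) == pytest.approx(0.625)

    def test_empty_map_rejected(self):
        with pytest.raises(UndefinedResultError):
            pi({})

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError):
            pi({"a": 0.6, "b": 0.6})


class TestDeltaPiAndNe:
    def test_direct_substitution(self):
        assert delta_pi(0.5, 0.625) == pytest.approx(0.25)

    def test_no_increase_is_zero(self):
        assert delta_pi(0.3, 0.3) == 0.0

    def test_complete_fixation(self):
        assert delta_pi(0.25, 1.0) == pytest.approx(1.0)

    def test_single_founder_line_undefined(self):
        with pytest.raises(UndefinedResultError):
            delta_pi(1.0, 1.0)

    def test_ne_reciprocal(self):
        assert effective_size(0.25) == pytest.approx(4.0)

    def test_ne_infinite_without_drift(self):
        assert effective_size(0.0) == INFINITE

    def test_ne_one_at_fixation(self):
        assert effective_size(1.0) == pytest.approx(1.0)

    def test_negative_delta_is_hard_error(self):
        with pytest.raises(ValueError):
            effective_size(-0.1)


def two_line_pedigree() -> Pedigree:
    """Two founder dams; reference females 3 (F) and 1 (G)."""
    recs = [rec("F", yob=1990), rec("G", yob=1990)]
    for i in range(3):
        recs.append(rec(f"f{i}", dam="F", yob=2000, gender=Gender.FEMALE))
    recs.append(rec("g0", dam="G", yob=2000, gender=Gender.FEMALE))
    return Pedigree(recs)


class TestMaternal:
    def test_reference_frequencies_from_female_counts(self):
        p = two_line_pedigree()
        f = build_forest(p)
        refpop = reference_population(p, ReferenceWindow(2000, 2005))
        founder, reference = maternal_frequencies(f, p, refpop)
        assert founder == {"F": 0.5, "G": 0.5}
        assert reference == {"F": 0.75, "G": 0.25}

    def test_worked_example_ne_four(self):
        p = two_line_pedigree()
        f = build_forest(p)
        refpop = reference_population(p, ReferenceWindow(2000, 2005))
        res = maternal_effective_size(p, refpop, f)
        assert res.pi_founder == pytest.approx(0.5)
        assert res.pi_reference == pytest.approx(0.625)
        assert res.delta_pi == pytest.approx(0.25)
        assert res.ne == pytest.approx(4.0)

    def test_uniform_survival_infinite_ne(self):
        recs = [rec("F", yob=1990), rec("G", yob=1990)]
        recs += [rec(f"f{i}", dam="F", yob=2000) for i in range(2)]
        recs += [rec(f"g{i}", dam="G", yob=2000) for i in range(2)]
        p = Pedigree(recs)
        refpop = reference_population(p, ReferenceWindow(2000, 2005))
        res = maternal_effective_size(p, refpop)
        assert res.delta_pi == 0.0 and res.ne == INFINITE

    def test_collapse_to_one_line_gives_ne_one(self):
        recs = [rec("F", yob=1990), rec("G", yob=1990), rec("H", yob=1990)]
        recs += [rec(f"f{i}", dam="F", yob=2000) for i in range(4)]
        p = Pedigree(recs)
        refpop = reference_population(p, ReferenceWindow(2000, 2005))
        res = maternal_effective_size(p, refpop)
        assert res.delta_pi == pytest.approx(1.0)
        assert res.ne == pytest.approx(1.0)

    def test_males_do_not_move_maternal_ne(self):
        p = two_line_pedigree()
        recs = list(p.records)
        recs.append(rec("m0", dam="F", yob=2000, gender=Gender.MALE))
        recs.append(rec("m1", dam="G", yob=2000, gender=Gender.MALE))
        q = Pedigree(recs)
        w = ReferenceWindow(2000, 2005)
        a = maternal_effective_size(p, reference_population(p, w))
        b = maternal_effective_size(q, reference_population(q, w))
        assert a.ne == pytest.approx(b.ne)

    def test_no_reference_females_undefined(self):
        p = Pedigree([rec("F", yob=1990), rec("m", dam="F", yob=2000, gender=Gender.MALE)])
        with pytest.raises(UndefinedResultError):
            maternal_effective_size(p, reference_population(p, ReferenceWindow(2000, 2005)))


class TestHaplotype:
    def test_founder_map_with_pseudo_label(self):
        recs = [
            rec("A", yob=1990, hap="HT1"),
            rec("B", yob=1990, hap="HT1"),
            rec("C", yob=1990, hap="HT2"),
            rec("D", yob=1990),  # unknown haplotype -> unique pseudo label
        ]
        recs += [rec(f"c{i}", dam="A", yob=2000) for i in range(2)]
        p = Pedigree(recs)
        f = build_forest(p)
        refpop = reference_population(p, ReferenceWindow(1990, 2005))
        imputed = impute_haplotypes(f, p)
        founder, _ = haplotype_frequencies(f, p, refpop, imputed)
        assert founder == {"HT1": 0.5, "HT2": 0.25, "PSEUDO_D": 0.25}

    def test_fixation_in_reference(self):
        recs = [rec("A", yob=1990, hap="HT1"), rec("B", yob=1990, hap="HT2")]
        recs += [rec(f"c{i}", dam="A", yob=2000) for i in range(3)]
        p = Pedigree(recs)
        f = build_forest(p)
        refpop = reference_population(p, ReferenceWindow(2000, 2005))
        res = haplotype_effective_size(p, refpop, f)
        assert res.pi_reference == pytest.approx(1.0)

    def test_males_count_in_haplotype_but_not_maternal(self):
        recs = [
            rec("A", yob=1990, hap="HT1"),
            rec("B", yob=1990, hap="HT2"),
            rec("fa", dam="A", yob=2000, gender=Gender.FEMALE),
            rec("fb", dam="B", yob=2000, gender=Gender.FEMALE),
        ]
        p0 = Pedigree(recs)
        p1 = Pedigree(recs + [rec("m", dam="A", yob=2000, gender=Gender.MALE)])
        w = ReferenceWindow(2000, 2005)
        mat0 = maternal_effective_size(p0, reference_population(p0, w))
        mat1 = maternal_effective_size(p1, reference_population(p1, w))
        hap0 = haplotype_effective_size(p0, reference_population(p0, w))
        hap1 = haplotype_effective_size(p1, reference_population(p1, w))
        assert mat0.ne == mat1.ne  # both INFINITE: uniform females
        assert hap0.pi_reference != hap1.pi_reference

    @pytest.mark.parametrize("seed", range(3))
    def test_pi_matches_brute_force_counts(self, seed):
        p, _ = generate(SynthConfig(seed=seed))
        f = build_forest(p)
        refpop = reference_population(p, ReferenceWindow(1980, 2010))
        imputed = impute_haplotypes(f, p)
        res = haplotype_effective_size(p, refpop, f, imputed)
        counts: dict[str, int] = {}
        for ind in refpop:
            lab = imputed[f.line_of[ind]] or f"PSEUDO_{f.line_of[ind]}"
            counts[lab] = counts.get(lab, 0) + 1
        brute = sum((c / len(refpop)) ** 2 for c in counts.values())
        assert res.pi_reference == pytest.approx(brute)


class TestPaternal:
    def test_mirror_of_maternal(self):
        """Swapping genders and parent columns must reproduce the maternal numbers."""
        p = two_line_pedigree()
        recs = []
        for r in p.records:
            recs.append(
                rec(
                    r.id,
                    sire=r.dam,
                    dam=None,
                    yob=r.yob,
                    gender=Gender.MALE if r.gender is Gender.FEMALE else Gender.FEMALE,
                )
            )
        q = Pedigree(recs)
        w = ReferenceWindow(2000, 2005)
        mat = maternal_effective_size(p, reference_population(p, w))
        pat = paternal_effective_size(q, reference_population(q, w))
        assert pat.pi_founder == pytest.approx(mat.pi_founder)
        assert pat.pi_reference == pytest.approx(mat.pi_reference)
        assert pat.ne == pytest.approx(mat.ne)

    def test_no_reference_males_undefined(self):
        p = two_line_pedigree()
        with pytest.raises(UndefinedResultError):
            paternal_effective_size(p, reference_population(p, ReferenceWindow(2000, 2005)))

    def test_uniform_sires_infinite(self):
        recs = [rec("S1", yob=1990, gender=Gender.MALE), rec("S2", yob=1990, gender=Gender.MALE)]
        recs += [rec(f"m{i}", sire="S1", yob=2000, gender=Gender.MALE) for i in range(2)]
        recs += [rec(f"n{i}", sire="S2", yob=2000, gender=Gender.MALE) for i in range(2)]
        p = Pedigree(recs)
        res = paternal_effective_size(p, reference_population(p, ReferenceWindow(2000, 2005)))
        assert res.ne == INFINITE
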