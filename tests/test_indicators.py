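"""Indicator and pattern-frequency semantics, including the brute-force
characterization of perfect co-segregation (LF = 0) under Condition 2."""

import itertools

import pytest

from gst.indicators import (
    build_indicator_matrix,
    determine_condition,
    indicator_condition1,
    indicator_condition2,
    modal_patient_genotype,
    pattern_frequency,
)
from gst.pedigree import ROLE_FATHER, ROLE_MOTHER, ROLE_OFFSPRING, FamilyStructure
from gst.variants import GenotypeCall

from conftest import make_member, site


class TestDetermineCondition:
    def test_both_parents_genotyped(self, quartet):
        assert determine_condition(quartet) == 1

    def test_single_or_no_genotyped_parent(self, siblings7):
        assert determine_condition(siblings7) == 2
        fam = FamilyStructure([
            make_member("M", 1, ROLE_MOTHER, affected=False),
            make_member("D", 2, ROLE_OFFSPRING, affected=True),
        ])
        assert determine_condition(fam) == 2

    def test_parent_present_without_data(self):
        fam = FamilyStructure([
            make_member("F", 1, ROLE_FATHER, affected=False, has_data=False),
            make_member("M", 2, ROLE_MOTHER, affected=False),
            make_member("D", 3, ROLE_OFFSPRING, affected=True),
        ])
        assert determine_condition(fam) == 2


class TestCondition1:
    @pytest.mark.parametrize("d1_gt, expected", [
        ("A/G", 0.0),  # affected daughter shares affected mother's het
        ("A/A", 1.0),  # affected daughter matching the reference is inconsistent
        ("G/G", 1.0),  # differs from the affected parent's genotype
    ])
    def test_affected_offspring(self, quartet, d1_gt, expected):
        s = site("A", {"F": "A/A", "M": "A/G", "D1": d1_gt, "D2": "A/G"})
        ind = indicator_condition1(s, quartet)
        assert ind["D1"] == expected
        assert ind["D2"] == 0.0

    def test_unaffected_offspring_matches_reference(self):
        fam = FamilyStructure([
            make_member("F", 1, ROLE_FATHER, affected=False),
            make_member("M", 2, ROLE_MOTHER, affected=True),
            make_member("S", 3, ROLE_OFFSPRING, affected=False),
        ])
        s = site("A", {"F": "A/A", "M": "A/G", "S": "A/A"})
        assert indicator_condition1(s, fam)["S"] == 0.0
        s = site("A", {"F": "A/A", "M": "A/G", "S": "A/G"})
        assert indicator_condition1(s, fam)["S"] == 1.0

    def test_missing_genotype_forces_one(self, quartet):
        s = site("A", {"F": "A/A", "M": "A/G", "D1": None, "D2": "A/G"})
        ind = indicator_condition1(s, quartet)
        assert ind["D1"] == 1.0
        s = site("A", {"F": None, "M": "A/G", "D1": "A/G", "D2": "A/G"})
        assert all(v == 1.0 for v in indicator_condition1(s, quartet).values())

    def test_same_state_parents_drop_absent_clause(self):
        # both parents unaffected: affected offspring needs only
        # hom-ref parents and a non-reference genotype of its own
        fam = FamilyStructure([
            make_member("F", 1, ROLE_FATHER, affected=False),
            make_member("M", 2, ROLE_MOTHER, affected=False),
            make_member("D", 3, ROLE_OFFSPRING, affected=True),
        ])
        s = site("A", {"F": "A/A", "M": "A/A", "D": "A/G"})
        assert indicator_condition1(s, fam)["D"] == 0.0
        s = site("A", {"F": "A/A", "M": "A/A", "D": "A/A"})
        assert indicator_condition1(s, fam)["D"] == 1.0

    def test_wrong_condition_is_hard_error(self, siblings7):
        s = site("A", {f"M{k}": "A/A" for k in range(1, 8)})
        with pytest.raises(ValueError):
            indicator_condition1(s, siblings7)

    def test_offspring_label_permutation_invariance(self, quartet):
        s1 = site("A", {"F": "A/A", "M": "A/G", "D1": "A/G", "D2": "G/G"})
        s2 = site("A", {"F": "A/A", "M": "A/G", "D1": "G/G", "D2": "A/G"})
        i1 = indicator_condition1(s1, quartet)
        i2 = indicator_condition1(s2, quartet)
        assert sorted(i1.values()) == sorted(i2.values())


class TestModalGenotype:
    def test_majority_mode(self, siblings7):
        fam = FamilyStructure([make_member(f"M{k}", k, ROLE_OFFSPRING, affected=True)
                               for k in range(1, 4)])
        s = site("A", {"M1": "A/G", "M2": "A/G", "M3": "G/G"})
        assert modal_patient_genotype(s, fam) == GenotypeCall(("A", "G"))

    def test_tie_breaks_lexicographically(self):
        fam = FamilyStructure([make_member(f"M{k}", k, ROLE_OFFSPRING, affected=True)
                               for k in range(1, 3)])
        s = site("A", {"M1": "G/G", "M2": "A/G"})
        assert modal_patient_genotype(s, fam) == GenotypeCall(("A", "G"))

    def test_singleton_and_all_missing(self):
        fam = FamilyStructure([make_member("M1", 1, ROLE_OFFSPRING, affected=True)])
        s = site("A", {"M1": "G/G"})
        assert modal_patient_genotype(s, fam) == GenotypeCall(("G", "G"))
        s = site("A", {"M1": None})
        assert modal_patient_genotype(s, fam).missing
        # downstream: the affected member then scores I = 1
        assert indicator_condition2(s, fam)["M1"] == 1.0


class TestCondition2:
    @pytest.mark.parametrize("affected, gt, msnv, expected", [
        (False, "A/A", None, 0.0),     # unaffected homozygous reference
        (False, "A/G", None, 1.0),     # unaffected carrying a variant
        (True, "A/G", "A/G", 0.0),     # affected carries the modal variant
        (True, "G/G", "A/G", 0.5),     # affected carries a different variant
        (True, "A/A", "A/G", 1.0),     # affected matching the reference
        (True, "A/A", "A/A", 1.0),     # modal genotype equal to reference
        (True, None, "A/G", 1.0),      # missing call
    ])
    def test_indicator_cases(self, affected, gt, msnv, expected):
        fam = FamilyStructure([
            make_member("X", 1, ROLE_OFFSPRING, affected=affected),
            make_member("P", 2, ROLE_OFFSPRING, affected=True),
        ])
        s = site("A", {"X": gt, "P": msnv or "A/G"})
        m = GenotypeCall(tuple(msnv.split("/"))) if msnv else None
        assert indicator_condition2(s, fam, m)["X"] == expected

    def test_same_state_permutation_invariance(self, siblings7):
        gts = {"M1": "A/G", "M2": "G/G", "M3": "A/A", "M4": "A/G",
               "M5": "A/A", "M6": "A/A", "M7": "A/G"}
        swapped = dict(gts, M3="A/G", M7="A/A")  # swap two unaffected members
        i1 = indicator_condition2(site("A", gts), siblings7)
        i2 = indicator_condition2(site("A", swapped), siblings7)
        assert sorted(i1.values()) == sorted(i2.values())


class TestPatternFrequency:
    @pytest.mark.parametrize("vals, expected", [
        ({"a": 0.0, "b": 0.0, "c": 0.0}, 0.0),
        ({"a": 0.0, "b": 0.5, "c": 1.0}, 1.5),
        ({"a": 1.0, "b": 1.0}, 2.0),
    ])
    def test_exact_sum(self, vals, expected):
        lf, c = pattern_frequency(vals)
        assert lf == expected
        assert c == len(vals)

    def test_invalid_indicator_rejected(self):
        with pytest.raises(ValueError):
            pattern_frequency({"a": 0.25})

    def test_skip_policy_decrements_local_count(self):
        lf, c = pattern_frequency({"a": 0.0, "b": None, "c": 1.0})
        assert lf == 1.0 and c == 2

    def test_flipping_zero_to_one_adds_exactly_one(self):
        base = {"a": 0.0, "b": 0.5, "c": 0.0}
        lf0, _ = pattern_frequency(base)
        lf1, _ = pattern_frequency(dict(base, c=1.0))
        assert lf1 - lf0 == 1.0


GENOTYPES = ["A/A", "A/G", "G/G"]


def brute_force_lf_zero(affections, genotypes):
    """Independent characterization: LF = 0 under Condition 2 iff every
    unaffected member is hom-ref, every affected member carries the modal
    affected genotype, and that modal genotype is not hom-ref."""
    aff_gts = [g for a, g in zip(affections, genotypes) if a]
    counts = {}
    for g in aff_gts:
        counts[tuple(sorted(g.split("/")))] = counts.get(tuple(sorted(g.split("/"))), 0) + 1
    msnv = min(counts, key=lambda c: (-counts[c], "/".join(c)))
    if msnv == ("A", "A"):
        return False
    for a, g in zip(affections, genotypes):
        gt = tuple(sorted(g.split("/")))
        if a and gt != msnv:
            return False
        if not a and gt != ("A", "A"):
            return False
    return True


def test_condition2_lf_zero_characterization_exhaustive():
    """Enumerate every genotype assignment for families of 2-4 members over
    a biallelic site and compare LF = 0 against the brute-force oracle."""
    for n_members in (2, 3, 4):
        ids = [f"P{k}" for k in range(n_members)]
        for affections in itertools.product([False, True], repeat=n_members):
            if not any(affections):
                continue
            fam = FamilyStructure([
                make_member(mid, v + 1, ROLE_OFFSPRING, affected=a)
                for v, (mid, a) in enumerate(zip(ids, affections))
            ])
            for genotypes in itertools.product(GENOTYPES, repeat=n_members):
                s = site("A", dict(zip(ids, genotypes)))
                ind = indicator_condition2(s, fam)
                lf, _ = pattern_frequency(ind)
                assert (lf == 0.0) == brute_force_lf_zero(affections, genotypes), (
                    affections, genotypes)


def test_build_indicator_matrix_condition2(siblings7):
    from gst.variants import SiteTable
    table = SiteTable(member_ids=[m.member_id for m in siblings7.members])
    causal = site("A", {"M1": "A/G", "M2": "A/G", **{f"M{k}": "A/A" for k in range(3, 8)}},
                  locus=100)
    shared = site("C", {f"M{k}": "C/T" for k in range(1, 8)}, locus=200)
    table.sites["chr1"] = [causal, shared]
    matrix = build_indicator_matrix(table, siblings7)
    assert matrix.condition == 2
    assert matrix.lf["chr1"][0] == 0.0
    # shared het: affected match msnv (0 each), all 5 unaffected carry it (1 each)
    assert matrix.lf["chr1"][1] == 5.0
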