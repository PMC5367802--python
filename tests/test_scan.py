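"""Scanner unit tests: analytic counts, carriers, partition and exclusive scans."""

import numpy as np
import pytest

from exclucomb import (
    BudgetError,
    CarrierSet,
    Combination,
    GenotypeAtom,
    GenotypeDataset,
    MultiplicityDistribution,
    ScanConfig,
    ValidationError,
    atom_carriers,
    combination_carriers,
    exclusive_scan,
    guided_scan,
    iter_partition_combinations,
    multiplicity_distribution,
    partition_scan,
    theoretical_combination_count,
)
from exclucomb.stats import atom_pvalue_matrix

from conftest import random_dataset


def combo(*pairs):
    return Combination(tuple(GenotypeAtom(s, c) for s, c in pairs))


class TestTheoreticalCount:
    @pytest.mark.parametrize(
        "n, r, genotyped, expected",
        [
            (803, 3, True, 2_321_319_627),
            (100, 10, False, 17_310_309_456_440),
            (5, 0, True, 1),
            (3, 5, False, 0),
            (1, 1, True, 3),
        ],
    )
    def test_values(self, n, r, genotyped, expected):
        assert theoretical_combination_count(n, r, genotyped) == expected

    def test_genotyped_is_plain_times_3_to_r(self):
        for n, r in [(10, 2), (50, 4), (803, 3), (7, 7)]:
            assert theoretical_combination_count(
                n, r, True
            ) == theoretical_combination_count(n, r, False) * 3**r

    def test_exact_integer_at_genome_scale(self):
        # way beyond float precision; must stay exact
        v = theoretical_combination_count(500_000, 3, True)
        assert v % 3**3 == 0

    @pytest.mark.parametrize("n, r", [(-1, 2), (5, -1)])
    def test_negative_inputs_rejected(self, n, r):
        with pytest.raises(ValidationError):
            theoretical_combination_count(n, r)


class TestCarriers:
    def test_atom_carriers_by_hand(self, d0):
        cs = atom_carriers(d0, GenotypeAtom(1, 1))
        assert cs.members == frozenset({0, 1, 3})
        assert (cs.n_patients, cs.n_controls) == (2, 1)

    def test_absent_code_gives_empty_set(self, d0):
        cs = atom_carriers(d0, GenotypeAtom(0, 2))
        assert len(cs) == 0

    def test_missing_genotype_never_carries(self):
        ds = GenotypeDataset(
            ["a", "b"], [True, False], ["x"], np.array([[-1], [0]])
        )
        for code in (0, 1, 2):
            assert 0 not in atom_carriers(ds, GenotypeAtom(0, code)).members

    def test_invalid_snp_index_rejected(self, d0):
        with pytest.raises(ValidationError):
            atom_carriers(d0, GenotypeAtom(99, 0))

    @pytest.mark.parametrize(
        "pairs, expected",
        [([(0, 0), (1, 1)], {0, 1}), ([(1, 1), (2, 2)], {0})],
    )
    def test_combination_carriers_by_hand(self, d0, pairs, expected):
        cs = combination_carriers(d0, combo(*pairs))
        assert cs.members == frozenset(expected)

    def test_empty_combination_matches_everyone(self, d0):
        cs = combination_carriers(d0, Combination(()))
        assert cs.members == frozenset(range(4))

    def test_superset_of_empty_carrier_atom_is_empty(self, d0):
        cs = combination_carriers(d0, combo((0, 2), (1, 1)))
        assert len(cs) == 0

    def test_intersection_equals_atom_mask_and(self, d0):
        c = combo((0, 0), (2, 0))
        expected = frozenset(
            np.flatnonzero(
                d0.atom_mask(GenotypeAtom(0, 0)) & d0.atom_mask(GenotypeAtom(2, 0))
            ).tolist()
        )
        assert combination_carriers(d0, c).members == expected


class TestPartitionScan:
    def test_d0_r2_full_accounting(self, d0):
        pc = partition_scan(d0, 2)
        assert (pc.found, pc.shared, pc.patient_only, pc.control_only) == (9, 2, 3, 4)
        assert dict(pc.patient_multiplicity) == {1: 2, 2: 1}
        assert pc.theoretical == 27

    def test_d0_r1(self, d0):
        pc = partition_scan(d0, 1)
        assert (pc.found, pc.shared, pc.patient_only, pc.control_only) == (6, 4, 0, 2)

    def test_identical_subjects_all_shared(self):
        geno = np.tile([0, 1, 2], (6, 1))
        ds = GenotypeDataset(
            [f"s{i}" for i in range(6)], [True] * 3 + [False] * 3,
            ["a", "b", "c"], geno,
        )
        pc = partition_scan(ds, 2)
        assert pc.patient_only == 0 and pc.control_only == 0
        assert pc.found == pc.shared

    def test_budget_refusal_names_the_count(self, d0):
        with pytest.raises(BudgetError, match="27"):
            partition_scan(d0, 2, budget=10)

    def test_streaming_iterator_matches_counts(self, d0):
        cats = [cat for _, _, cat in iter_partition_combinations(d0, 2)]
        assert len(cats) == 9
        assert cats.count("shared") == 2
        assert cats.count("patient_only") == 3
        assert cats.count("control_only") == 4

    def test_conservation_on_random_data(self):
        rng = np.random.default_rng(11)
        for _ in range(15):
            ds = random_dataset(rng)
            for r in (1, 2):
                pc = partition_scan(ds, r)
                assert pc.found == pc.shared + pc.patient_only + pc.control_only
                assert sum(pc.patient_multiplicity.values()) == pc.patient_only
                assert pc.found <= pc.theoretical


class TestExclusiveScan:
    def test_d0_exact_result(self, d0):
        res = exclusive_scan(d0, ScanConfig(max_k=3))
        assert res.levels[1] == []
        got = {c.render(d0.snp_ids): sorted(cs.members) for _, c, cs in res.combinations()}
        assert got == {
            "s1:0+s2:1": [0, 1],
            "s1:0+s3:0": [1],
            "s2:1+s3:2": [0],
        }
        assert res.levels[3] == []

    def test_min_support_filters_reporting_only(self, d0):
        res = exclusive_scan(d0, ScanConfig(max_k=3, min_patient_support=2))
        assert [c.render(d0.snp_ids) for _, c, _ in res.combinations()] == ["s1:0+s2:1"]
        # the full minimal list is retained internally
        assert res.n_exclusive_total() == 3

    def test_control_duplicate_of_every_patient_kills_exclusivity(self):
        rng = np.random.default_rng(5)
        pat = rng.integers(0, 3, size=(4, 5))
        geno = np.vstack([pat, pat, rng.integers(0, 3, size=(2, 5))])
        ds = GenotypeDataset(
            [f"x{i}" for i in range(10)],
            [True] * 4 + [False] * 6,
            [f"r{j}" for j in range(5)],
            geno,
        )
        res = exclusive_scan(ds, ScanConfig(max_k=3))
        assert res.n_exclusive_total() == 0

    def test_emitted_combinations_are_exclusive_and_minimal(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            ds = random_dataset(rng)
            res = exclusive_scan(ds, ScanConfig(max_k=4))
            seen = set()
            for _, c, cs in res.combinations():
                assert cs.n_controls == 0 and cs.n_patients >= 1
                for prev in seen:
                    assert not c.contains(prev)
                seen.add(c)
            # within the full list, minimality holds across levels
            full = res.all_exclusive()
            flat = [c for combos in full.values() for c in combos]
            for i, a in enumerate(flat):
                for b in flat[:i]:
                    assert not (a.contains(b) and len(a) > len(b))

    def test_reported_order_is_lexicographic(self):
        rng = np.random.default_rng(31)
        ds = random_dataset(rng, with_missing=False)
        res = exclusive_scan(ds, ScanConfig(max_k=3))
        for k, combos in res.levels.items():
            keys = [tuple((a.snp_index, a.code) for a in c.atoms) for c, _ in combos]
            assert keys == sorted(keys)

    def test_raising_min_support_never_adds_combinations(self):
        rng = np.random.default_rng(41)
        ds = random_dataset(rng)
        low = exclusive_scan(ds, ScanConfig(max_k=3, min_patient_support=1))
        high = exclusive_scan(ds, ScanConfig(max_k=3, min_patient_support=2))
        low_set = {c for _, c, _ in low.combinations()}
        high_set = {c for _, c, _ in high.combinations()}
        assert high_set <= low_set

    def test_candidate_budget_refusal(self):
        rng = np.random.default_rng(3)
        ds = random_dataset(rng, max_snps=8, max_subjects=20)
        with pytest.raises(BudgetError):
            exclusive_scan(ds, ScanConfig(max_k=3, max_candidates=5))


class TestGuidedScan:
    def test_alpha_one_equals_exclusive_scan(self):
        rng = np.random.default_rng(17)
        for _ in range(8):
            ds = random_dataset(rng)
            cfg = ScanConfig(max_k=3)
            full = {c for _, c, _ in exclusive_scan(ds, cfg).combinations()}
            guided = {c for _, c, _ in guided_scan(ds, 1.0, cfg).combinations()}
            assert guided == full

    def test_alpha_below_minimum_p_leaves_level_one_only(self, d0):
        res = guided_scan(d0, 1e-12, ScanConfig(max_k=3))
        assert all(len(c) == 1 for _, c, _ in res.combinations())

    def test_guided_output_subset_of_exclusive(self):
        rng = np.random.default_rng(19)
        for alpha in (0.1, 0.5, 0.9):
            ds = random_dataset(rng)
            cfg = ScanConfig(max_k=3)
            full = {c for _, c, _ in exclusive_scan(ds, cfg).combinations()}
            guided = {c for _, c, _ in guided_scan(ds, alpha, cfg).combinations()}
            assert guided <= full

    def test_emitted_multis_contain_a_seed_atom(self):
        rng = np.random.default_rng(29)
        ds = random_dataset(rng, with_missing=False)
        alpha = 0.4
        pvals = atom_pvalue_matrix(ds)
        res = guided_scan(ds, alpha, ScanConfig(max_k=3))
        for k, c, _ in res.combinations():
            if k >= 2:
                assert any(pvals[a.snp_index, a.code] <= alpha for a in c)

    def test_invalid_alpha_rejected(self, d0):
        with pytest.raises(ValidationError):
            guided_scan(d0, 0.0, ScanConfig(max_k=2))


class TestMultiplicity:
    # the published 803-SNP bipolar accounting, used here as input data for
    # the tabulation arithmetic
    TABLE_HISTOGRAM = {
        1: 45_285_770, 2: 9_557_540, 3: 2_277_107, 4: 578_259, 5: 156_343,
        6: 41_019, 7: 10_990, 8: 3_002, 9: 826, 10: 261, 11: 70, 12: 22, 13: 2,
    }

    def test_published_histogram_tail_and_total(self):
        dist = MultiplicityDistribution(self.TABLE_HISTOGRAM)
        assert dist.tail(9) == 1_181
        assert dist.total == 57_911_211

    def test_empty(self):
        dist = multiplicity_distribution([])
        assert dist.total == 0 and dist.tail(1) == 0

    def test_from_scan_result(self, d0):
        res = exclusive_scan(d0, ScanConfig(max_k=3))
        dist = multiplicity_distribution(
            [(c, cs) for _, c, cs in res.combinations()]
        )
        assert dist.histogram == {1: 2, 2: 1}
        assert dist.tail(2) == 1

    def test_from_carrier_sets_directly(self):
        carriers = [CarrierSet(frozenset({0, 1}), 2, 0), CarrierSet(frozenset({0}), 1, 0)]
        assert multiplicity_distribution(carriers).histogram == {1: 1, 2: 1}
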