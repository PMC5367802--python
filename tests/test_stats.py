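"""Association tests, permutation tests and BH correction."""

import numpy as np
import pytest

from exclucomb import (
    AnchorRule,
    BudgetError,
    GenotypeAtom,
    GenotypeDataset,
    PlantSpec,
    ScanConfig,
    SimulationSpec,
    ValidationError,
    atom_association_test,
    bh_adjust,
    cluster_permutation_test,
    generate_study,
)
from exclucomb.stats import atom_pvalue_matrix

from conftest import random_dataset


def table_dataset(pat_car, pat_non, ctrl_car, ctrl_non):
    """One-SNP dataset realising a given 2x2 carrier table (carrier code 0)."""
    geno = [[0]] * pat_car + [[1]] * pat_non + [[0]] * ctrl_car + [[1]] * ctrl_non
    n_pat = pat_car + pat_non
    n = len(geno)
    return GenotypeDataset(
        [f"s{i}" for i in range(n)],
        [True] * n_pat + [False] * (n - n_pat),
        ["x"],
        np.array(geno),
    )


class TestAtomAssociation:
    def test_perfect_separation_chi_square_is_twenty(self):
        ds = table_dataset(10, 0, 0, 10)
        res = atom_association_test(ds, GenotypeAtom(0, 0))
        assert res.statistic == pytest.approx(20.0)
        assert res.df == 1
        assert not res.degenerate

    def test_equal_proportions_give_zero(self):
        ds = table_dataset(5, 5, 5, 5)
        res = atom_association_test(ds, GenotypeAtom(0, 0))
        assert res.statistic == 0.0
        assert res.p == pytest.approx(1.0)

    @pytest.mark.parametrize("table", [(10, 0, 0, 10), (7, 3, 2, 8), (1, 9, 5, 5)])
    def test_z_squared_equals_chi_square(self, table):
        ds = table_dataset(*table)
        chi = atom_association_test(ds, GenotypeAtom(0, 0))
        z = atom_association_test(ds, GenotypeAtom(0, 0), method="z")
        assert z.statistic**2 == pytest.approx(chi.statistic)
        assert z.p == pytest.approx(chi.p)

    def test_z_sign_tracks_patient_excess(self):
        assert atom_association_test(
            table_dataset(8, 2, 2, 8), GenotypeAtom(0, 0), method="z"
        ).statistic > 0
        assert atom_association_test(
            table_dataset(2, 8, 8, 2), GenotypeAtom(0, 0), method="z"
        ).statistic < 0

    def test_degenerate_margin_flagged(self):
        ds = table_dataset(10, 0, 10, 0)  # everyone a carrier
        res = atom_association_test(ds, GenotypeAtom(0, 0))
        assert res.degenerate and res.p == 1.0 and res.statistic == 0.0

    def test_unknown_method_rejected(self, d0):
        with pytest.raises(ValidationError):
            atom_association_test(d0, GenotypeAtom(0, 0), method="fisher")

    def test_pvalue_matrix_matches_single_tests(self):
        rng = np.random.default_rng(8)
        ds = random_dataset(rng, max_subjects=30)
        pvals = atom_pvalue_matrix(ds)
        for snp in range(ds.n_snps):
            for code in (0, 1, 2):
                single = atom_association_test(ds, GenotypeAtom(snp, code))
                assert pvals[snp, code] == pytest.approx(single.p)


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_hand_computed_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_hand_computed_mixed_vector(self):
        # ascending p: 0.005, 0.011, 0.02, 0.04 with m=4:
        # p*m/j = 0.02, 0.022, 0.0267, 0.04 -> step-up mins from the right
        got = bh_adjust([0.02, 0.005, 0.04, 0.011])
        assert got == pytest.approx([0.02 * 4 / 3, 0.02, 0.04, 0.022])

    def test_properties_on_random_vectors(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            p = rng.random(int(rng.integers(1, 40)))
            q = bh_adjust(p)
            assert np.all(q >= p)
            assert np.all(q <= 1)
            order = np.argsort(p)
            assert np.all(np.diff(q[order]) >= -1e-12)
            # re-adjusting never decreases
            assert np.all(bh_adjust(q) >= q - 1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])

    def test_empty_input(self):
        assert bh_adjust([]).size == 0


def planted_small_study(seed=1):
    spec = SimulationSpec(
        n_patients=5, n_controls=7, n_snps=8, seed=seed,
        planted_clusters=(
            PlantSpec(anchor=GenotypeAtom(0, 1), n_members=3, k=2, patients_per_member=3),
        ),
    )
    ds, _ = generate_study(spec)
    return ds


class TestPermutationTest:
    RULE = AnchorRule(GenotypeAtom(0, 1))
    CFG = ScanConfig(max_k=2)

    def test_rule_matching_nothing_gives_p_one(self, d0):
        res = cluster_permutation_test(
            d0, AnchorRule(GenotypeAtom(2, 1)), ScanConfig(max_k=3), B=20, seed=0
        )
        assert res.observed == 0
        assert res.p == 1.0

    def test_p_is_count_over_B(self):
        ds = planted_small_study()
        res = cluster_permutation_test(ds, self.RULE, self.CFG, B=97, seed=4)
        assert res.p == res.count_ge / res.B
        assert res.B == 97

    def test_plus_one_convention(self):
        ds = planted_small_study()
        res = cluster_permutation_test(
            ds, self.RULE, self.CFG, B=50, seed=4, plus_one=True
        )
        assert res.p == (res.count_ge + 1) / (res.B + 1)
        assert res.p > 0

    def test_seed_determinism(self):
        ds = planted_small_study()
        a = cluster_permutation_test(ds, self.RULE, self.CFG, B=60, seed=12)
        b = cluster_permutation_test(ds, self.RULE, self.CFG, B=60, seed=12)
        assert a == b

    def test_sampled_converges_to_exhaustive(self):
        ds = planted_small_study(seed=1)
        exact = cluster_permutation_test(ds, self.RULE, self.CFG, exhaustive=True)
        assert 0 < exact.p < 1  # fixture chosen to be non-degenerate
        sampled = cluster_permutation_test(ds, self.RULE, self.CFG, B=4000, seed=9)
        tol = 2 * np.sqrt(exact.p * (1 - exact.p) / 4000)
        assert abs(sampled.p - exact.p) <= max(tol, 2 / 4000)

    def test_exhaustive_includes_true_labeling(self):
        ds = planted_small_study()
        exact = cluster_permutation_test(ds, self.RULE, self.CFG, exhaustive=True)
        assert exact.count_ge >= 1  # the identity labeling always ties

    def test_fixed_variant_agrees_in_sign(self):
        # fixed freezes the member list; on a strongly planted dataset both
        # variants call the cluster significant
        spec = SimulationSpec(
            n_patients=30, n_controls=60, n_snps=30, seed=3,
            planted_clusters=(
                PlantSpec(anchor=GenotypeAtom(0, 1), n_members=5, k=2,
                          patients_per_member=4),
            ),
        )
        ds, _ = generate_study(spec)
        cfg = ScanConfig(max_k=2, min_patient_support=3)
        fixed = cluster_permutation_test(
            ds, self.RULE, cfg, B=100, seed=0, variant="fixed"
        )
        rederived = cluster_permutation_test(
            ds, self.RULE, cfg, B=100, seed=0, variant="rederive"
        )
        assert fixed.observed == rederived.observed
        assert fixed.p <= 0.05 and rederived.p <= 0.05

    def test_rederive_budget_refusal_advises_fixed(self):
        ds = planted_small_study()
        with pytest.raises(BudgetError, match="fixed"):
            cluster_permutation_test(
                ds, self.RULE, self.CFG, B=1000, seed=0, rederive_budget=10
            )

    def test_null_stats_retained_on_request(self):
        ds = planted_small_study()
        res = cluster_permutation_test(
            ds, self.RULE, self.CFG, B=25, seed=1, keep_null=True
        )
        assert len(res.null_stats) == 25
        assert res.count_ge == sum(s >= res.observed for s in res.null_stats)

    def test_degenerate_labels_rejected(self):
        ds = GenotypeDataset(
            ["a", "b"], [True, True], ["x"], np.array([[0], [1]])
        )
        with pytest.raises(ValidationError):
            cluster_permutation_test(ds, self.RULE, self.CFG, B=5)
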