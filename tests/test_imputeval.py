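"""imputeval: metrics, masking, the nearest-haplotype imputer, R²-by-AF."""

import numpy as np
import pytest

from hdgbs.imputeval import (
    AFBinning,
    MaskRecord,
    allele_frequency,
    depth_distribution,
    imputation_accuracy,
    impute_nearest_haplotype,
    impute_panel_af,
    mask_to_platform,
    missingness,
    platform_report,
    read_mask_tsv,
    write_mask_tsv,
)
from hdgbs.io_formats import MISSING, GenotypeMatrix, HaplotypePanel, Variant
from hdgbs.synthdata import PanelSimConfig, simulate_panel


def matrix_of(dosage, depth=None):
    dosage = np.asarray(dosage, dtype=np.int8)
    return GenotypeMatrix(
        [f"S{i}" for i in range(dosage.shape[0])],
        [Variant("1", 10 * (j + 1), "A", "C") for j in range(dosage.shape[1])],
        dosage,
        depth,
    )


def split_panel(config, n_reference):
    """Simulate one population; first haplotypes form the reference panel,
    the remaining pairs form the study samples with known truth."""
    panel, truth = simulate_panel(config)
    reference = HaplotypePanel(
        panel.haplotype_ids[:n_reference],
        panel.alleles[:n_reference],
        panel.variants,
    )
    study = GenotypeMatrix(
        truth.sample_ids[n_reference // 2 :],
        truth.variants,
        truth.dosage[n_reference // 2 :],
    )
    return reference, study


class TestBasicMetrics:
    def test_missingness(self):
        assert missingness(matrix_of([[0, MISSING], [1, 2]])) == 0.25
        assert missingness(matrix_of([[0, 1], [1, 2]])) == 0.0
        assert missingness(matrix_of([[MISSING, MISSING]])) == 1.0

    def test_missingness_empty_matrix(self):
        with pytest.raises(ValueError, match="empty"):
            missingness(matrix_of(np.zeros((0, 0))))

    def test_depth_distribution_fraction(self):
        m = matrix_of([[0, 1, 2, 1]], depth=[[1, 6, 10, 3]])
        fractions, per_variant = depth_distribution(m, [5])
        assert fractions[5] == 0.5
        assert per_variant.tolist() == [1, 6, 10, 3]

    def test_depth_distribution_threshold_zero_and_empty(self):
        m = matrix_of([[0, 1]], depth=[[4, 2]])
        fractions, _ = depth_distribution(m, [0])
        assert fractions[0] == 1.0
        assert depth_distribution(m, [])[0] == {}

    def test_depth_distribution_excludes_missing_calls(self):
        m = matrix_of([[0, MISSING]], depth=[[9, 9]])
        fractions, _ = depth_distribution(m, [5])
        assert fractions[5] == 1.0  # only the called genotype counts

    def test_depth_distribution_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        m = matrix_of(
            rng.choice([0, 1, 2], size=(5, 30)), depth=rng.integers(0, 15, (5, 30))
        )
        fractions, _ = depth_distribution(m, list(range(12)))
        vals = [fractions[k] for k in range(12)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_depth_required(self):
        with pytest.raises(ValueError, match="depth"):
            depth_distribution(matrix_of([[0]]), [1])

    def test_allele_frequency(self):
        af = allele_frequency(matrix_of([[0], [1], [2]]))
        assert af.tolist() == [0.5]
        af = allele_frequency(matrix_of([[0], [0], [MISSING]]))
        assert af.tolist() == [0.0]
        assert np.isnan(allele_frequency(matrix_of([[MISSING], [MISSING]]))[0])

    def test_panel_allele_frequency(self):
        panel = HaplotypePanel(
            ["a", "b", "c", "d"],
            np.array([[0], [0], [1], [1]]),
            [Variant("1", 1, "A", "C")],
        )
        assert allele_frequency(panel).tolist() == [0.5]


class TestAFBinning:
    def test_default_edges_and_assignment(self):
        bins = AFBinning()
        assert bins.n_bins == 10
        idx = bins.assign(np.array([0.0, 0.05, 0.1, 0.95, 1.0, np.nan]))
        assert idx.tolist() == [0, 0, 1, 9, 9, -1]

    def test_invalid_edges(self):
        with pytest.raises(ValueError):
            AFBinning((0.0, 0.5, 0.5, 1.0))
        with pytest.raises(ValueError):
            AFBinning((0.1, 1.0))

    def test_width_constructor(self):
        assert AFBinning.with_width(0.25).n_bins == 4


class TestMasking:
    def test_keep_all_is_identity(self):
        truth = matrix_of([[0, 1, 2], [2, 1, 0]])
        typed, record = mask_to_platform(truth, 3)
        assert typed == truth
        assert record.masked_indices.size == 0

    def test_deterministic_and_recoverable(self):
        rng = np.random.default_rng(1)
        truth = matrix_of(rng.choice([0, 1, 2], size=(4, 100)))
        typed1, rec1 = mask_to_platform(truth, 50, seed=7)
        typed2, rec2 = mask_to_platform(truth, 50, seed=7)
        assert typed1 == typed2
        assert np.array_equal(rec1.kept_indices, rec2.kept_indices)
        assert (typed1.dosage[:, rec1.masked_indices] == MISSING).all()
        assert np.array_equal(
            rec1.true_dosages(truth), truth.dosage[:, rec1.masked_indices]
        )

    def test_explicit_list_and_errors(self):
        truth = matrix_of([[0, 1, 2, 1]])
        typed, rec = mask_to_platform(truth, [0, 2])
        assert rec.kept_indices.tolist() == [0, 2]
        assert typed.dosage[0].tolist() == [0, MISSING, 2, MISSING]
        with pytest.raises(ValueError):
            mask_to_platform(truth, 0)
        with pytest.raises(ValueError):
            mask_to_platform(truth, [9])

    def test_masking_never_decreases_missingness(self):
        rng = np.random.default_rng(3)
        truth = matrix_of(rng.choice([0, 1, 2, MISSING], size=(5, 60)))
        for k in (10, 30, 60):
            typed, _ = mask_to_platform(truth, k, seed=0)
            if k == truth.n_variants:
                assert missingness(typed) == missingness(truth)
            else:
                assert missingness(typed) > missingness(truth)

    def test_mask_tsv_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        truth = matrix_of(rng.choice([0, 1, 2], size=(3, 40)))
        _, rec = mask_to_platform(truth, 15, seed=2)
        p = tmp_path / "mask.tsv"
        write_mask_tsv(rec, truth, p)
        back = read_mask_tsv(p, truth)
        assert np.array_equal(back.masked_indices, rec.masked_indices)
        assert np.array_equal(back.kept_indices, rec.kept_indices)


class TestImputationAccuracy:
    def _setup(self, truth_dosage, imputed_dosage, af=0.45):
        truth = matrix_of(np.asarray(truth_dosage).reshape(-1, 1).repeat(1, 1))
        # single masked variant, af placed mid-bin via an explicit tiny panel
        n = len(truth_dosage)
        alleles = np.zeros((20, 1), dtype=np.uint8)
        alleles[: int(round(af * 20))] = 1
        panel = HaplotypePanel(
            [f"h{i}" for i in range(20)], alleles, truth.variants
        )
        record = MaskRecord(np.array([], dtype=int), np.array([0]), 1)
        imputed = np.asarray(imputed_dosage, dtype=float).reshape(-1, 1)
        return truth, imputed, record, panel

    def test_hand_computed_pearson(self):
        """truth [0,1,2,1] vs imputed [0,1,1,1]: independent direct computation.

        cov = 0.25, var_t = 0.5, var_i = 0.1875 -> R² = 0.0625/0.09375 = 2/3.
        """
        t = [0, 1, 2, 1]
        x = [0, 1, 1, 1]
        mt, mx = sum(t) / 4, sum(x) / 4
        cov = sum((a - mt) * (b - mx) for a, b in zip(t, x)) / 4
        var_t = sum((a - mt) ** 2 for a in t) / 4
        var_x = sum((b - mx) ** 2 for b in x) / 4
        expected = cov**2 / (var_t * var_x)
        assert expected == pytest.approx(2 / 3)

        truth, imputed, record, panel = self._setup(t, x)
        report = imputation_accuracy(imputed, truth, record, panel)
        assert report.overall_r2 == pytest.approx(expected)

    def test_perfect_imputation(self):
        truth, imputed, record, panel = self._setup([0, 1, 2, 1], [0, 1, 2, 1])
        report = imputation_accuracy(imputed, truth, record, panel)
        assert report.overall_r2 == pytest.approx(1.0)
        populated = report.table.dropna(subset=["r2"])
        assert np.allclose(populated.r2, 1.0)

    def test_constant_imputation_flagged_undefined(self):
        truth, imputed, record, panel = self._setup([0, 1, 2, 1], [1, 1, 1, 1])
        report = imputation_accuracy(imputed, truth, record, panel)
        assert np.isnan(report.overall_r2)

    def test_no_masked_entries_is_error(self):
        truth, imputed, _, panel = self._setup([0, 1], [0, 1])
        empty = MaskRecord(np.array([0]), np.array([], dtype=int), 1)
        with pytest.raises(ValueError, match="masked"):
            imputation_accuracy(imputed, truth, empty, panel)

    def test_global_label_swap_invariance_pooled(self):
        rng = np.random.default_rng(2)
        truth = matrix_of(rng.choice([0, 1, 2], size=(10, 30)))
        imputed = rng.choice([0, 1, 2], size=(10, 30)).astype(float)
        panel = HaplotypePanel(
            [f"h{i}" for i in range(8)],
            rng.integers(0, 2, (8, 30)),
            truth.variants,
        )
        record = MaskRecord(np.array([], dtype=int), np.arange(30), 30)
        r = imputation_accuracy(imputed, truth, record, panel).overall_r2
        flipped_truth = matrix_of(2 - truth.dosage)
        flipped_panel = HaplotypePanel(
            panel.haplotype_ids, 1 - panel.alleles, panel.variants
        )
        r_flip = imputation_accuracy(
            2 - imputed, flipped_truth, record, flipped_panel
        ).overall_r2
        assert r == pytest.approx(r_flip)

    def test_single_variant_label_swap_invariance_per_variant(self):
        rng = np.random.default_rng(6)
        truth_d = rng.choice([0, 1, 2], size=(12, 10))
        imputed = rng.choice([0, 1, 2], size=(12, 10)).astype(float)
        panel_a = rng.integers(0, 2, (8, 10))
        record = MaskRecord(np.array([], dtype=int), np.arange(10), 10)

        def score(td, im, pa):
            return imputation_accuracy(
                im, matrix_of(td), record,
                HaplotypePanel([f"h{i}" for i in range(8)], pa, matrix_of(td).variants),
                mode="per_variant",
            ).overall_r2

        base = score(truth_d, imputed, panel_a)
        td, im, pa = truth_d.copy(), imputed.copy(), panel_a.copy()
        td[:, 4] = 2 - td[:, 4]
        im[:, 4] = 2 - im[:, 4]
        pa[:, 4] = 1 - pa[:, 4]
        assert score(td, im, pa) == pytest.approx(base)


class TestImputer:
    def test_exact_recovery_when_target_in_panel(self):
        """Zero recombination/error with targets present in the panel -> R² = 1."""
        cfg = PanelSimConfig(
            n_founders=12, n_haplotypes=80, n_variants=300,
            recombinations_per_haplotype=0.0, genotyping_error=0.0, seed=21,
        )
        panel, truth = simulate_panel(cfg)
        typed, record = mask_to_platform(truth, truth.n_variants // 2, seed=3)
        imputed = impute_nearest_haplotype(typed, panel, flank=10**6)
        report = imputation_accuracy(imputed, truth, record, panel)
        assert report.overall_r2 == pytest.approx(1.0)
        assert np.array_equal(imputed.dosage, truth.dosage)

    def test_flank_larger_than_variant_count(self):
        cfg = PanelSimConfig(n_founders=5, n_haplotypes=20, n_variants=30, seed=2)
        panel, truth = simulate_panel(cfg)
        typed, record = mask_to_platform(truth, 15, seed=0)
        a = impute_nearest_haplotype(typed, panel, flank=10**9)
        b = impute_nearest_haplotype(typed, panel, flank=30)
        assert a == b
        assert not a.missing_mask.any()

    def test_beats_panel_af_baseline(self):
        """Nearest-haplotype copying must beat the haplotype-blind AF baseline."""
        wins = 0
        for seed in range(10):
            cfg = PanelSimConfig(
                n_founders=20, n_haplotypes=120, n_variants=300,
                recombinations_per_haplotype=2.0, genotyping_error=0.01, seed=seed,
            )
            reference, study = split_panel(cfg, 80)
            typed, record = mask_to_platform(study, 150, seed=seed)
            hap = impute_nearest_haplotype(typed, reference, flank=10)
            base = impute_panel_af(typed, reference)
            r_hap = imputation_accuracy(hap, study, record, reference).overall_r2
            r_base = imputation_accuracy(base, study, record, reference).overall_r2
            wins += r_hap > r_base
        assert wins == 10

    def test_no_typed_variants_falls_back_to_major_allele(self):
        panel = HaplotypePanel(
            ["a", "b", "c", "d"],
            np.array([[1, 0], [1, 0], [1, 0], [0, 0]]),
            [Variant("1", 1, "A", "C"), Variant("1", 2, "A", "C")],
        )
        typed = matrix_of([[MISSING, MISSING]])
        imputed = impute_nearest_haplotype(typed, panel)
        assert imputed.dosage[0].tolist() == [2, 0]  # AF .75 -> 2, AF 0 -> 0

    def test_variant_list_mismatch_rejected(self):
        panel = HaplotypePanel(["a"], np.array([[0]]), [Variant("1", 1, "A", "C")])
        with pytest.raises(ValueError, match="variant list"):
            impute_nearest_haplotype(matrix_of([[0, 1]]), panel)


class TestPlatformReport:
    def _scenario(self, label, cfg_seed, kept, reference, study):
        typed, record = mask_to_platform(study, kept, seed=99)
        imputed = impute_nearest_haplotype(typed, reference, flank=10)
        return (label, typed, imputed, record, None)

    def test_single_scenario_row_and_columns(self):
        cfg = PanelSimConfig(n_founders=10, n_haplotypes=60, n_variants=120, seed=5)
        reference, study = split_panel(cfg, 40)
        table = platform_report(
            [self._scenario("HD", 5, 60, reference, study)], study, reference
        )
        assert len(table) == 1
        assert table.loc[0, "label"] == "HD"
        assert table.loc[0, "n_variants"] == 60
        assert 0 <= table.loc[0, "overall_r2"] <= 1

    def test_duplicate_labels_rejected(self):
        cfg = PanelSimConfig(n_founders=10, n_haplotypes=60, n_variants=120, seed=5)
        reference, study = split_panel(cfg, 40)
        s = self._scenario("X", 5, 60, reference, study)
        with pytest.raises(ValueError, match="duplicate"):
            platform_report([s, s], study, reference)

    def test_cost_column_matches_design_model(self):
        from hdgbs.design import CostModel, cost_per_sample

        cfg = PanelSimConfig(n_founders=10, n_haplotypes=60, n_variants=120, seed=5)
        reference, study = split_panel(cfg, 40)
        label, typed, imputed, record, _ = self._scenario("HD", 5, 60, reference, study)
        cost = CostModel(2000, 5, 96)
        table = platform_report([(label, typed, imputed, record, cost)], study, reference)
        assert table.loc[0, "cost_per_sample"] == cost_per_sample(cost)
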