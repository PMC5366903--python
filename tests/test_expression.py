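"""Gene classification by CNVR overlap, median-expression contrasts,
median-of-ratios normalisation and carrier z-score analysis."""

import numpy as np
import pandas as pd
import pytest

from conftest import iv
from placnv.cnvr import Cnvr
from placnv.expression import (
    ExpressionMatrix,
    GeneAnnot,
    bcv_bandwidth,
    classify_genes,
    compare_median_expression,
    normalize_counts,
    size_factors,
    zscore_carrier_compare,
    zscore_carrier_scan,
)

K = 1_000


def region(start, end, cnv_type="del", chrom="1", rid="r"):
    return Cnvr(rid, cnv_type, iv(start, end, chrom), ())


def gene(gid, start, end, chrom="1"):
    return GeneAnnot(gid, iv(start, end, chrom))


class TestClassifyGenes:
    def test_classes_follow_overlap(self):
        genes = [
            gene("g_del", 0, 10 * K),
            gene("g_dup", 100 * K, 110 * K),
            gene("g_both", 200 * K, 210 * K),
            gene("g_none", 900 * K, 910 * K),
        ]
        cnvrs = [
            region(5 * K, 50 * K, "del"),
            region(105 * K, 150 * K, "dup"),
            region(200 * K, 205 * K, "del"),
            region(206 * K, 209 * K, "dup"),
        ]
        got = {c.gene_id: c.cnv_class for c in classify_genes(genes, cnvrs)}
        assert got == {
            "g_del": "del_only",
            "g_dup": "dup_only",
            "g_both": "both",
            "g_none": "non_cnv",
        }

    def test_partition_and_brute_force_equivalence(self, rng):
        genes = [
            gene(f"g{i}", int(s), int(s) + int(l))
            for i, (s, l) in enumerate(
                zip(rng.integers(0, 5_000 * K, 300), rng.integers(1 * K, 50 * K, 300))
            )
        ]
        cnvrs = [
            region(
                int(s),
                int(s) + int(l),
                ("del", "dup")[rng.integers(0, 2)],
                rid=f"r{i}",
            )
            for i, (s, l) in enumerate(
                zip(rng.integers(0, 5_000 * K, 60), rng.integers(10 * K, 200 * K, 60))
            )
        ]
        classes = classify_genes(genes, cnvrs)
        assert len(classes) == len(genes)  # partition: one class per gene
        for g, c in zip(genes, classes):
            hit = {
                r.cnv_type
                for r in cnvrs
                if r.span.chrom == g.interval.chrom
                and r.span.start_bp < g.interval.end_bp
                and g.interval.start_bp < r.span.end_bp
            }
            expected = {
                frozenset(): "non_cnv",
                frozenset({"del"}): "del_only",
                frozenset({"dup"}): "dup_only",
                frozenset({"del", "dup"}): "both",
            }[frozenset(hit)]
            assert c.cnv_class == expected


class TestCompareMedianExpression:
    def test_identical_distributions(self, rng):
        x = rng.lognormal(0, 1, 200)
        r = compare_median_expression(x, x)
        assert r.fold == pytest.approx(1.0)
        assert r.p_value == pytest.approx(1.0)

    def test_shifted_class_has_elevated_fold_and_small_p(self, rng):
        base = rng.lognormal(0, 0.5, 500)
        r = compare_median_expression(base * 3, base)
        assert r.fold == pytest.approx(3.0, rel=1e-9)
        assert r.p_value < 1e-10

    def test_zero_reference_median_reports_undefined_fold(self):
        r = compare_median_expression([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        assert r.fold is None

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            compare_median_expression([], [1.0])


def matrix(data, columns, layer="raw_counts"):
    genes = [f"g{i}" for i in range(len(data))]
    return ExpressionMatrix(pd.DataFrame(data, index=genes, columns=columns), layer)


class TestSizeFactors:
    def test_doubled_sample_gets_sqrt2_factors(self):
        m = matrix([[10, 20], [100, 200], [7, 14]], ["s1", "s2"])
        sf = size_factors(m)
        assert sf["s1"] == pytest.approx(1 / np.sqrt(2))
        assert sf["s2"] == pytest.approx(np.sqrt(2))

    def test_identical_samples_get_unit_factors(self):
        m = matrix([[5, 5, 5], [80, 80, 80]], ["a", "b", "c"])
        assert size_factors(m).tolist() == pytest.approx([1.0, 1.0, 1.0])

    def test_hand_computed_three_gene_example(self):
        # per-gene geometric means: sqrt(4*9)=6, sqrt(10*40)=20, sqrt(1*4)=2
        # ratios s1: 4/6, 10/20, 1/2 -> median 0.5; s2: 1.5, 2, 2 -> median 2
        m = matrix([[4, 9], [10, 40], [1, 4]], ["s1", "s2"])
        sf = size_factors(m)
        assert sf["s1"] == pytest.approx(0.5)
        assert sf["s2"] == pytest.approx(2.0)

    def test_genes_with_zeros_are_excluded(self):
        m = matrix([[0, 100], [10, 10]], ["s1", "s2"])
        assert size_factors(m).tolist() == pytest.approx([1.0, 1.0])

    def test_all_zero_matrix_rejected(self):
        m = matrix([[0, 1], [2, 0]], ["s1", "s2"])
        with pytest.raises(ValueError):
            size_factors(m)

    def test_scale_equivariance(self, rng):
        counts = rng.integers(1, 1000, size=(50, 4))
        m = matrix(counts, list("abcd"))
        scaled = counts.astype(float).copy()
        scaled[:, 2] *= 5  # all-nonzero gene set unchanged
        m2 = matrix(scaled, list("abcd"))
        sf, sf2 = size_factors(m), size_factors(m2)
        # geometric mean also scales, so every sample's factor moves by 5^(1/4)
        assert sf2["c"] / sf["c"] == pytest.approx(5 / 5 ** (1 / 4))
        assert sf2["a"] / sf["a"] == pytest.approx(1 / 5 ** (1 / 4))

    def test_normalize_counts_divides_by_factors(self):
        m = matrix([[10, 20], [100, 200], [7, 14]], ["s1", "s2"])
        norm = normalize_counts(m)
        assert norm.layer == "normalized_counts"
        pd.testing.assert_series_equal(
            norm.values["s1"] * size_factors(m)["s1"],
            m.values["s1"].astype(float),
            check_names=False,
        )


class TestZscoreCarrierCompare:
    def _matrix(self, rng, n_samples=40):
        cols = [f"s{i}" for i in range(n_samples)]
        data = rng.lognormal(3, 0.3, size=(5, n_samples))
        return ExpressionMatrix(
            pd.DataFrame(data, index=[f"g{i}" for i in range(5)], columns=cols),
            "normalized_counts",
        )

    def test_constant_gene_skipped(self):
        m = ExpressionMatrix(
            pd.DataFrame({"s1": [5.0], "s2": [5.0], "s3": [5.0]}, index=["g0"]),
            "normalized_counts",
        )
        res = zscore_carrier_compare(m, "g0", {"s1"}, {"s2", "s3"})
        assert res.skip_reason == "zero_variance"

    def test_empty_group_skipped_with_reason(self, rng):
        m = self._matrix(rng)
        assert zscore_carrier_compare(m, "g0", set(), {"s1"}).skip_reason == "no_carriers"
        assert (
            zscore_carrier_compare(m, "g0", {"s1"}, set()).skip_reason
            == "no_noncarriers"
        )

    def test_shifted_carriers_detected(self, rng):
        m = self._matrix(rng)
        carriers = {f"s{i}" for i in range(10)}
        noncarriers = set(m.sample_ids) - carriers
        m.values.loc["g1", sorted(carriers)] *= 10
        res = zscore_carrier_compare(m, "g1", carriers, noncarriers)
        assert res.p_value < 1e-4
        assert res.carrier_mean_z > 0

    def test_null_permutation_is_calibrated(self, rng):
        """Carriers drawn at random from the same distribution: p-values are
        not systematically small and mean carrier z stays near 0."""
        pvals, zbar = [], []
        for _ in range(50):
            m = self._matrix(rng)
            carriers = set(rng.choice(m.sample_ids, 15, replace=False))
            res = zscore_carrier_compare(
                m, "g0", carriers, set(m.sample_ids) - carriers
            )
            pvals.append(res.p_value)
            zbar.append(res.carrier_mean_z)
        assert np.mean([p < 0.05 for p in pvals]) <= 0.2
        assert abs(np.mean(zbar)) < 0.2

    def test_scan_pooled_mode(self, rng):
        m = self._matrix(rng)
        carriers = {f"s{i}" for i in range(8)}
        for g in ("g0", "g1"):
            m.values.loc[g, sorted(carriers)] *= 8
        out = zscore_carrier_scan(m, {"g0": carriers, "g1": carriers}, mode="pooled")
        assert out["n_tested"] == 2
        assert out["pooled_p"] < 1e-6
        assert out["pooled_carrier_mean_z"] > 0


def test_del_prone_fold_recovered_from_synthetic_cohort():
    """Generator-level recovery: deletion-prone genes simulated at a 3-fold
    elevated baseline give a del-only vs non-CNV median-FPKM fold within
    +/-15% of the construction."""
    from placnv.simulate import (
        GroupConfig,
        SimConfig,
        default_chromosomes,
        generate_cohort,
        generate_expression,
        generate_genes,
    )
    from placnv.simulate import CallerConfig, ExpressionConfig

    config = SimConfig(
        seed=2024,
        chromosomes=tuple(default_chromosomes()),
        groups=(
            GroupConfig(
                name="control_term",
                n_placentas=20,
                mean_cnvs_placenta=30.0,
                dup_fraction_placenta=0.0,  # deletions only: clean del-prone set
                shared_prob=0.0,
            ),
        ),
        callers=(CallerConfig("A"),),
        expression=ExpressionConfig(
            n_genes=2000, del_prone_fold=3.0, dosage_effect=False
        ),
        cnv_length_median_bp=400_000.0,  # long CNVs so many genes are del-prone
    )
    truth, meta, _ = generate_cohort(config)
    genes = generate_genes(config)
    sim = generate_expression(truth, genes, config)
    medians = sim.fpkm.gene_medians()
    del_prone = sorted(sim.del_prone_genes)
    assert len(del_prone) > 100
    background = [g.gene_id for g in genes if g.gene_id not in sim.del_prone_genes]
    r = compare_median_expression(
        medians[del_prone].tolist(), medians[background].tolist()
    )
    assert r.fold == pytest.approx(3.0, rel=0.15)


def test_bcv_bandwidth_reasonable_on_gaussian(rng):
    x = rng.normal(0, 1, 300)
    h = bcv_bandwidth(x)
    assert 0.05 < h < 1.5
    assert np.isfinite(h)
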