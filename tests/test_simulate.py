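"""Properties of the synthetic cohort generator and caller emulation."""

import numpy as np
import pytest

from placnv.consensus import build_consensus
from placnv.simulate import (
    CallerConfig,
    ExpressionConfig,
    GroupConfig,
    SimConfig,
    default_chromosomes,
    default_config,
    emulate_callers,
    generate_cohort,
    generate_expression,
    generate_genes,
)


def single_group_config(seed, n_samples, mean, callers=None, **kwargs):
    return SimConfig(
        seed=seed,
        chromosomes=tuple(default_chromosomes()),
        groups=(
            GroupConfig(
                name="control_term",
                n_placentas=n_samples,
                mean_cnvs_placenta=mean,
                dup_fraction_placenta=0.4,
                shared_prob=kwargs.pop("shared_prob", 0.3),
            ),
        ),
        callers=callers or (CallerConfig("A"), CallerConfig("B"), CallerConfig("C")),
        **kwargs,
    )


def perfect_callers(n=3):
    return tuple(
        CallerConfig(f"c{i}", detection_prob=1.0, jitter_sd_bp=0.0, fp_rate=0.0)
        for i in range(n)
    )


class TestGenerateCohort:
    def test_same_seed_is_byte_identical(self):
        c1 = generate_cohort(default_config(42))
        c2 = generate_cohort(default_config(42))
        assert c1.truth == c2.truth
        assert c1.meta == c2.meta
        e1 = emulate_callers(c1.truth, default_config(42))
        e2 = emulate_callers(c2.truth, default_config(42))
        assert e1 == e2

    def test_different_seeds_differ(self):
        assert generate_cohort(default_config(1)).truth != generate_cohort(
            default_config(2)
        ).truth

    def test_poisson_mean_recovered_at_large_n(self):
        config = single_group_config(7, 1000, 15.0)
        truth, meta, _ = generate_cohort(config)
        counts = [len(truth.for_sample(m.sample_id)) for m in meta]
        se = np.sqrt(15.0 / 1000)
        assert abs(np.mean(counts) - 15.0) <= 3 * se

    def test_zero_shared_probability_gives_private_cnvs_only(self):
        config = single_group_config(5, 30, 12.0, shared_prob=0.0)
        truth, _, _ = generate_cohort(config)
        assert all(c.origin == "private" for c in truth.cnvs)

    def test_same_type_cnvs_never_overlap_within_a_sample(self):
        truth, meta, _ = generate_cohort(default_config(3))
        for m in meta:
            cnvs = truth.for_sample(m.sample_id)
            for i, a in enumerate(cnvs):
                for b in cnvs[i + 1 :]:
                    if a.cnv_type == b.cnv_type and a.interval.chrom == b.interval.chrom:
                        assert (
                            a.interval.end_bp <= b.interval.start_bp
                            or b.interval.end_bp <= a.interval.start_bp
                        )

    def test_family_structure_and_inheritance_labels(self):
        truth, meta, _ = generate_cohort(default_config(11))
        by_family: dict = {}
        for m in meta:
            by_family.setdefault(m.family_id, []).append(m)
        roles_of = {m.sample_id: m.role for m in meta}
        for c in truth.cnvs:
            if c.inherited_from is not None:
                assert roles_of[c.sample_id] == "placenta"
                fam = next(m.family_id for m in meta if m.sample_id == c.sample_id)
                parent_roles = {m.role for m in by_family[fam]}
                assert c.inherited_from in parent_roles
                # the parental origin CNV exists at the same locus
                parent = next(
                    m for m in by_family[fam] if m.role == c.inherited_from
                )
                assert any(
                    p.interval == c.interval and p.cnv_type == c.cnv_type
                    for p in truth.for_sample(parent.sample_id)
                )

    def test_infeasible_minimum_length_rejected(self):
        from placnv.genome import ChromInfo

        with pytest.raises(ValueError):
            SimConfig(
                seed=1,
                chromosomes=(ChromInfo("1", 10_000, 5_000),),
                groups=(GroupConfig("control_term", 2),),
                callers=(CallerConfig("A"),),
                min_cnv_length_bp=20_000,
            )


class TestEmulateCallers:
    def test_noiseless_callers_round_trip_through_consensus(self):
        config = single_group_config(13, 10, 12.0, callers=perfect_callers())
        truth, meta, _ = generate_cohort(config)
        calls = emulate_callers(truth, config)
        for m in meta:
            consensus = build_consensus(
                [c for c in calls if c.sample_id == m.sample_id], m.sample_id
            )
            got = {(c.interval, c.cnv_type) for c in consensus}
            expected = {
                (c.interval, c.cnv_type) for c in truth.for_sample(m.sample_id)
            }
            assert got == expected

    def test_two_of_three_caller_recovery_matches_closed_form(self):
        """Three callers at detection 0.8: P(>=2 detect) = 3 p^2 (1-p) + p^3."""
        callers = tuple(
            CallerConfig(f"c{i}", detection_prob=0.8, jitter_sd_bp=0.0, fp_rate=0.0)
            for i in range(3)
        )
        config = single_group_config(17, 40, 20.0, callers=callers)
        truth, meta, _ = generate_cohort(config)
        calls = emulate_callers(truth, config)
        recovered = 0
        for m in meta:
            consensus = build_consensus(
                [c for c in calls if c.sample_id == m.sample_id], m.sample_id
            )
            spans = {(c.interval, c.cnv_type) for c in consensus}
            recovered += sum(
                1
                for c in truth.for_sample(m.sample_id)
                if (c.interval, c.cnv_type) in spans
            )
        n = len(truth.cnvs)
        expected = 3 * 0.8**2 * 0.2 + 0.8**3
        se = np.sqrt(expected * (1 - expected) / n)
        assert n >= 500
        assert abs(recovered / n - expected) <= 3 * se

    def test_moderate_jitter_does_not_break_recall(self):
        """500 bp endpoint jitter on ~50 kb CNVs leaves reciprocal overlap far
        above 0.4, so consensus recall equals the noiseless case."""
        callers = tuple(
            CallerConfig(f"c{i}", detection_prob=1.0, jitter_sd_bp=500.0, fp_rate=0.0)
            for i in range(3)
        )
        config = single_group_config(
            19, 15, 10.0, callers=callers,
            cnv_length_median_bp=50_000.0, cnv_length_sigma=0.0,
        )
        truth, meta, _ = generate_cohort(config)
        calls = emulate_callers(truth, config)
        total = 0
        for m in meta:
            total += len(
                build_consensus(
                    [c for c in calls if c.sample_id == m.sample_id], m.sample_id
                )
            )
        assert total == len(truth.cnvs)

    def test_recall_and_precision_degrade_with_noise(self):
        """Recovery ladder: recall falls as jitter grows; precision falls as
        the false-positive rate grows."""

        def run(jitter, fp):
            callers = tuple(
                CallerConfig(
                    f"c{i}", detection_prob=1.0, jitter_sd_bp=jitter, fp_rate=fp
                )
                for i in range(3)
            )
            config = single_group_config(
                23, 30, 15.0, callers=callers,
                cnv_length_median_bp=50_000.0, cnv_length_sigma=0.0,
            )
            truth, meta, _ = generate_cohort(config)
            calls = emulate_callers(truth, config)
            tp = fp_count = 0
            for m in meta:
                consensus = build_consensus(
                    [c for c in calls if c.sample_id == m.sample_id], m.sample_id
                )
                true_spans = {
                    (c.interval, c.cnv_type) for c in truth.for_sample(m.sample_id)
                }
                from placnv.genome import reciprocal_overlap

                for c in consensus:
                    if any(
                        t == c.cnv_type and reciprocal_overlap(ti, c.interval) >= 0.4
                        for ti, t in true_spans
                    ):
                        tp += 1
                    else:
                        fp_count += 1
            recall = tp / len(truth.cnvs)
            precision = tp / max(1, tp + fp_count)
            return recall, precision

        r0, _ = run(0.0, 0.0)
        r1, _ = run(20_000.0, 0.0)
        r2, _ = run(60_000.0, 0.0)
        assert r0 >= r1 >= r2
        assert r0 == pytest.approx(1.0)
        _, p0 = run(0.0, 0.0)
        _, p1 = run(0.0, 5.0)
        _, p2 = run(0.0, 20.0)
        assert p0 >= p1 >= p2

    def test_confidence_reported_only_by_configured_caller(self):
        config = default_config(29)
        truth, _, _ = generate_cohort(config)
        calls = emulate_callers(truth, config)
        for c in calls:
            if c.caller_id == "caller_C":
                assert c.confidence is not None
            else:
                assert c.confidence is None


class TestGenerateExpression:
    def test_deterministic_and_independent_of_caller_stage(self):
        config = default_config(31)
        truth, meta, _ = generate_cohort(config)
        genes = generate_genes(config)
        placental = [m.sample_id for m in meta if m.tissue == "placenta"]
        a = generate_expression(truth, genes, config, samples=placental)
        # caller emulation in between must not perturb the expression stream
        emulate_callers(truth, config)
        b = generate_expression(truth, genes, config, samples=placental)
        assert a.raw_counts.values.equals(b.raw_counts.values)
        assert a.fpkm.values.equals(b.fpkm.values)

    def test_null_construction_shows_no_class_effect(self):
        import dataclasses

        config = dataclasses.replace(
            single_group_config(37, 20, 15.0),
            expression=ExpressionConfig(
                n_genes=800, del_prone_fold=1.0, dosage_effect=False
            ),
        )
        truth, meta, _ = generate_cohort(config)
        genes = generate_genes(config)
        sim = generate_expression(truth, genes, config)
        from placnv.expression import compare_median_expression

        # contrast on count medians: length-independent, so the only possible
        # difference between the classes is the (disabled) baseline fold
        medians = sim.raw_counts.gene_medians()
        prone = sorted(sim.del_prone_genes)
        background = [g.gene_id for g in genes if g.gene_id not in sim.del_prone_genes]
        r = compare_median_expression(medians[prone].tolist(), medians[background].tolist())
        assert r.p_value > 0.01
        assert 0.6 < r.fold < 1.6

    def test_dosage_shift_detected_for_deleted_gene(self):
        """0.5x dosage for deletion carriers must surface in the carrier
        z-score contrast with high power (20 vs 20 samples)."""
        from placnv.expression import normalize_counts, zscore_carrier_compare
        from placnv.simulate import truth_carriers

        import dataclasses

        config = dataclasses.replace(
            single_group_config(41, 40, 25.0),
            expression=ExpressionConfig(n_genes=400, del_prone_fold=1.0),
        )
        truth, meta, _ = generate_cohort(config)
        genes = generate_genes(config)
        sim = generate_expression(truth, genes, config)
        carriers = truth_carriers(truth, genes)
        # pick the gene with the most deletion carriers and enough non-carriers
        gene_id, sets = max(
            carriers.items(), key=lambda kv: len(kv[1]["del"] - kv[1]["dup"])
        )
        del_carriers = sets["del"] - sets["dup"]
        noncarriers = set(sim.raw_counts.sample_ids) - sets["del"] - sets["dup"]
        assert len(del_carriers) >= 3
        norm = normalize_counts(sim.raw_counts)
        res = zscore_carrier_compare(norm, gene_id, del_carriers, noncarriers)
        assert res.p_value < 0.05
        assert res.carrier_mean_z < 0
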