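"""Spike-in scaling, flooring rules, totals and replicate QC vs oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from zdecay import (
    SpikeInNormalizer,
    compute_spikein_factors,
    floor_and_filter,
    normalize_expression,
    qc_replicate_correlation,
    total_copy_change,
)
from zdecay.simulate import SimulationParams, generate_mzt_experiment

from conftest import make_matrix


def brute_force_factors(spike: pd.DataFrame) -> pd.Series:
    """Naive re-statement of the definition: median_g(geomean_g / x_gj)."""
    out = {}
    for sample in spike.columns:
        ratios = []
        for gene in spike.index:
            row = [v for v in spike.loc[gene] if v > 0]
            ref = math.exp(sum(math.log(v) for v in row) / len(row))
            x = spike.loc[gene, sample]
            if x > 0:
                ratios.append(ref / x)
        out[sample] = float(np.median(ratios))
    return pd.Series(out)


class TestFlooring:
    def test_gene_below_one_everywhere_is_excluded(self, four_sample_meta):
        m = make_matrix(
            {"gene_a": [0.5, 0.8, 0.2, 0.9], "gene_b": [5, 5, 5, 5], "ERCC-1": [1, 1, 1, 1]},
            four_sample_meta,
        )
        out = floor_and_filter(m)
        assert out.excluded_gene_ids == ["gene_a"]
        assert "gene_a" not in out.values.index

    def test_partial_sub_one_values_floored_to_one(self, four_sample_meta):
        m = make_matrix(
            {"gene_a": [0.5, 3.0, 0.5, 3.0], "ERCC-1": [1, 1, 1, 1]}, four_sample_meta
        )
        out = floor_and_filter(m)
        assert list(out.values.loc["gene_a"]) == [1.0, 3.0, 1.0, 3.0]

    def test_spikeins_exempt_from_both_rules(self, four_sample_meta):
        m = make_matrix(
            {"gene_a": [2, 2, 2, 2], "ERCC-1": [0.3, 0.3, 0.3, 0.3]}, four_sample_meta
        )
        out = floor_and_filter(m)
        assert list(out.values.loc["ERCC-1"]) == [0.3, 0.3, 0.3, 0.3]

    def test_noop_when_all_at_least_one(self, four_sample_meta):
        m = make_matrix({"gene_a": [1, 2, 3, 4], "ERCC-1": [1, 1, 1, 1]}, four_sample_meta)
        out = floor_and_filter(m)
        assert out.excluded_gene_ids == []
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_idempotence(self, small_experiment):
        matrix, _ = small_experiment
        once = floor_and_filter(matrix)
        twice = floor_and_filter(once.matrix)
        pd.testing.assert_frame_equal(once.values, twice.values)
        assert twice.excluded_gene_ids == []


class TestSpikeinFactors:
    def test_identical_spikein_columns_give_unit_factors(self, four_sample_meta):
        m = make_matrix(
            {"gene_a": [1, 2, 3, 4], "ERCC-1": [5, 5, 5, 5], "ERCC-2": [9, 9, 9, 9]},
            four_sample_meta,
        )
        np.testing.assert_allclose(compute_spikein_factors(m), 1.0)

    def test_doubled_sample_gets_half_factor(self, four_sample_meta):
        base = {"ERCC-1": [4.0, 4, 4, 4], "ERCC-2": [10.0, 10, 10, 10], "gene_a": [1, 1, 1, 1]}
        base["ERCC-1"][0] *= 2
        base["ERCC-2"][0] *= 2
        factors = compute_spikein_factors(make_matrix(base, four_sample_meta))
        # the doubled sample is pulled down by 2 relative to the others
        assert factors["z1"] / factors["z2"] == pytest.approx(0.5)

    def test_matches_brute_force_on_random_table(self, rng, four_sample_meta):
        vals = {f"ERCC-{i}": rng.lognormal(1, 1, 4).tolist() for i in range(5)}
        vals["gene_a"] = [1, 2, 3, 4]
        m = make_matrix(vals, four_sample_meta)
        got = compute_spikein_factors(m)
        expected = brute_force_factors(m.spikein_values())
        np.testing.assert_allclose(got, expected.reindex(got.index))

    def test_all_zero_spikeins_in_sample_rejected(self, four_sample_meta):
        m = make_matrix({"ERCC-1": [0, 1, 1, 1], "gene_a": [1, 1, 1, 1]}, four_sample_meta)
        with pytest.raises(ValueError, match="all-zero spike-ins"):
            compute_spikein_factors(m)

    def test_column_scaling_removed_up_to_global_factor(self, small_experiment, rng):
        # per-sample depth distortions are absorbed by the factors: the
        # normalized matrix changes only by one global constant, so every
        # ratio-based downstream quantity is exactly invariant
        matrix, _ = small_experiment
        norm1 = normalize_expression(matrix, floor=False)
        depths = rng.uniform(0.2, 5.0, size=matrix.values.shape[1])
        scaled = matrix.with_values(matrix.values * depths)
        norm2 = normalize_expression(scaled, floor=False)
        ratio = (norm2.values / norm1.values).to_numpy()
        np.testing.assert_allclose(ratio, ratio.flat[0])
        rel1 = total_copy_change(norm1, "zygote", "WT")
        rel2 = total_copy_change(norm2, "zygote", "WT")
        pd.testing.assert_series_equal(rel1, rel2)

    def test_transform_rejects_unfitted_and_unknown_samples(self, small_experiment):
        matrix, _ = small_experiment
        with pytest.raises(ValueError):
            SpikeInNormalizer().transform(matrix)


class TestTotalCopyChange:
    def test_baseline_is_exactly_one(self, small_norm):
        rel = total_copy_change(small_norm, "zygote", "WT")
        assert rel[("zygote", "WT")] == 1.0

    def test_homogeneous_doubling_gives_two(self, four_sample_meta):
        m = make_matrix(
            {"gene_a": [3, 3, 6, 6], "gene_b": [1, 1, 2, 2], "ERCC-1": [1, 1, 1, 1]},
            four_sample_meta,
        )
        rel = total_copy_change(normalize_expression(m, floor=False), "zygote")
        assert rel[("2cell", "WT")] == pytest.approx(2.0)

    def test_kd_exceeds_wt_and_matches_sum_oracle(self):
        # stabilized maternal decay with no activated class: knockdown must
        # accumulate transcripts at the 2-cell stage
        p = SimulationParams(seed=3, n_decay=40, n_zga=0, n_stable=20, n_spikeins=8,
                             noise_sd=0.0, kd_stabilization=2.0)
        matrix, _ = generate_mzt_experiment(p)
        norm = normalize_expression(matrix, floor=False)
        rel = total_copy_change(norm, "zygote", "WT")
        assert rel[("2cell", "KD")] > rel[("2cell", "WT")]
        # sum-and-divide oracle straight off the normalized table
        genes = norm.matrix.gene_values()
        meta = norm.metadata
        def group_total(stage, cond):
            cols = [s for s in genes.columns
                    if meta.loc[s, "stage"] == stage and meta.loc[s, "condition"] == cond]
            return np.mean([genes[c].sum() for c in cols])
        for (stage, cond), value in rel.items():
            assert value == pytest.approx(group_total(stage, cond) / group_total("zygote", "WT"))

    def test_missing_baseline_rejected(self, small_norm):
        with pytest.raises(ValueError, match="absent"):
            total_copy_change(small_norm, "8cell", "WT")

    def test_gene_row_permutation_invariance(self, small_norm):
        import dataclasses
        rel1 = total_copy_change(small_norm, "zygote", "WT")
        shuffled = dataclasses.replace(
            small_norm,
            matrix=small_norm.matrix.with_values(small_norm.values.iloc[::-1]),
        )
        rel2 = total_copy_change(shuffled, "zygote", "WT")
        pd.testing.assert_series_equal(rel1, rel2)


def brute_force_spearman(x, y):
    """Average-rank Spearman via the Pearson formula on ranks."""
    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r
    rx, ry = ranks(list(x)), ranks(list(y))
    mx, my = np.mean(rx), np.mean(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


class TestReplicateQc:
    def test_duplicate_columns_give_unit_correlation(self, four_sample_meta):
        m = make_matrix(
            {"g1": [1, 1, 9, 9], "g2": [4, 4, 2, 2], "g3": [2, 2, 5, 5], "ERCC-1": [1, 1, 1, 1]},
            four_sample_meta,
        )
        report = qc_replicate_correlation(normalize_expression(m, floor=False))
        assert report.correlations[("zygote", "WT")][("z1", "z2")] == pytest.approx(1.0)

    def test_rank_reversal_gives_minus_one(self, four_sample_meta):
        m = make_matrix(
            {"g1": [1, 9, 1, 2], "g2": [5, 5, 2, 3], "g3": [9, 1, 3, 1], "ERCC-1": [1, 1, 1, 1]},
            four_sample_meta,
        )
        report = qc_replicate_correlation(normalize_expression(m, floor=False))
        assert report.correlations[("zygote", "WT")][("z1", "z2")] == pytest.approx(-1.0)

    def test_matches_brute_force_with_ties(self, rng, four_sample_meta):
        vals = {f"g{i}": rng.integers(1, 5, 4).astype(float).tolist() for i in range(10)}
        vals["ERCC-1"] = [1, 1, 1, 1]
        m = make_matrix(vals, four_sample_meta)
        norm = normalize_expression(m, floor=False)
        report = qc_replicate_correlation(norm)
        genes = norm.matrix.gene_values()
        expected = brute_force_spearman(genes["z1"], genes["z2"])
        assert report.correlations[("zygote", "WT")][("z1", "z2")] == pytest.approx(expected)

    def test_single_replicate_group_skipped(self):
        meta = {"z1": ("zygote", "WT", 1), "t1": ("2cell", "WT", 1), "t2": ("2cell", "WT", 2)}
        m = make_matrix({"g1": [1, 2, 3], "g2": [3, 4, 1], "ERCC-1": [1, 1, 1]}, meta)
        report = qc_replicate_correlation(normalize_expression(m, floor=False))
        assert ("zygote", "WT") in report.skipped
        assert ("2cell", "WT") in report.correlations
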