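"""Spike-in normalization, FPKM flooring rules, totals and replicate QC.

Exogenous spike-ins are added at fixed amounts per sample, so after correct
scaling their levels must be equal across samples; endogenous totals then
sit on an absolute (copy-number-proportional) scale.  Scaling uses
median-of-ratios against a geometric-mean spike-in reference: for sample
``j``, ``s_j = median_g(ref_g / x_gj)`` over spike-in species ``g``, where
``ref_g`` is the geometric mean of species ``g`` across samples.  This is
robust to individual spike-in dropout.

Flooring follows the FPKM conventions of embryo transcriptome studies:
genes below 1 FPKM in every sample are excluded; remaining values below 1
are set to 1 so all downstream ratios are finite.  Spike-ins are exempt.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .matrix import ExpressionMatrix, NormalizedExpression

logger = logging.getLogger(__name__)

FLOOR = 1.0  # FPKM floor applied to retained endogenous genes


def compute_spikein_factors(matrix: ExpressionMatrix) -> pd.Series:
    """Per-sample scale factors that equalize spike-in levels across samples.

    Zero spike-in readings are treated as missing for the median rather than
    as infinite ratios.  A sample with more than half its spike-ins missing
    triggers a warning; a sample with no usable spike-in raises.

    Returns
    -------
    pandas.Series
        ``s_j`` indexed by sample; multiplying column ``j`` by ``s_j``
        brings its spike-ins onto the common reference.
    """
    spike = matrix.spikein_values()
    if spike.shape[0] == 0:
        raise ValueError("no spike-in rows; normalization requires at least one")
    vals = spike.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logs = np.where(vals > 0, np.log(np.where(vals > 0, vals, 1.0)), np.nan)
    # geometric mean reference per spike-in over samples where it was observed
    ref = np.exp(np.nanmean(logs, axis=1))
    factors = {}
    for j, sample in enumerate(spike.columns):
        col = vals[:, j]
        usable = col > 0
        if not usable.any():
            raise ValueError(f"sample {sample!r} has all-zero spike-ins; cannot normalize")
        if usable.sum() < 0.5 * len(col):
            warnings.warn(
                f"sample {sample!r}: more than 50% of spike-ins are zero", stacklevel=2
            )
        ratios = ref[usable] / col[usable]
        factors[sample] = float(np.median(ratios))
        logger.debug("spike-in factor for %s: %.6g", sample, factors[sample])
    return pd.Series(factors, name="scale_factor").reindex(matrix.values.columns)


def floor_and_filter(matrix: ExpressionMatrix) -> NormalizedExpression:
    """Apply the FPKM<1 exclusion and flooring rules (no scaling).

    Endogenous genes with abundance < 1 in every sample are removed and
    listed in ``excluded_gene_ids``; remaining endogenous values < 1 are set
    to 1.  Spike-in rows are exempt from both rules.
    """
    values = matrix.values.copy()
    gene_ids = matrix.gene_ids
    genes = values.loc[gene_ids]
    all_below = (genes < FLOOR).all(axis=1)
    excluded = list(genes.index[all_below])
    values = values.drop(index=excluded)
    kept_genes = [g for g in gene_ids if g not in set(excluded)]
    values.loc[kept_genes] = values.loc[kept_genes].clip(lower=FLOOR)
    return NormalizedExpression(
        matrix=matrix.with_values(values),
        scale_factors=pd.Series(1.0, index=values.columns, name="scale_factor"),
        floored=True,
        excluded_gene_ids=excluded,
    )


class SpikeInNormalizer(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer: spike-in scaling, then floor/filter.

    Parameters
    ----------
    floor : bool, default True
        Apply the FPKM<1 exclusion/flooring rules after scaling.

    Attributes
    ----------
    scale_factors_ : pandas.Series
        Fitted per-sample multipliers.
    """

    def __init__(self, floor: bool = True):
        self.floor = floor

    def fit(self, X: ExpressionMatrix, y=None) -> "SpikeInNormalizer":
        self.scale_factors_ = compute_spikein_factors(X)
        return self

    def transform(self, X: ExpressionMatrix) -> NormalizedExpression:
        if not hasattr(self, "scale_factors_"):
            raise ValueError("SpikeInNormalizer is not fitted")
        factors = self.scale_factors_.reindex(X.values.columns)
        if factors.isna().any():
            raise ValueError("matrix contains samples unseen at fit time")
        scaled = X.with_values(X.values.mul(factors, axis=1))
        if self.floor:
            out = floor_and_filter(scaled)
            return dataclasses.replace(out, scale_factors=factors)
        return NormalizedExpression(matrix=scaled, scale_factors=factors, floored=False)


def normalize_expression(matrix: ExpressionMatrix, floor: bool = True) -> NormalizedExpression:
    """Spike-in-normalize and (optionally) floor an FPKM matrix."""
    return SpikeInNormalizer(floor=floor).fit(matrix).transform(matrix)


def total_copy_change(
    norm: NormalizedExpression,
    baseline_stage: str,
    baseline_condition: str | None = None,
) -> pd.Series:
    """Relative total mRNA level per (stage, condition) group.

    The endogenous (non-spike-in) values are summed per sample, averaged
    over replicates within each group, and divided by the baseline group's
    mean total, so the baseline reads exactly 1.0 — the convention used when
    absolute transcriptome output is tracked across stages with the zygote
    set to 1.

    Parameters
    ----------
    baseline_stage : str
        Stage of the baseline group.
    baseline_condition : str, optional
        Condition of the baseline group; if omitted and only one condition
        has the baseline stage, that one is used.
    """
    mat = norm.matrix
    totals = mat.gene_values().sum(axis=0)
    meta = mat.metadata.loc[list(mat.values.columns)]
    group_means = totals.groupby([meta["stage"], meta["condition"]]).mean()
    if baseline_condition is None:
        candidates = [c for (s, c) in group_means.index if s == baseline_stage]
        if not candidates:
            raise ValueError(f"baseline stage {baseline_stage!r} absent")
        if len(set(candidates)) > 1:
            raise ValueError(
                f"baseline stage {baseline_stage!r} present under several conditions; "
                "pass baseline_condition"
            )
        baseline_condition = candidates[0]
    key = (baseline_stage, baseline_condition)
    if key not in group_means.index:
        raise ValueError(f"baseline group {key} absent")
    rel = group_means / group_means.loc[key]
    rel.name = "relative_total"
    return rel


@dataclass
class QcReport:
    """Pairwise replicate Spearman correlations per (stage, condition).

    ``correlations`` maps each group to ``{(sample_i, sample_j): r_s}``;
    groups with fewer than two replicates are listed in ``skipped``.
    """

    correlations: dict = field(default_factory=dict)
    skipped: list = field(default_factory=list)

    def min_correlation(self) -> float:
        vals = [r for pairs in self.correlations.values() for r in pairs.values()]
        return float(min(vals)) if vals else float("nan")

    def to_jsonable(self) -> dict:
        return {
            "correlations": {
                f"{stage}/{cond}": {f"{a} vs {b}": r for (a, b), r in pairs.items()}
                for (stage, cond), pairs in self.correlations.items()
            },
            "skipped": [f"{stage}/{cond}" for stage, cond in self.skipped],
        }


def qc_replicate_correlation(norm: NormalizedExpression) -> QcReport:
    """Spearman rank correlation between replicate pairs of each group.

    Computed on endogenous gene values; ties receive average ranks (the
    standard Spearman convention).  Groups with a single replicate are
    skipped with a logged notice.
    """
    mat = norm.matrix
    genes = mat.gene_values()
    report = QcReport()
    for stage, condition in mat.groups():
        cols = mat.samples(stage=stage, condition=condition)
        if len(cols) < 2:
            logger.info("QC: group (%s, %s) has < 2 replicates; skipped", stage, condition)
            report.skipped.append((stage, condition))
            continue
        pairs = {}
        for a, b in combinations(cols, 2):
            r, _ = stats.spearmanr(genes[a], genes[b])
            pairs[(a, b)] = float(r)
        report.correlations[(stage, condition)] = pairs
    if not report.correlations:
        raise ValueError("no group has >= 2 replicates; QC impossible")
    return report
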