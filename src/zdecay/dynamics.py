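"""Transcript dynamic-class calling and knockdown fold-change summaries.

During the mouse maternal-to-zygotic transition, transcripts fall into
three dynamic classes between the zygote and late 2-cell stage: maternal
transcripts undergoing decay (zygote/2-cell ratio above a fold threshold),
zygotically activated transcripts (2-cell/zygote above the threshold), and
stable transcripts (neither).  Classes are called on replicate-averaged,
floored, spike-in-normalized FPKM, so every ratio is finite.

Boundary convention: a ratio exactly at the threshold is assigned to the
stable class, so the three classes always partition the gene universe
(the strict ``> fold`` rule on both sides leaves equality unassigned).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from sklearn.base import BaseEstimator

from .matrix import NormalizedExpression

MATERNAL_DECAY = "maternal_decay"
ZYGOTIC_ACTIVATED = "zygotic_activated"
STABLE = "stable"
GROUPS = (MATERNAL_DECAY, ZYGOTIC_ACTIVATED, STABLE)


@dataclass
class GeneClassification:
    """Partition of genes into the three dynamic classes.

    Attributes
    ----------
    labels : pandas.Series
        gene_id -> class label.
    ratios : pandas.Series
        gene_id -> replicate-averaged stage_a/stage_b abundance ratio that
        justified the label.
    """

    labels: pd.Series
    ratios: pd.Series
    stage_a: str
    stage_b: str
    condition: str
    fold: float

    def members(self, group: str) -> frozenset:
        if group not in GROUPS:
            raise KeyError(f"unknown group {group!r}")
        return frozenset(self.labels.index[self.labels == group])

    def counts(self) -> dict:
        return {g: int((self.labels == g).sum()) for g in GROUPS}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"group": self.labels, "ratio": self.ratios})


def _stage_means(norm: NormalizedExpression, stage: str, condition: str) -> pd.Series:
    cols = norm.matrix.samples(stage=stage, condition=condition)
    if not cols:
        raise ValueError(f"no samples for stage={stage!r}, condition={condition!r}")
    return norm.matrix.gene_values()[cols].mean(axis=1)


class TranscriptClassifier(BaseEstimator):
    """Sklearn-style estimator assigning each gene a dynamic class.

    Parameters
    ----------
    stage_a, stage_b : str
        Earlier and later stage; the decision ratio is mean(a)/mean(b).
    condition : str
        Condition whose samples define the classes (wild type by default).
    fold : float
        Strict ratio threshold on both sides (default 2).

    Attributes
    ----------
    labels_ : pandas.Series of class labels per gene.
    ratios_ : pandas.Series of decision ratios per gene.
    classification_ : GeneClassification bundling both.
    """

    def __init__(
        self,
        stage_a: str = "zygote",
        stage_b: str = "2cell",
        condition: str = "WT",
        fold: float = 2.0,
    ):
        self.stage_a = stage_a
        self.stage_b = stage_b
        self.condition = condition
        self.fold = fold

    def fit(self, X: NormalizedExpression, y=None) -> "TranscriptClassifier":
        if self.fold <= 1:
            raise ValueError("fold threshold must exceed 1")
        mean_a = _stage_means(X, self.stage_a, self.condition)
        mean_b = _stage_means(X, self.stage_b, self.condition)
        ratio = mean_a / mean_b
        labels = pd.Series(STABLE, index=ratio.index, name="group")
        labels[ratio > self.fold] = MATERNAL_DECAY
        labels[1.0 / ratio > self.fold] = ZYGOTIC_ACTIVATED
        self.labels_ = labels
        self.ratios_ = ratio.rename("ratio")
        self.classification_ = GeneClassification(
            labels=labels,
            ratios=self.ratios_,
            stage_a=self.stage_a,
            stage_b=self.stage_b,
            condition=self.condition,
            fold=self.fold,
        )
        return self

    def predict(self, X: NormalizedExpression | None = None) -> pd.Series:
        if not hasattr(self, "labels_"):
            raise ValueError("TranscriptClassifier is not fitted")
        if X is None:
            return self.labels_
        return self.fit(X).labels_


def classify_genes(
    norm: NormalizedExpression,
    stage_a: str = "zygote",
    stage_b: str = "2cell",
    condition: str = "WT",
    fold: float = 2.0,
) -> GeneClassification:
    """Classify genes into {maternal_decay, zygotic_activated, stable}."""
    clf = TranscriptClassifier(stage_a=stage_a, stage_b=stage_b, condition=condition, fold=fold)
    return clf.fit(norm).classification_


def median_trajectory(
    norm: NormalizedExpression,
    classification: GeneClassification,
    condition: str,
) -> pd.DataFrame:
    """Per-group median expression at each stage of a condition.

    Replicates are averaged per gene first; the median is then taken over
    group members.  Empty groups are flagged and omitted.

    Returns
    -------
    pandas.DataFrame
        index = group label, columns = stages present for the condition.
    """
    mat = norm.matrix
    stages = [s for s, c in mat.groups() if c == condition]
    if not stages:
        raise ValueError(f"condition {condition!r} absent")
    rows = {}
    for group in GROUPS:
        members = sorted(classification.members(group))
        if not members:
            warnings.warn(f"group {group!r} is empty; omitted from trajectory", stacklevel=2)
            continue
        rows[group] = {
            stage: float(_stage_means(norm, stage, condition).loc[members].median())
            for stage in stages
        }
    return pd.DataFrame.from_dict(rows, orient="index").loc[:, stages]


def median_fold_change(
    trajectory_test: pd.DataFrame,
    trajectory_ref: pd.DataFrame,
    group: str,
    stage: str,
) -> float:
    """Ratio of group-median levels, test condition over reference.

    A value above 1 reads as "increased by f-fold"; below 1 the
    conventional report is "decreased by 1/f-fold" (see
    :func:`format_fold_change`).
    """
    for traj, name in ((trajectory_test, "test"), (trajectory_ref, "reference")):
        if group not in traj.index or stage not in traj.columns:
            raise KeyError(f"{name} trajectory lacks group {group!r} at stage {stage!r}")
    ref = float(trajectory_ref.loc[group, stage])
    if ref == 0:
        raise ValueError("zero reference median (values should be floored)")
    return float(trajectory_test.loc[group, stage]) / ref


def format_fold_change(fold: float) -> str:
    """Render a ratio the way results sections print it."""
    if fold >= 1:
        return f"increased by {fold:.2f}-fold"
    return f"decreased by {1.0 / fold:.2f}-fold"


@dataclass
class DifferentialSets:
    """Genes up/down beyond a fold threshold between two conditions."""

    up: frozenset
    down: frozenset
    fold_threshold: float
    stage: str
    conditions: tuple  # (test, reference)

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("up and down sets overlap")


def differential_sets(
    norm: NormalizedExpression,
    stage: str,
    test_condition: str,
    ref_condition: str,
    fold: float = 2.0,
) -> DifferentialSets:
    """Genes changed by more than ``fold`` between conditions at a stage.

    up = mean(test)/mean(ref) > fold; down = mean(ref)/mean(test) > fold;
    both strict, on replicate-averaged floored values.
    """
    if fold <= 1:
        raise ValueError("fold threshold must exceed 1")
    mean_test = _stage_means(norm, stage, test_condition)
    mean_ref = _stage_means(norm, stage, ref_condition)
    ratio = mean_test / mean_ref
    return DifferentialSets(
        up=frozenset(ratio.index[ratio > fold]),
        down=frozenset(ratio.index[1.0 / ratio > fold]),
        fold_threshold=fold,
        stage=stage,
        conditions=(test_condition, ref_condition),
    )
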