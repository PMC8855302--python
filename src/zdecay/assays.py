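"""Closed-form assay quantifications: ddCT qPCR and immunofluorescence.

Relative qPCR quantification follows the standard ddCT scheme against a
reference transcript (Gapdh by default):

    dCT   = CT(gene) - CT(reference)            per replicate
    ddCT  = mean dCT(test) - mean dCT(reference condition)
    fold  = 2^(-ddCT)

Replicate-level folds 2^(-ddCT_i) (with ddCT_i = dCT_test_i - mean
dCT(ref)) provide the SEM on the fold scale; the dCT-scale SEM is emitted
alongside.  Significance is a Welch (unequal-variance) two-sided t-test on
the replicate dCT values.

Immunofluorescence signal is the background-subtracted antibody intensity
normalized to the DNA (DAPI) channel, area-weighted:

    S = A_d (S_a - S_ba) / (A_a (S_d - S_bd))
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

REFERENCE_GENE = "Gapdh"

QPCR_COLUMNS = ("gene", "condition", "replicate", "ct_gene", "ct_ref")


def read_qpcr_tsv(path) -> pd.DataFrame:
    """Read a CT replicate table (gene, condition, replicate, ct_gene, ct_ref)."""
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in QPCR_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"qPCR table missing columns: {missing}")
    return table


def ddct_fold_change(
    table: pd.DataFrame, test_condition: str, ref_condition: str
) -> pd.DataFrame:
    """Per-gene fold change 2^(-ddCT) with SEM and Welch t p-value.

    Parameters
    ----------
    table : pandas.DataFrame
        Long-format CT replicates with columns ``gene, condition,
        replicate, ct_gene, ct_ref``.
    test_condition, ref_condition : str
        Conditions compared; ddCT = mean dCT(test) - mean dCT(ref).

    Returns
    -------
    pandas.DataFrame indexed by gene with columns ``ddct, fold_change,
    sem_fold, sem_dct, p_value, n_test, n_ref``.  With a single test
    replicate the fold is still reported but SEM and p are NaN (noticed
    via a warning).
    """
    for col in QPCR_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"qPCR table missing column {col!r}")
    if not np.isfinite(table[["ct_gene", "ct_ref"]].to_numpy()).all():
        raise ValueError("CT values must be finite")
    work = table.assign(dct=table["ct_gene"] - table["ct_ref"])
    rows = {}
    for gene, sub in work.groupby("gene", sort=True):
        dct_test = sub.loc[sub["condition"] == test_condition, "dct"].to_numpy()
        dct_ref = sub.loc[sub["condition"] == ref_condition, "dct"].to_numpy()
        if dct_test.size == 0 or dct_ref.size == 0:
            raise ValueError(f"gene {gene!r}: both conditions must have replicates")
        ddct = dct_test.mean() - dct_ref.mean()
        fold = 2.0 ** (-ddct)
        folds_i = 2.0 ** (-(dct_test - dct_ref.mean()))
        if dct_test.size >= 2 and dct_ref.size >= 2:
            sem_fold = folds_i.std(ddof=1) / math.sqrt(folds_i.size)
            sem_dct = dct_test.std(ddof=1) / math.sqrt(dct_test.size)
            if dct_test.std(ddof=1) == 0 and dct_ref.std(ddof=1) == 0:
                # degenerate noise-free replicates: the t statistic is 0/0
                p = 1.0 if ddct == 0 else 0.0
            else:
                p = float(stats.ttest_ind(dct_test, dct_ref, equal_var=False).pvalue)
        else:
            warnings.warn(
                f"gene {gene!r}: single replicate; SEM and p-value omitted", stacklevel=2
            )
            sem_fold = sem_dct = p = float("nan")
        rows[gene] = {
            "ddct": float(ddct),
            "fold_change": float(fold),
            "sem_fold": float(sem_fold),
            "sem_dct": float(sem_dct),
            "p_value": p,
            "n_test": int(dct_test.size),
            "n_ref": int(dct_ref.size),
        }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("gene")


@dataclass(frozen=True)
class IfMeasurement:
    """One immunofluorescence quantification (arbitrary intensity units).

    s_a/s_ba: antibody signal and background; s_d/s_bd: DNA signal and
    background; a_a/a_d: areas of the antibody and DNA signals.
    """

    s_a: float
    s_ba: float
    s_d: float
    s_bd: float
    a_a: float
    a_d: float

    def __post_init__(self) -> None:
        if self.a_a <= 0 or self.a_d <= 0:
            raise ValueError("areas must be positive")
        if self.s_a < self.s_ba:
            raise ValueError("antibody signal below its background")
        if self.s_d <= self.s_bd:
            raise ValueError("DNA signal must exceed its background")


def if_signal(m: IfMeasurement) -> float:
    """Background-subtracted, DNA-normalized antibody signal S."""
    return (m.a_d * (m.s_a - m.s_ba)) / (m.a_a * (m.s_d - m.s_bd))


def compartment_proportion(cyto_signal: float, nuc_signal: float) -> tuple[float, float]:
    """Fractions of total signal in cytoplasm and nucleus (sum to 1)."""
    if cyto_signal < 0 or nuc_signal < 0:
        raise ValueError("signals must be non-negative")
    total = cyto_signal + nuc_signal
    if total == 0:
        raise ValueError("both signals are zero; proportion undefined")
    return cyto_signal / total, nuc_signal / total
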