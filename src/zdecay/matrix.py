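"""Expression-matrix container and tab-delimited I/O.

The pipeline's raw input is a gene x sample abundance table on the FPKM
scale, together with per-sample metadata (developmental stage, condition,
replicate index).  Exogenous spike-in species are ordinary rows whose
identifiers carry a known prefix (``ERCC-`` by default); they are flagged
here and exempted from gene-level rules downstream.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import pandas as pd

DEFAULT_SPIKEIN_PREFIX = "ERCC-"

REQUIRED_METADATA_COLUMNS = ("stage", "condition", "replicate")


@dataclass
class ExpressionMatrix:
    """Gene x sample abundance table with sample metadata and spike-in flags.

    Parameters
    ----------
    values : pandas.DataFrame
        Non-negative abundances; index = gene/spike-in identifiers,
        columns = sample identifiers.  Both must be unique.
    metadata : pandas.DataFrame
        One row per sample (index = sample identifier) with columns
        ``stage``, ``condition`` and ``replicate``.
    spikein_prefix : str
        Identifier prefix marking spike-in rows.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame
    spikein_prefix: str = DEFAULT_SPIKEIN_PREFIX

    def __post_init__(self) -> None:
        if self.values.empty:
            raise ValueError("expression matrix is empty")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene identifiers")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample identifiers")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("abundances must be non-negative")
        missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in self.metadata.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        unknown = set(self.values.columns) - set(self.metadata.index)
        if unknown:
            raise ValueError(f"samples without metadata: {sorted(unknown)}")

    # -- spike-in handling -------------------------------------------------

    @property
    def spikein_mask(self) -> pd.Series:
        """Boolean Series over rows; True for spike-in species."""
        return self.values.index.to_series().str.startswith(self.spikein_prefix)

    @property
    def gene_ids(self) -> pd.Index:
        """Identifiers of endogenous (non-spike-in) genes."""
        return self.values.index[~self.spikein_mask]

    @property
    def spikein_ids(self) -> pd.Index:
        return self.values.index[self.spikein_mask]

    def gene_values(self) -> pd.DataFrame:
        """Abundance sub-table restricted to endogenous genes."""
        return self.values.loc[self.gene_ids]

    def spikein_values(self) -> pd.DataFrame:
        return self.values.loc[self.spikein_ids]

    # -- sample selection --------------------------------------------------

    def samples(self, stage: str | None = None, condition: str | None = None) -> list[str]:
        """Sample identifiers matching the given stage and/or condition."""
        meta = self.metadata.loc[list(self.values.columns)]
        keep = pd.Series(True, index=meta.index)
        if stage is not None:
            keep &= meta["stage"] == stage
        if condition is not None:
            keep &= meta["condition"] == condition
        return list(meta.index[keep])

    def groups(self) -> list[tuple[str, str]]:
        """Distinct (stage, condition) pairs in column order of appearance."""
        meta = self.metadata.loc[list(self.values.columns)]
        seen: list[tuple[str, str]] = []
        for stage, condition in zip(meta["stage"], meta["condition"]):
            if (stage, condition) not in seen:
                seen.append((stage, condition))
        return seen

    def with_values(self, values: pd.DataFrame) -> "ExpressionMatrix":
        """Copy of this matrix with a replaced abundance table."""
        return dataclasses.replace(self, values=values)

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, matrix_path, metadata_path) -> None:
        self.values.to_csv(matrix_path, sep="\t", index_label="gene_id")
        self.metadata.to_csv(metadata_path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(
        cls, matrix_path, metadata_path, spikein_prefix: str = DEFAULT_SPIKEIN_PREFIX
    ) -> "ExpressionMatrix":
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        metadata = pd.read_csv(metadata_path, sep="\t", index_col=0)
        return cls(values=values, metadata=metadata, spikein_prefix=spikein_prefix)


@dataclass
class NormalizedExpression:
    """An :class:`ExpressionMatrix` after spike-in scaling and/or flooring.

    Attributes
    ----------
    matrix : ExpressionMatrix
        The scaled (and possibly floored/filtered) table.
    scale_factors : pandas.Series
        Per-sample multiplier ``s_j`` that was applied.
    floored : bool
        Whether the FPKM<1 exclusion/flooring rules were applied.
    excluded_gene_ids : list of str
        Genes removed because their abundance was < 1 in every sample.
    """

    matrix: ExpressionMatrix
    scale_factors: pd.Series
    floored: bool = False
    excluded_gene_ids: list = field(default_factory=list)

    @property
    def values(self) -> pd.DataFrame:
        return self.matrix.values

    @property
    def metadata(self) -> pd.DataFrame:
        return self.matrix.metadata
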