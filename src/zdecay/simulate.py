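"""Seeded synthetic datasets with known ground truth for every stage.

The expression simulator emulates a mouse zygote -> late-2-cell profiling
experiment: three transcript classes (maternal transcripts decaying across
the transition, zygotically activated transcripts rising, and stable
transcripts), constant exogenous spike-ins, and a knockdown condition that
blocks decay (stabilizing maternal transcripts at the 2-cell stage) while
suppressing zygotic activation.  Noise is multiplicative log-normal, the
natural choice for strictly positive FPKM-scale data.

Companion generators emit 3'-RACE reads with known poly(A)/oligo(U) tail
lengths and qPCR CT replicate tables with a known fold-change effect, so
every downstream caller can be validated against ground truth.

All generators require an explicit seed and are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .dynamics import MATERNAL_DECAY, STABLE, ZYGOTIC_ACTIVATED
from .matrix import DEFAULT_SPIKEIN_PREFIX, ExpressionMatrix

STAGE_ZYGOTE = "zygote"
STAGE_2CELL = "2cell"
CONDITION_WT = "WT"
CONDITION_KD = "KD"

# Documented fixed probe sequences for RACE simulation; both configurable.
# The linker is the universal miRNA cloning linker sequence ligated to mRNA
# 3' ends; the anchor stands in for the gene-specific forward primer region.
DEFAULT_ANCHOR = "GCTACGGTTACCTTGACG"
DEFAULT_LINKER = "CTGTAGGCACCATCAAT"


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions of the synthetic zygote -> 2-cell experiment.

    Defaults mirror the profiled system at desk scale: class sizes in the
    maternal-decay : activated : stable proportion observed in mouse
    embryos (624/140/495), duplicate libraries per stage and condition, a
    92-species spike-in mix, and knockdown effects of the magnitude seen
    when the zygotic decay pathway is depleted (maternal transcripts up
    ~2.32-fold, activated transcripts down ~4.37-fold at the 2-cell
    stage).
    """

    seed: int
    n_decay: int = 624
    n_zga: int = 140
    n_stable: int = 495
    decay_fold: float = 4.0
    zga_fold: float = 4.0
    kd_stabilization: float = 2.32
    kd_zga_suppression: float = 1.0 / 4.37
    noise_sd: float = 0.2
    n_replicates: int = 2
    n_spikeins: int = 92

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory; generation must be reproducible")
        for name in ("n_decay", "n_zga", "n_stable", "n_spikeins"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_replicates <= 0:
            raise ValueError("n_replicates must be positive")
        if self.decay_fold <= 2 or self.zga_fold <= 2:
            raise ValueError("decay_fold and zga_fold must exceed 2 for recoverable labels")
        if self.kd_stabilization <= 1:
            raise ValueError("kd_stabilization must exceed 1")
        if not 0 < self.kd_zga_suppression < 1:
            raise ValueError("kd_zga_suppression must lie in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class TruthTable:
    """Ground truth of one simulated experiment.

    Attributes
    ----------
    labels : pandas.Series
        gene_id -> true dynamic class.
    expected : pandas.DataFrame
        gene_id x "{stage}_{condition}" noise-free expected abundance.
    """

    labels: pd.Series
    expected: pd.DataFrame

    def members(self, label: str) -> frozenset:
        return frozenset(self.labels.index[self.labels == label])

    def to_tsv(self, path) -> None:
        out = self.expected.copy()
        out.insert(0, "label", self.labels)
        out.to_csv(path, sep="\t", index_label="gene_id")


def _expected_table(params: SimulationParams, rng: np.random.Generator):
    n_genes = params.n_decay + params.n_zga + params.n_stable
    gene_ids = [f"gene_{i:05d}" for i in range(1, n_genes + 1)]
    labels = np.array(
        [MATERNAL_DECAY] * params.n_decay
        + [ZYGOTIC_ACTIVATED] * params.n_zga
        + [STABLE] * params.n_stable
    )
    # peak abundance spans ~6-300 FPKM so even divided levels stay above the
    # floor; activated genes peak at the 2-cell stage (they are near-absent
    # before genome activation), the other classes peak in the zygote
    base = 10.0 ** rng.uniform(0.8, 2.5, size=n_genes)
    zga = labels == ZYGOTIC_ACTIVATED

    zygote = base.copy()
    zygote[zga] = base[zga] / params.zga_fold
    wt_2cell = base.copy()
    wt_2cell[labels == MATERNAL_DECAY] = base[labels == MATERNAL_DECAY] / params.decay_fold

    kd_2cell = wt_2cell.copy()
    kd_2cell[labels == MATERNAL_DECAY] *= params.kd_stabilization
    kd_2cell[zga] *= params.kd_zga_suppression

    expected = pd.DataFrame(
        {
            f"{STAGE_ZYGOTE}_{CONDITION_WT}": zygote,
            f"{STAGE_2CELL}_{CONDITION_WT}": wt_2cell,
            # siRNA is injected at the zygote stage; its effect appears later,
            # so zygote expectations are identical across conditions
            f"{STAGE_ZYGOTE}_{CONDITION_KD}": zygote,
            f"{STAGE_2CELL}_{CONDITION_KD}": kd_2cell,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return pd.Series(labels, index=expected.index, name="label"), expected


def generate_mzt_experiment(
    params: SimulationParams,
    spikein_prefix: str = DEFAULT_SPIKEIN_PREFIX,
) -> tuple[ExpressionMatrix, TruthTable]:
    """Simulate the four-group (2 stages x 2 conditions) FPKM matrix.

    Returns the matrix (gene rows plus spike-in rows, ``n_replicates``
    columns per stage x condition) and the truth table of labels and
    noise-free expectations.  Identical parameters give bit-identical
    output.
    """
    rng = np.random.default_rng(params.seed)
    labels, expected = _expected_table(params, rng)

    # spike-in mix: fixed per-species amounts spanning ~3.5 decades,
    # identical in every sample by construction
    spike_ids = [f"{spikein_prefix}{i:05d}" for i in range(1, params.n_spikeins + 1)]
    spike_levels = np.logspace(-0.5, 3.0, num=params.n_spikeins) if params.n_spikeins else np.array([])

    sample_ids, meta_rows, expected_cols = [], [], []
    for condition in (CONDITION_WT, CONDITION_KD):
        for stage in (STAGE_ZYGOTE, STAGE_2CELL):
            for rep in range(1, params.n_replicates + 1):
                sample_ids.append(f"{condition}_{stage}_r{rep}")
                meta_rows.append({"stage": stage, "condition": condition, "replicate": rep})
                expected_cols.append(f"{stage}_{condition}")

    mean = np.vstack(
        [expected[expected_cols].to_numpy()]
        + ([np.tile(spike_levels[:, None], (1, len(sample_ids)))] if params.n_spikeins else [])
    )
    noise = np.exp(rng.normal(0.0, params.noise_sd, size=mean.shape)) if params.noise_sd > 0 else 1.0
    values = pd.DataFrame(
        mean * noise,
        index=pd.Index(list(expected.index) + spike_ids, name="gene_id"),
        columns=sample_ids,
    )
    metadata = pd.DataFrame(meta_rows, index=pd.Index(sample_ids, name="sample_id"))
    matrix = ExpressionMatrix(values=values, metadata=metadata, spikein_prefix=spikein_prefix)
    return matrix, TruthTable(labels=labels, expected=expected)


@dataclass(frozen=True)
class RaceTailModel:
    """Sampling distribution for (poly(A), oligo(U)) tail lengths.

    Poly(A) lengths are uniform on [a_min, a_max].  A read is uridylated
    with probability ``p_u_short`` when its poly(A) tail is shorter than
    ``short_cut`` nt and ``p_u_long`` otherwise — the pattern produced when
    terminal uridylyl transferases prefer short-tailed substrates; oligo(U)
    lengths are uniform on [u_min, u_max].
    """

    a_min: int = 0
    a_max: int = 60
    short_cut: int = 20
    p_u_short: float = 0.8
    p_u_long: float = 0.1
    u_min: int = 1
    u_max: int = 8

    def __post_init__(self) -> None:
        if not (0 <= self.a_min <= self.a_max):
            raise ValueError("need 0 <= a_min <= a_max")
        if not (1 <= self.u_min <= self.u_max):
            raise ValueError("need 1 <= u_min <= u_max")
        for p in (self.p_u_short, self.p_u_long):
            if not 0 <= p <= 1:
                raise ValueError("uridylation probabilities must lie in [0, 1]")


def _check_seq(seq: str, what: str) -> str:
    seq = seq.upper()
    if not seq or set(seq) - set("ACGT"):
        raise ValueError(f"{what} must be non-empty over A/C/G/T")
    return seq


def generate_race_reads(
    n_reads: int | None = None,
    tails: list[tuple[int, int]] | None = None,
    tail_model: RaceTailModel | None = None,
    anchor_seq: str = DEFAULT_ANCHOR,
    linker_seq: str = DEFAULT_LINKER,
    seed: int | None = None,
    prefix_len: int = 30,
) -> tuple[list[SeqRecord], list[tuple[str, int, int]]]:
    """Simulate 3'-RACE reads ``prefix + anchor + A^a + T^u + linker``.

    Tails come either from an explicit ``tails`` list of (A-length,
    U-length) pairs or are sampled (``n_reads`` of them) from
    ``tail_model``.  Uridines are emitted as T: sequenced clones are cDNA.
    Returns Biopython SeqRecords and the truth list (read_id, a, u).
    """
    anchor = _check_seq(anchor_seq, "anchor")
    linker = _check_seq(linker_seq, "linker")
    if seed is None:
        raise ValueError("a seed is mandatory; generation must be reproducible")
    rng = np.random.default_rng(seed)
    if tails is None:
        if n_reads is None:
            raise ValueError("pass either an explicit tails list or n_reads")
        model = tail_model or RaceTailModel()
        a_lens = rng.integers(model.a_min, model.a_max + 1, size=n_reads)
        p_u = np.where(a_lens < model.short_cut, model.p_u_short, model.p_u_long)
        uridylate = rng.random(n_reads) < p_u
        u_lens = np.where(
            uridylate, rng.integers(model.u_min, model.u_max + 1, size=n_reads), 0
        )
        tails = list(zip(a_lens.tolist(), u_lens.tolist()))
    else:
        tails = [(int(a), int(u)) for a, u in tails]
        for a, u in tails:
            if a < 0 or u < 0:
                raise ValueError("tail lengths must be >= 0")

    bases = np.array(list("ACGT"))
    records, truth = [], []
    for i, (a, u) in enumerate(tails, start=1):
        read_id = f"read_{i:05d}"
        prefix = "".join(rng.choice(bases, size=prefix_len)) if prefix_len else ""
        seq = prefix + anchor + "A" * a + "T" * u + linker
        records.append(SeqRecord(Seq(seq), id=read_id, description=f"polyA={a} oligoU={u}"))
        truth.append((read_id, a, u))
    return records, truth


def write_fasta(records: list[SeqRecord], path) -> None:
    from Bio import SeqIO

    SeqIO.write(records, str(path), "fasta")


def generate_qpcr(
    genes: list[str],
    true_fold: float | dict,
    ct_noise_sd: float = 0.0,
    seed: int | None = None,
    n_replicates: int = 3,
    test_condition: str = CONDITION_KD,
    ref_condition: str = CONDITION_WT,
    base_ct_ref: float = 16.0,
    base_dct: float = 5.0,
) -> pd.DataFrame:
    """Simulate a CT replicate table with a known KD/WT fold change.

    Per replicate, reference-gene and target CTs each receive independent
    Gaussian noise of SD ``ct_noise_sd`` cycles; the test condition's
    expected dCT is shifted by -log2(true_fold), so E[ddCT] =
    -log2(true_fold) and the ddCT estimator recovers ``true_fold``.

    Returns a long-format table with columns ``gene, condition, replicate,
    ct_gene, ct_ref``.
    """
    if seed is None:
        raise ValueError("a seed is mandatory; generation must be reproducible")
    folds = {g: float(true_fold[g] if isinstance(true_fold, dict) else true_fold) for g in genes}
    for g, f in folds.items():
        if f <= 0:
            raise ValueError(f"gene {g!r}: fold change must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for gene in genes:
        for condition in (ref_condition, test_condition):
            shift = -np.log2(folds[gene]) if condition == test_condition else 0.0
            for rep in range(1, n_replicates + 1):
                ct_ref = base_ct_ref + rng.normal(0.0, ct_noise_sd) if ct_noise_sd else base_ct_ref
                ct_gene = ct_ref + base_dct + shift
                if ct_noise_sd:
                    ct_gene += rng.normal(0.0, ct_noise_sd)
                rows.append(
                    {
                        "gene": gene,
                        "condition": condition,
                        "replicate": rep,
                        "ct_gene": ct_gene,
                        "ct_ref": ct_ref,
                    }
                )
    return pd.DataFrame(rows)
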