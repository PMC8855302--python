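"""3'-ligation RACE tail calling: poly(A) length and terminal oligo(U).

In 3'-ligation RACE a known linker is ligated to mRNA 3' ends; after RT-PCR
with a gene-specific forward primer, each sequenced clone reads (5'->3'):

    [gene body ...] anchor  A^a  U^u  linker [...]

in cDNA space, where uridines appear as T.  The tail grammar is fixed as an
adenosine run followed by a terminal uridine run — the architecture left by
deadenylation and terminal uridylyl transferase (TUT4/7) action.  Reads
whose tail contains anything else are flagged unparseable rather than
guessed.

Summaries bin reads by poly(A) length (default: < 20 nt vs >= 20 nt) and
report the uridylation frequency per bin, the readout used to show that
oligo(U) marks accumulate on short-tailed transcripts.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import SeqIO
from Bio.Seq import Seq

VALID_BASES = set("ACGT")
READ_BASES = set("ACGTN")

A_ONLY = "A-only"
A_U = "A+U"
U_ONLY = "U-only"
NO_TAIL = "no-tail"


@dataclass
class TailRecord:
    """Parsed 3' architecture of one RACE read."""

    read_id: str
    polya_len: int
    oligou_len: int
    anchor_found: bool
    linker_found: bool
    parse_ok: bool
    classification: str | None

    @property
    def uridylated(self) -> bool:
        return self.parse_ok and self.oligou_len > 0


def _classify(a: int, u: int) -> str:
    if a > 0 and u > 0:
        return A_U
    if a > 0:
        return A_ONLY
    if u > 0:
        return U_ONLY
    return NO_TAIL


def _check_probe(seq: str, what: str) -> str:
    seq = seq.upper()
    if not seq or set(seq) - VALID_BASES:
        raise ValueError(f"{what} must be a non-empty string over A/C/G/T: {seq!r}")
    return seq


def _find_approx(hay: str, needle: str, start: int, max_mismatch: int, rightmost: bool) -> int:
    """Index of the (left- or right-)most window within Hamming distance."""
    if max_mismatch == 0:
        return hay.rfind(needle) if rightmost else hay.find(needle, start)
    best = -1
    rng = range(start, len(hay) - len(needle) + 1)
    for i in rng:
        mm = sum(1 for x, y in zip(hay[i : i + len(needle)], needle) if x != y)
        if mm <= max_mismatch:
            best = i
            if not rightmost:
                break
    return best


def parse_tail(
    read: str,
    anchor_seq: str,
    linker_seq: str,
    max_mismatch: int = 0,
    read_id: str = "",
) -> TailRecord:
    """Call poly(A) and terminal oligo(U) lengths from one read.

    The anchor is located by its rightmost match (sequence upstream of the
    anchor is irrelevant), the linker by its leftmost match after the
    anchor; the tail is the substring strictly between them.  The terminal
    T run (oligo(U) in cDNA space) is measured first, then the A run
    immediately 5' of it; any other residue in the tail marks the read as
    a parse failure.
    """
    anchor = _check_probe(anchor_seq, "anchor")
    linker = _check_probe(linker_seq, "linker")
    seq = read.upper()
    if set(seq) - READ_BASES:
        raise ValueError("read contains characters outside A/C/G/T/N")

    failed = TailRecord(read_id, 0, 0, False, False, False, None)
    a_pos = _find_approx(seq, anchor, 0, max_mismatch, rightmost=True)
    if a_pos < 0:
        return failed
    tail_start = a_pos + len(anchor)
    l_pos = _find_approx(seq, linker, tail_start, max_mismatch, rightmost=False)
    if l_pos < 0:
        return TailRecord(read_id, 0, 0, True, False, False, None)

    tail = seq[tail_start:l_pos]
    u = len(tail) - len(tail.rstrip("T"))
    rest = tail[: len(tail) - u]
    a = len(rest) - len(rest.rstrip("A"))
    if rest[: len(rest) - a]:  # interior bases violate the A^a U^u grammar
        return TailRecord(read_id, 0, 0, True, True, False, None)
    return TailRecord(read_id, a, u, True, True, True, _classify(a, u))


def parse_fasta(
    path,
    anchor_seq: str,
    linker_seq: str,
    max_mismatch: int = 0,
    reverse_complement: bool = False,
) -> list[TailRecord]:
    """Parse every read of a FASTA file into a TailRecord.

    ``reverse_complement`` applies a reverse-complement pre-pass for reads
    cloned in antisense orientation (off by default: Sanger reads of TA
    clones are submitted sense-strand).
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if reverse_complement:
            seq = str(Seq(seq).reverse_complement())
        records.append(
            parse_tail(seq, anchor_seq, linker_seq, max_mismatch=max_mismatch, read_id=rec.id)
        )
    return records


@dataclass
class TailBin:
    n_reads: int
    n_uridylated: int

    @property
    def uridylation_frequency(self) -> float | None:
        return self.n_uridylated / self.n_reads if self.n_reads else None


@dataclass
class TailSummary:
    """Read counts and uridylation frequency per poly(A)-length bin."""

    short: TailBin
    long: TailBin
    short_cut: int
    min_u: int
    n_parsed: int

    def to_jsonable(self) -> dict:
        return {
            "short_cut_nt": self.short_cut,
            "min_u_nt": self.min_u,
            "n_parsed": self.n_parsed,
            "bins": {
                f"polyA<{self.short_cut}": {
                    "n_reads": self.short.n_reads,
                    "n_uridylated": self.short.n_uridylated,
                    "uridylation_frequency": self.short.uridylation_frequency,
                },
                f"polyA>={self.short_cut}": {
                    "n_reads": self.long.n_reads,
                    "n_uridylated": self.long.n_uridylated,
                    "uridylation_frequency": self.long.uridylation_frequency,
                },
            },
        }


def uridylation_by_tail_bin(
    records: list[TailRecord], short_cut: int = 20, min_u: int = 1
) -> TailSummary:
    """Uridylation frequency among short (< short_cut) vs long poly(A) tails.

    Only successfully parsed reads are counted; a read is uridylated when
    its terminal oligo(U) run is at least ``min_u`` nucleotides.
    """
    ok = [r for r in records if r.parse_ok]
    if not ok:
        raise ValueError("no successfully parsed reads to summarize")
    short = [r for r in ok if r.polya_len < short_cut]
    long_ = [r for r in ok if r.polya_len >= short_cut]
    return TailSummary(
        short=TailBin(len(short), sum(r.oligou_len >= min_u for r in short)),
        long=TailBin(len(long_), sum(r.oligou_len >= min_u for r in long_)),
        short_cut=short_cut,
        min_u=min_u,
        n_parsed=len(ok),
    )
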