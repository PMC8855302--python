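"""Gene-set overlaps, printed-style percentages and hypergeometric enrichment.

Overlap fractions are reported the way results sections print them: as a
percentage of one set, rounded half-up to one decimal ("3014 out of 3515
(85.7%)").  Enrichment is the one-sided upper-tail hypergeometric
probability P(X >= k) of drawing at least the observed intersection from a
finite universe without replacement; it is also returned in log10 so that
overlaps far beyond double-precision significance remain comparable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from scipy import stats


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero, matching printed percentages."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers with a provenance note."""

    name: str
    members: frozenset
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))

    def __len__(self) -> int:
        return len(self.members)

    @classmethod
    def from_file(cls, path, name: str | None = None) -> "GeneSet":
        """Read a plain-text gene list, one identifier per line."""
        with open(path) as fh:
            ids = [line.strip() for line in fh if line.strip()]
        return cls(name=name or str(path), members=frozenset(ids), provenance=f"file:{path}")

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for g in sorted(self.members):
                fh.write(g + "\n")


@dataclass
class OverlapResult:
    """Intersection counts, printed percentages, optional enrichment."""

    name_a: str
    name_b: str
    size_a: int
    size_b: int
    intersection: int
    fraction_of_a: float | None
    fraction_of_b: float | None
    universe_size: int | None = None
    p_value: float | None = None
    log10_p: float | None = None

    def to_jsonable(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def overlap_fraction(set_a: GeneSet, set_b: GeneSet) -> OverlapResult:
    """Counts and printed percentages of the pairwise overlap.

    ``fraction_of_a`` is 100*k/|A| rounded half-up to one decimal; it is
    None (undefined) for an empty set.
    """
    k = len(set_a.members & set_b.members)

    def frac(size: int) -> float | None:
        return round_half_up(100.0 * k / size, 1) if size else None

    return OverlapResult(
        name_a=set_a.name,
        name_b=set_b.name,
        size_a=len(set_a),
        size_b=len(set_b),
        intersection=k,
        fraction_of_a=frac(len(set_a)),
        fraction_of_b=frac(len(set_b)),
    )


def hypergeometric_enrichment(
    set_a: GeneSet, set_b: GeneSet, universe_size: int
) -> tuple[float, float]:
    """Upper-tail hypergeometric enrichment p-value of the overlap.

    With X ~ Hypergeometric(N=universe_size, K=|A|, n=|B|) and observed
    intersection k, returns (P(X >= k), log10 of that probability); the log
    form is computed in log space and survives arbitrarily extreme
    significance.

    Raises
    ------
    ValueError
        If the universe cannot contain the union of the two sets.
    """
    n_a, n_b = len(set_a), len(set_b)
    union = len(set_a.members | set_b.members)
    if universe_size < union:
        raise ValueError(
            f"universe size {universe_size} smaller than |A U B| = {union}"
        )
    k = len(set_a.members & set_b.members)
    # survival function is P(X > k-1) = P(X >= k)
    p = float(stats.hypergeom.sf(k - 1, universe_size, n_a, n_b))
    logp = float(stats.hypergeom.logsf(k - 1, universe_size, n_a, n_b))
    return p, logp / math.log(10.0)


# Region keys of a three-set Venn diagram.
VENN_REGIONS = ("a_only", "b_only", "c_only", "ab_only", "ac_only", "bc_only", "abc")


def three_way_overlap(set_a: GeneSet, set_b: GeneSet, set_c: GeneSet) -> dict:
    """Counts of the seven exclusive Venn regions of three sets."""
    a, b, c = set_a.members, set_b.members, set_c.members
    abc = a & b & c
    return {
        "a_only": len(a - b - c),
        "b_only": len(b - a - c),
        "c_only": len(c - a - b),
        "ab_only": len((a & b) - c),
        "ac_only": len((a & c) - b),
        "bc_only": len((b & c) - a),
        "abc": len(abc),
    }


@dataclass
class OverlapReport:
    """Pairwise result plus optional three-way regions, for serialization."""

    pairwise: OverlapResult
    venn: dict | None = field(default=None)

    def to_jsonable(self) -> dict:
        out = {"pairwise": self.pairwise.to_jsonable()}
        if self.venn is not None:
            out["venn_regions"] = dict(self.venn)
        return out
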