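"""Core domain containers for the interactome-enrichment pipeline.

All genomic coordinates are 1-based and interval bounds are inclusive.
Chromosome labels are normalized (no ``chr`` prefix, ``X``/``Y``/``MT``
uppercase) as soon as data enters the package, so downstream comparisons
are plain string equality.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Iterator, Tuple


def normalize_chrom(label: object) -> str:
    """Normalize a chromosome label to the internal convention.

    Strips a leading ``chr``/``CHR`` prefix and uppercases the sex and
    mitochondrial labels, so ``chr6``, ``Chr6`` and ``6`` all compare
    equal.  Numeric labels are kept as their decimal string.
    """
    text = str(label).strip()
    if text.lower().startswith("chr"):
        text = text[3:]
    if text.lower() in {"x", "y", "mt", "m"}:
        text = "MT" if text.lower() in {"mt", "m"} else text.upper()
    return text


class SetSource(str, Enum):
    """Provenance class of a gene set (mirrors the usual reporting style
    of interactome tables: taken from the literature as published,
    manually curated from primary evidence, or pulled from an
    interaction database)."""

    LITERATURE = "literature"
    CURATED = "curated"
    DATABASE = "database"


class InteractionClass(str, Enum):
    DIRECT = "direct"
    INDIRECT = "indirect"
    UNKNOWN = "unknown"


@dataclass(frozen=True, slots=True)
class SnpRecord:
    """One tested variant from a GWAS summary-statistics file."""

    rsid: str
    chrom: str
    pos: int
    pvalue: float

    def __post_init__(self) -> None:
        if not self.rsid:
            raise ValueError("rsid must be non-empty")
        if self.pos < 1:
            raise ValueError(f"SNP {self.rsid}: position must be >= 1, got {self.pos}")
        if not (0.0 < self.pvalue <= 1.0):
            raise ValueError(
                f"SNP {self.rsid}: p-value must lie in (0, 1], got {self.pvalue}"
            )


@dataclass(frozen=True, slots=True)
class GeneRecord:
    """A gene interval; ``start``/``end`` are 1-based inclusive."""

    symbol: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.symbol:
            raise ValueError("gene symbol must be non-empty")
        if self.start < 1 or self.start > self.end:
            raise ValueError(
                f"gene {self.symbol}: invalid interval [{self.start}, {self.end}]"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GeneSet:
    """A named interactome: human gene symbols plus a provenance tag."""

    name: str
    source: SetSource
    genes: frozenset

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set name must be non-empty")
        if len(self.genes) < 1:
            raise ValueError(f"gene set {self.name!r} must contain at least one gene")
        object.__setattr__(self, "genes", frozenset(self.genes))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.genes


@dataclass(frozen=True, slots=True)
class EvidenceRecord:
    """A single interaction-evidence row linking an environmental-factor
    protein to a human gene, with its publication and method."""

    env_protein: str
    human_gene: str
    source_id: str
    method: str
    interaction_class: InteractionClass

    def __post_init__(self) -> None:
        if not self.human_gene:
            raise ValueError("evidence record must name a human gene")
        if not self.source_id:
            raise ValueError("evidence record must carry a source identifier")


@dataclass(frozen=True)
class RegionMask:
    """Genomic intervals to exclude (e.g. an extended-MHC-style region).

    Intervals are ``(chrom, start, end)``, 1-based inclusive at both
    bounds.
    """

    intervals: Tuple[Tuple[str, int, int], ...]
    label: str = "mask"

    def __post_init__(self) -> None:
        norm = []
        for chrom, start, end in self.intervals:
            if start > end:
                raise ValueError(
                    f"mask {self.label!r}: invalid interval [{start}, {end}] on {chrom}"
                )
            norm.append((normalize_chrom(chrom), int(start), int(end)))
        object.__setattr__(self, "intervals", tuple(norm))

    def contains(self, chrom: str, pos: int) -> bool:
        return any(
            chrom == c and s <= pos <= e for c, s, e in self.intervals
        )

    def __len__(self) -> int:
        return len(self.intervals)


class LdTable:
    """Sparse symmetric lookup of pairwise r² between SNPs.

    Absent pairs are 0 by contract and the diagonal is 1; both
    conventions mirror how pairwise-LD reports are consumed in practice
    (only correlated pairs are listed).
    """

    __slots__ = ("_pairs",)

    def __init__(self, pairs: Iterable[Tuple[str, str, float]] = ()) -> None:
        self._pairs: dict = {}
        for a, b, r2 in pairs:
            self.add(a, b, r2)

    @staticmethod
    def _key(a: str, b: str) -> Tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add(self, a: str, b: str, r2: float) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise ValueError(f"r2 must lie in [0, 1], got {r2} for ({a}, {b})")
        if a == b:
            return  # diagonal is implicit
        self._pairs[self._key(a, b)] = float(r2)

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._pairs.get(self._key(a, b), 0.0)

    def items(self) -> Iterator[Tuple[str, str, float]]:
        for (a, b), r2 in self._pairs.items():
            yield a, b, r2

    def __len__(self) -> int:
        return len(self._pairs)

    def __contains__(self, pair: Tuple[str, str]) -> bool:
        return self._key(*pair) in self._pairs
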