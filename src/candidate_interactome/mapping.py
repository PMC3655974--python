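"""SNP-to-gene mapping, index-SNP selection and LD-aware pruning.

This module turns SNP-level association p-values into an LD-pruned list
of significant genes:

1. optionally drop SNPs inside a region mask (inclusive bounds);
2. assign every SNP to each gene whose interval, extended by a flanking
   window (default 20 kb, inclusive at the boundary), contains it;
3. per gene, keep the single most-associated assigned SNP (the index
   SNP; ties broken by position, then rsid);
4. flag genes whose index p-value is strictly below the SNP-level
   cutoff P-CUT;
5. greedily prune the flagged genes in ascending index-p order so the
   retained index SNPs are pairwise independent.  Two SNPs count as
   independent when they sit on different chromosomes, are farther
   apart than 1000 kb, or have r² ≤ 0.2.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

from .errors import MappingError
from .models import GeneRecord, LdTable, RegionMask, SnpRecord

DEFAULT_WINDOW_BP = 20_000
DEFAULT_R2_MAX = 0.2
DEFAULT_DIST_BP = 1_000_000


@dataclass
class GeneSnpIndex:
    """Assignment of SNPs to genes plus, once selected, the per-gene
    index SNP (the assigned SNP with the smallest p-value)."""

    snps: List[SnpRecord]
    assignments: Dict[str, List[int]]  # gene symbol -> indices into ``snps``
    unmappable: frozenset
    window_bp: int
    index_snps: Dict[str, SnpRecord] = field(default_factory=dict)

    def rsids(self, gene: str) -> List[str]:
        return [self.snps[i].rsid for i in self.assignments.get(gene, [])]

    def snp_count(self, gene: str) -> int:
        return len(self.assignments.get(gene, ()))

    @property
    def mappable_genes(self) -> List[str]:
        return sorted(g for g, idx in self.assignments.items() if idx)


@dataclass
class SignificantGeneList:
    """Genes whose index SNP beats P-CUT, ordered by ascending index p.

    ``entries`` holds ``(gene symbol, index rsid, index p-value)``;
    ``pruned`` records whether the LD filter has been applied.
    """

    entries: List[Tuple[str, str, float]]
    pcut: float
    masked: bool = False
    pruned: bool = False

    def genes(self) -> List[str]:
        return [g for g, _, _ in self.entries]

    def __len__(self) -> int:
        return len(self.entries)


def apply_region_mask(
    snps: Sequence[SnpRecord], mask: Optional[RegionMask]
) -> List[SnpRecord]:
    """Drop SNPs falling inside any mask interval (bounds inclusive)."""
    if mask is None or len(mask) == 0:
        return list(snps)
    return [s for s in snps if not mask.contains(s.chrom, s.pos)]


def map_snps_to_genes(
    snps: Sequence[SnpRecord],
    genes: Sequence[GeneRecord],
    window_bp: int = DEFAULT_WINDOW_BP,
) -> GeneSnpIndex:
    """Assign each SNP to every gene within ``window_bp`` of its interval.

    A SNP s is assigned to gene g iff the chromosomes match and
    ``g.start - window_bp <= s.pos <= g.end + window_bp`` (boundary
    inclusive).  A SNP may serve several genes; genes left without any
    SNP are recorded as unmappable.
    """
    if window_bp < 0:
        raise MappingError(f"window_bp must be >= 0, got {window_bp}")
    snps = list(snps)
    by_chrom: Dict[str, Tuple[List[int], List[int]]] = {}
    order: Dict[str, List[int]] = {}
    for i, s in enumerate(snps):
        order.setdefault(s.chrom, []).append(i)
    for chrom, idx in order.items():
        idx.sort(key=lambda i: snps[i].pos)
        by_chrom[chrom] = ([snps[i].pos for i in idx], idx)

    assignments: Dict[str, List[int]] = {}
    unmappable = []
    for gene in genes:
        positions, idx = by_chrom.get(gene.chrom, ([], []))
        lo = bisect.bisect_left(positions, gene.start - window_bp)
        hi = bisect.bisect_right(positions, gene.end + window_bp)
        assigned = idx[lo:hi]
        assignments[gene.symbol] = assigned
        if not assigned:
            unmappable.append(gene.symbol)
    return GeneSnpIndex(
        snps=snps,
        assignments=assignments,
        unmappable=frozenset(unmappable),
        window_bp=window_bp,
    )


def select_index_snps(index: GeneSnpIndex) -> GeneSnpIndex:
    """Pick each gene's index SNP: minimal p-value, ties broken by
    smaller position then lexicographic rsid.  Unmappable genes stay
    unmappable."""
    chosen: Dict[str, SnpRecord] = {}
    snps = index.snps
    for gene, assigned in index.assignments.items():
        if not assigned:
            continue
        best = min(assigned, key=lambda i: (snps[i].pvalue, snps[i].pos, snps[i].rsid))
        chosen[gene] = snps[best]
    index.index_snps = chosen
    return index


def flag_significant_genes(
    index: GeneSnpIndex, pcut: float, masked: bool = False
) -> SignificantGeneList:
    """Keep genes whose index p-value is strictly below ``pcut``
    (a p-value "stronger than" the cutoff)."""
    if not (0.0 < pcut < 1.0):
        raise MappingError(f"pcut must lie in (0, 1), got {pcut}")
    if not index.index_snps and any(index.assignments.values()):
        select_index_snps(index)
    entries = [
        (gene, snp.rsid, snp.pvalue)
        for gene, snp in index.index_snps.items()
        if snp.pvalue < pcut
    ]
    entries.sort(key=lambda e: (e[2], e[0]))
    return SignificantGeneList(entries=entries, pcut=pcut, masked=masked)


def ld_prune(
    sig: SignificantGeneList,
    ld: LdTable,
    snps: Sequence[SnpRecord],
    r2_max: float = DEFAULT_R2_MAX,
    dist_bp: int = DEFAULT_DIST_BP,
) -> SignificantGeneList:
    """Greedy strongest-first pruning of the significant-gene list.

    Genes are visited in ascending index-p order; a gene is retained iff
    its index SNP is independent of every already-retained index SNP
    (different chromosome, or |Δpos| > ``dist_bp``, or r² ≤ ``r2_max``).
    Dropped genes are recorded against the retained gene that absorbed
    them and reported via the ``dropped`` attribute of the result.
    """
    coords: Dict[str, Tuple[str, int]] = {s.rsid: (s.chrom, s.pos) for s in snps}
    for _, rsid, _ in sig.entries:
        if rsid not in coords:
            raise MappingError(f"index SNP {rsid!r} has no known coordinate")

    ordered = sorted(
        sig.entries, key=lambda e: (e[2], coords[e[1]][0], coords[e[1]][1], e[1])
    )
    retained: List[Tuple[str, str, float]] = []
    dropped: List[Tuple[str, str]] = []  # (dropped gene, absorbing gene)
    for gene, rsid, pval in ordered:
        chrom, pos = coords[rsid]
        absorber = None
        for kept_gene, kept_rsid, _ in retained:
            k_chrom, k_pos = coords[kept_rsid]
            if chrom != k_chrom:
                continue
            if abs(pos - k_pos) > dist_bp:
                continue
            if ld.r2(rsid, kept_rsid) <= r2_max:
                continue
            absorber = kept_gene
            break
        if absorber is None:
            retained.append((gene, rsid, pval))
        else:
            dropped.append((gene, absorber))
    pruned = replace(sig, entries=retained, pruned=True)
    pruned.dropped = dropped  # type: ignore[attr-defined]
    return pruned


def score_significant_genes(
    snps: Sequence[SnpRecord],
    genes: Sequence[GeneRecord],
    ld: LdTable,
    pcut: float,
    mask: Optional[RegionMask] = None,
    window_bp: int = DEFAULT_WINDOW_BP,
    r2_max: float = DEFAULT_R2_MAX,
    dist_bp: int = DEFAULT_DIST_BP,
) -> Tuple[SignificantGeneList, GeneSnpIndex]:
    """Run the full observed-data scoring stage: mask, map, select index
    SNPs, flag significant genes, LD-prune.  Returns the pruned list and
    the gene/SNP index (for mappable-gene universe and SNP-count
    weights)."""
    kept = apply_region_mask(snps, mask)
    index = map_snps_to_genes(kept, genes, window_bp=window_bp)
    select_index_snps(index)
    flagged = flag_significant_genes(index, pcut, masked=mask is not None and len(mask) > 0)
    pruned = ld_prune(flagged, ld, kept, r2_max=r2_max, dist_bp=dist_bp)
    return pruned, index
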