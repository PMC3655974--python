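"""Independent brute-force reference for the mapping/pruning stage.

Deliberately naive (nested loops, no indexing) so it can serve as an
oracle for the production implementation.
"""

from typing import List, Tuple


def bruteforce_significant_genes(
    snps,
    genes,
    ld,
    pcut: float,
    mask=None,
    window_bp: int = 20_000,
    r2_max: float = 0.2,
    dist_bp: int = 1_000_000,
) -> List[Tuple[str, str, float]]:
    """Mask -> assign -> index SNP -> flag -> greedy LD prune, all by
    exhaustive loops.  Returns (gene, index rsid, index p) retained."""
    kept_snps = []
    for s in snps:
        inside = False
        if mask is not None:
            for chrom, start, end in mask.intervals:
                if s.chrom == chrom and start <= s.pos <= end:
                    inside = True
        if not inside:
            kept_snps.append(s)

    flagged = []
    for g in genes:
        assigned = [
            s for s in kept_snps
            if s.chrom == g.chrom and g.start - window_bp <= s.pos <= g.end + window_bp
        ]
        if not assigned:
            continue
        index_snp = sorted(assigned, key=lambda s: (s.pvalue, s.pos, s.rsid))[0]
        if index_snp.pvalue < pcut:
            flagged.append((g.symbol, index_snp.rsid, index_snp.pvalue))

    coords = {s.rsid: (s.chrom, s.pos) for s in snps}
    flagged.sort(key=lambda e: (e[2], coords[e[1]][0], coords[e[1]][1], e[1]))
    retained: List[Tuple[str, str, float]] = []
    for gene, rsid, p in flagged:
        chrom, pos = coords[rsid]
        independent_of_all = True
        for _, kept_rsid, _ in retained:
            k_chrom, k_pos = coords[kept_rsid]
            same_chrom = chrom == k_chrom
            near = abs(pos - k_pos) <= dist_bp
            r2 = 1.0 if rsid == kept_rsid else ld.r2(rsid, kept_rsid)
            if same_chrom and near and r2 > r2_max:
                independent_of_all = False
        if independent_of_all:
            retained.append((gene, rsid, p))
    return retained
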