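"""Synthetic GWAS inputs with the statistical structure the analysis assumes.

The generator emulates, at desk scale, the features of a genome-wide
summary-statistics panel that the enrichment method relies on:

* non-overlapping genes with log-normal lengths spread over several
  chromosomes, separated by intergenic gaps wide enough that a fraction
  of SNPs maps to no gene;
* SNP counts proportional to sequence length (Poisson), denser inside
  genes than between them, as on gene-centric genotyping arrays;
* null p-values that are exactly uniform marginally but correlated
  within LD blocks through a Gaussian copula (blocks of consecutive
  SNPs share a latent factor with pairwise correlation ``ld_rho``; the
  accompanying LD table reports those pairs with r² = ld_rho²);
* an optional spiked gene set in which a fraction ``spike_fraction`` of
  the member genes carries true signal: the p-values of their
  index-eligible SNPs are redrawn from Beta(a, 1) with a < 1;
* an interaction-evidence table with planted curation outcomes.

Every product is deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import ndtr

from . import io as cio
from .models import (
    EvidenceRecord,
    GeneRecord,
    GeneSet,
    InteractionClass,
    LdTable,
    RegionMask,
    SetSource,
    SnpRecord,
)

_P_FLOOR = 1e-300  # keep generated p-values inside (0, 1]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Defaults describe the reference desk-scale study: 300 genes with
    log-normal lengths (median 20 kb), 1 SNP/kb inside genes, LD blocks
    of 10 SNPs with latent correlation 0.7, and a 30-gene spiked set in
    which 30% of the genes carry Beta(0.1, 1) signal.
    """

    n_genes: int = 300
    gene_length_median: float = 20_000.0
    gene_length_sigma: float = 0.8  # sigma of log-length
    snp_density_per_kb: float = 1.0
    intergenic_density_factor: float = 0.2  # arrays tag intergenic DNA more sparsely
    mean_intergenic_gap: float = 60_000.0
    min_intergenic_gap: int = 2_000
    n_chromosomes: int = 5
    ld_block_size: int = 10
    ld_rho: float = 0.7
    spiked_set_size: int = 30
    spike_fraction: float = 0.3
    alt_p_shape: float = 0.1
    n_sets: int = 13
    n_evidence_genes: int = 12
    mask_intervals: Optional[Tuple[Tuple[str, int, int], ...]] = None
    max_chrom_bp: int = 500_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_chromosomes, self.ld_block_size, self.n_sets) < 1:
            raise ValueError("all sizes must be positive")
        if self.spiked_set_size < 1 or self.spiked_set_size > self.n_genes:
            raise ValueError("spiked_set_size must lie in [1, n_genes]")
        if not (0.0 <= self.spike_fraction <= 1.0):
            raise ValueError("spike_fraction must lie in [0, 1]")
        if not (0.0 < self.alt_p_shape <= 1.0):
            raise ValueError("alt_p_shape must lie in (0, 1]")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must lie in [0, 1)")
        if self.snp_density_per_kb < 0 or self.intergenic_density_factor < 0:
            raise ValueError("densities must be non-negative")


# ---------------------------------------------------------------------------
# Genome


def generate_genome(
    cfg: SimConfig, rng: np.random.Generator
) -> Tuple[List[GeneRecord], List[Tuple[str, int]]]:
    """Lay out non-overlapping genes and SNP positions.

    Genes are packed chromosome by chromosome with exponential
    intergenic gaps; SNP counts are Poisson with mean length x density
    (scaled down by ``intergenic_density_factor`` between genes), so
    SNPs in the middle of wide gaps map to no gene.
    """
    genes: List[GeneRecord] = []
    snp_positions: List[Tuple[str, int]] = []
    per_chrom = [len(a) for a in np.array_split(np.arange(cfg.n_genes), cfg.n_chromosomes)]
    gene_id = 0
    mu = np.log(cfg.gene_length_median)
    for c in range(cfg.n_chromosomes):
        chrom = str(c + 1)
        cursor = 0  # last occupied base
        chrom_positions: List[int] = []
        for _ in range(per_chrom[c]):
            gap = cfg.min_intergenic_gap + rng.exponential(
                max(cfg.mean_intergenic_gap - cfg.min_intergenic_gap, 1.0)
            )
            length = max(500, int(round(rng.lognormal(mu, cfg.gene_length_sigma))))
            start = cursor + int(round(gap)) + 1
            end = start + length - 1
            if end > cfg.max_chrom_bp:
                raise ValueError(
                    f"infeasible packing: chromosome {chrom} exceeds "
                    f"{cfg.max_chrom_bp} bp"
                )
            gene_id += 1
            genes.append(GeneRecord(f"G{gene_id:04d}", chrom, start, end))
            # intergenic SNPs in the gap just before this gene
            gap_len = start - cursor - 1
            n_inter = rng.poisson(
                gap_len / 1000.0 * cfg.snp_density_per_kb * cfg.intergenic_density_factor
            )
            if n_inter > 0 and gap_len > 0:
                chrom_positions.extend(
                    int(p) for p in rng.integers(cursor + 1, start, size=n_inter)
                )
            # genic SNPs
            n_genic = rng.poisson(length / 1000.0 * cfg.snp_density_per_kb)
            if n_genic > 0:
                chrom_positions.extend(
                    int(p) for p in rng.integers(start, end + 1, size=n_genic)
                )
            cursor = end
        for p in sorted(set(chrom_positions)):
            snp_positions.append((chrom, p))
    return genes, snp_positions


# ---------------------------------------------------------------------------
# Null p-values with LD blocks


def generate_null_pvalues(
    snp_positions: Sequence[Tuple[str, int]],
    cfg: SimConfig,
    rng: np.random.Generator,
) -> Tuple[List[SnpRecord], LdTable]:
    """Draw block-correlated null p-values via a Gaussian copula.

    Within each block of ``ld_block_size`` consecutive SNPs (per
    chromosome) the latent Gaussians share pairwise correlation
    ``ld_rho``; the probability-integral transform makes every marginal
    exactly uniform.  The LD table lists all within-block pairs with
    r² = ld_rho² (empty when ``ld_rho`` is 0).
    """
    ordered = sorted(
        range(len(snp_positions)),
        key=lambda i: (_chrom_sort_key(snp_positions[i][0]), snp_positions[i][1]),
    )
    rho = cfg.ld_rho
    records: List[SnpRecord] = []
    ld = LdTable()
    rsid_counter = 0
    # group by chromosome in sorted order
    by_chrom: Dict[str, List[int]] = {}
    for i in ordered:
        by_chrom.setdefault(snp_positions[i][0], []).append(i)
    for chrom in sorted(by_chrom, key=_chrom_sort_key):
        idx = by_chrom[chrom]
        n = len(idx)
        blocks = np.arange(n) // cfg.ld_block_size
        n_blocks = int(blocks[-1]) + 1 if n else 0
        shared = rng.normal(size=n_blocks)
        noise = rng.normal(size=n)
        z = np.sqrt(rho) * shared[blocks] + np.sqrt(1.0 - rho) * noise
        pvals = np.clip(ndtr(z), _P_FLOOR, 1.0)
        rsids = []
        for k, i in enumerate(idx):
            rsid_counter += 1
            rsid = f"rs{rsid_counter:07d}"
            rsids.append(rsid)
            records.append(
                SnpRecord(
                    rsid=rsid,
                    chrom=chrom,
                    pos=snp_positions[i][1],
                    pvalue=float(pvals[k]),
                )
            )
        if rho > 0.0:
            r2 = rho * rho
            for b in range(n_blocks):
                members = rsids[b * cfg.ld_block_size : (b + 1) * cfg.ld_block_size]
                for x in range(len(members)):
                    for y in range(x + 1, len(members)):
                        ld.add(members[x], members[y], r2)
    return records, ld


def _chrom_sort_key(chrom: str):
    return (0, int(chrom)) if chrom.isdigit() else (1, chrom)


# ---------------------------------------------------------------------------
# Spiked signal


def spike_signal(
    snps: Sequence[SnpRecord],
    gene_set: GeneSet,
    genes: Sequence[GeneRecord],
    cfg: SimConfig,
    rng: np.random.Generator,
    window_bp: int = 20_000,
) -> List[SnpRecord]:
    """Inject association signal into a gene set.

    For a fraction ``spike_fraction`` of the set's genes (chosen at
    random), every index-eligible SNP — any SNP within ``window_bp`` of
    the gene interval — has its p-value replaced by a Beta(a, 1) draw
    with ``a = alt_p_shape``; all other SNPs are untouched.
    """
    by_symbol = {g.symbol: g for g in genes}
    unknown = sorted(gene_set.genes - set(by_symbol))
    if unknown:
        raise ValueError(f"spiked set names unknown gene(s): {', '.join(unknown)}")
    members = sorted(gene_set.genes)
    n_spike = int(round(cfg.spike_fraction * len(members)))
    if n_spike == 0:
        return list(snps)
    chosen = rng.choice(members, size=n_spike, replace=False)
    targets: set = set()
    for symbol in chosen:
        g = by_symbol[symbol]
        for i, s in enumerate(snps):
            if s.chrom == g.chrom and g.start - window_bp <= s.pos <= g.end + window_bp:
                targets.add(i)
    target_idx = sorted(targets)
    new_p = np.clip(rng.beta(cfg.alt_p_shape, 1.0, size=len(target_idx)), _P_FLOOR, 1.0)
    out = list(snps)
    for j, i in enumerate(target_idx):
        out[i] = replace(out[i], pvalue=float(new_p[j]))
    return out


# ---------------------------------------------------------------------------
# Evidence table with planted curation outcomes


def generate_evidence_table(
    cfg: SimConfig, rng: np.random.Generator
) -> Tuple[List[EvidenceRecord], FrozenSet[str]]:
    """Emit evidence records cycling through the four curation cases.

    Case 0: two independent sources, direct -> kept.
    Case 1: one source, one method, direct -> dropped.
    Case 2: one source, two distinct methods, direct -> kept.
    Case 3: indirect records only -> dropped.

    Returns the records (in random order) and the planted keep set.
    """
    records: List[EvidenceRecord] = []
    expected: List[str] = []
    env = "ENVP1"
    direct = InteractionClass.DIRECT
    indirect = InteractionClass.INDIRECT
    for i in range(cfg.n_evidence_genes):
        gene = f"CURG{i + 1:02d}"
        case = i % 4
        if case == 0:
            records.append(EvidenceRecord(env, gene, f"PMID{i}a", "y2h", direct))
            records.append(EvidenceRecord(env, gene, f"PMID{i}b", "y2h", direct))
            expected.append(gene)
        elif case == 1:
            records.append(EvidenceRecord(env, gene, f"PMID{i}a", "y2h", direct))
        elif case == 2:
            records.append(EvidenceRecord(env, gene, f"PMID{i}a", "y2h", direct))
            records.append(EvidenceRecord(env, gene, f"PMID{i}a", "co-ip", direct))
            expected.append(gene)
        else:
            records.append(EvidenceRecord(env, gene, f"PMID{i}a", "y2h", indirect))
            records.append(EvidenceRecord(env, gene, f"PMID{i}b", "co-ip", indirect))
    order = rng.permutation(len(records))
    return [records[i] for i in order], frozenset(expected)


# ---------------------------------------------------------------------------
# Whole datasets


@dataclass
class SimulatedDataset:
    """All inputs of one synthetic study, in memory."""

    config: SimConfig
    genes: List[GeneRecord]
    snps_null: List[SnpRecord]  # uniform p-values (no signal)
    snps: List[SnpRecord]  # spiked panel when spike_fraction > 0
    ld: LdTable
    sets: List[GeneSet]
    spiked_set_name: str
    mask: RegionMask
    evidence: List[EvidenceRecord]
    evidence_expected: FrozenSet[str]


def _default_mask(genes: Sequence[GeneRecord]) -> RegionMask:
    """A mask over a central run of chromosome-1 genes, standing in for
    a high-LD exclusion region."""
    chrom1 = [g for g in genes if g.chrom == "1"]
    if not chrom1:
        return RegionMask(intervals=(), label="synthetic exclusion region")
    n = len(chrom1)
    lo = n // 4
    hi = min(n, lo + max(2, n // 10))
    block = chrom1[lo:hi]
    return RegionMask(
        intervals=(("1", block[0].start, block[-1].end),),
        label="synthetic exclusion region",
    )


def generate_dataset(cfg: SimConfig) -> SimulatedDataset:
    """Generate a complete synthetic study from ``cfg.seed``."""
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    genes, positions = generate_genome(cfg, rng)
    snps_null, ld = generate_null_pvalues(positions, cfg, rng)

    symbols = [g.symbol for g in genes]
    sets: List[GeneSet] = []
    spiked_members = rng.choice(symbols, size=cfg.spiked_set_size, replace=False)
    spiked = GeneSet("SPIKED", SetSource.CURATED, frozenset(spiked_members))
    sets.append(spiked)
    for k in range(cfg.n_sets - 1):
        members = rng.choice(symbols, size=cfg.spiked_set_size, replace=False)
        sets.append(GeneSet(f"NULL{k + 1:02d}", SetSource.CURATED, frozenset(members)))

    snps = (
        spike_signal(snps_null, spiked, genes, cfg, rng)
        if cfg.spike_fraction > 0
        else list(snps_null)
    )
    mask = (
        RegionMask(intervals=cfg.mask_intervals, label="synthetic exclusion region")
        if cfg.mask_intervals is not None
        else _default_mask(genes)
    )
    evidence, expected = generate_evidence_table(cfg, rng)
    return SimulatedDataset(
        config=cfg,
        genes=genes,
        snps_null=snps_null,
        snps=snps,
        ld=ld,
        sets=sets,
        spiked_set_name=spiked.name,
        mask=mask,
        evidence=evidence,
        evidence_expected=expected,
    )


def write_dataset(ds: SimulatedDataset, outdir) -> Dict[str, Path]:
    """Persist a dataset in the documented flat-file formats.

    Output is byte-identical for a fixed ``SimConfig.seed``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "gwas": outdir / "gwas.tsv",
        "genes": outdir / "genes.bed",
        "ld": outdir / "ld.tsv",
        "sets": outdir / "sets.gmt",
        "mask": outdir / "mask.bed",
        "evidence": outdir / "evidence.tsv",
    }
    cio.write_gwas_summary(ds.snps, paths["gwas"])
    cio.write_gene_annotation(ds.genes, paths["genes"])
    cio.write_ld_table(ds.ld, paths["ld"])
    cio.write_gene_sets(ds.sets, paths["sets"])
    cio.write_region_mask(ds.mask, paths["mask"])
    cio.write_evidence_table(ds.evidence, paths["evidence"])
    return paths
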