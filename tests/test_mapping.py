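"""SNP-to-gene mapping, index-SNP selection, significance flagging, LD pruning."""

import numpy as np
import pytest

import candidate_interactome as ci
from candidate_interactome.errors import MappingError
from bruteforce import bruteforce_significant_genes


# ---------------------------------------------------------------------------
# region mask


def test_mask_bounds_are_inclusive(toy_snps):
    mask = ci.RegionMask(intervals=(("1", 5_000, 12_000),))
    kept = ci.apply_region_mask(toy_snps, mask)
    removed = {s.rsid for s in toy_snps} - {s.rsid for s in kept}
    assert removed == {"rs1", "rs2"}  # rs1 sits exactly on the start bound


def test_empty_mask_is_identity(toy_snps):
    assert ci.apply_region_mask(toy_snps, None) == toy_snps
    assert ci.apply_region_mask(toy_snps, ci.RegionMask(intervals=())) == toy_snps


def test_mask_removes_exactly_covered_snps(toy_snps):
    mask = ci.RegionMask(intervals=(("2", 1, 20_000),))
    covered = [s for s in toy_snps if s.chrom == "2" and s.pos <= 20_000]
    kept = ci.apply_region_mask(toy_snps, mask)
    assert len(kept) == len(toy_snps) - len(covered) and len(covered) == 3


# ---------------------------------------------------------------------------
# window mapping


def test_window_boundary_is_inclusive_at_exactly_20kb():
    gene = ci.GeneRecord("G", "1", 10_000, 20_000)
    inside = ci.SnpRecord("a", "1", 40_000, 0.5)   # end + 20 kb exactly
    outside = ci.SnpRecord("b", "1", 40_001, 0.5)
    upstream = ci.SnpRecord("c", "1", 5_000, 0.5)  # 5 kb upstream
    index = ci.map_snps_to_genes([inside, outside, upstream], [gene])
    assert set(index.rsids("G")) == {"a", "c"}


def test_snp_may_serve_multiple_genes_and_unmappable_recorded(toy_snps, toy_genes):
    index = ci.map_snps_to_genes(toy_snps, toy_genes)
    # rs4 at 40 kb is exactly 20 kb from both GA's end and GB's start:
    # assigned to both genes (no nearest-gene arbitration)
    assert "rs4" in index.rsids("GA") and "rs4" in index.rsids("GB")
    # rs9 is within 20 kb of GD on chromosome 2
    assert "rs9" in index.rsids("GD")
    assert index.unmappable == frozenset()


def test_mapping_matches_double_loop_on_toy_instance(toy_snps, toy_genes):
    index = ci.map_snps_to_genes(toy_snps, toy_genes, window_bp=20_000)
    for g in toy_genes:
        expected = {
            s.rsid for s in toy_snps
            if s.chrom == g.chrom and g.start - 20_000 <= s.pos <= g.end + 20_000
        }
        assert set(index.rsids(g.symbol)) == expected


# ---------------------------------------------------------------------------
# index SNP selection


def test_index_snp_is_minimum_pvalue(toy_snps, toy_genes):
    index = ci.select_index_snps(ci.map_snps_to_genes(toy_snps, toy_genes))
    assert index.index_snps["GA"].rsid == "rs2"  # 0.01 beats 0.20/0.04
    for gene, snp in index.index_snps.items():
        assert snp.pvalue == min(
            index.snps[i].pvalue for i in index.assignments[gene]
        )


def test_index_snp_tie_broken_by_position_then_rsid():
    gene = ci.GeneRecord("G", "1", 1, 1_000)
    snps = [
        ci.SnpRecord("rsB", "1", 200, 0.01),
        ci.SnpRecord("rsA", "1", 100, 0.01),
        ci.SnpRecord("rsC", "1", 100, 0.01),
    ]
    index = ci.select_index_snps(ci.map_snps_to_genes(snps, [gene]))
    assert index.index_snps["G"].rsid == "rsA"  # pos 100 first, then rsA < rsC


# ---------------------------------------------------------------------------
# significance flagging (strict inequality at P-CUT)


def test_pcut_is_strict(toy_snps, toy_genes):
    index = ci.select_index_snps(ci.map_snps_to_genes(toy_snps, toy_genes))
    sig = ci.flag_significant_genes(index, 0.05)
    # GD's index p is exactly 0.049 < 0.05 -> in; an index p == pcut would be out
    assert "GD" in sig.genes()
    sig_at_049 = ci.flag_significant_genes(index, 0.049)
    assert "GD" not in sig_at_049.genes()
    for _, _, p in sig.entries:
        assert p < 0.05


# ---------------------------------------------------------------------------
# LD pruning


def _two_gene_sig(p1=0.001, p2=0.02, pos2=510_000):
    snps = [
        ci.SnpRecord("rsX", "1", 10_000, p1),
        ci.SnpRecord("rsY", "1", pos2, p2),
    ]
    genes = [
        ci.GeneRecord("G1", "1", 5_000, 15_000),
        ci.GeneRecord("G2", "1", pos2 - 5_000, pos2 + 5_000),
    ]
    index = ci.select_index_snps(ci.map_snps_to_genes(snps, genes))
    return ci.flag_significant_genes(index, 0.05), snps


def test_dependent_pair_drops_larger_p_gene():
    sig, snps = _two_gene_sig()
    ld = ci.LdTable([("rsX", "rsY", 0.5)])
    pruned = ci.ld_prune(sig, ld, snps)
    assert pruned.genes() == ["G1"]
    assert pruned.dropped == [("G2", "G1")]


def test_r2_exactly_at_threshold_counts_as_independent():
    sig, snps = _two_gene_sig()
    pruned = ci.ld_prune(sig, ci.LdTable([("rsX", "rsY", 0.2)]), snps)
    assert set(pruned.genes()) == {"G1", "G2"}


def test_high_r2_beyond_distance_limit_counts_as_independent():
    sig, snps = _two_gene_sig(pos2=1_210_000)  # 1200 kb apart
    pruned = ci.ld_prune(sig, ci.LdTable([("rsX", "rsY", 0.9)]), snps)
    assert set(pruned.genes()) == {"G1", "G2"}


def test_empty_ld_table_retains_all_and_pruning_is_idempotent(toy_snps, toy_genes):
    index = ci.select_index_snps(ci.map_snps_to_genes(toy_snps, toy_genes))
    sig = ci.flag_significant_genes(index, 0.05)
    once = ci.ld_prune(sig, ci.LdTable(), toy_snps)
    # distinct index SNPs with r2 = 0 are all independent
    assert len(once) == len(sig)
    twice = ci.ld_prune(once, ci.LdTable(), toy_snps)
    assert twice.entries == once.entries


def test_unknown_index_snp_coordinate_is_error(toy_snps, toy_genes):
    index = ci.select_index_snps(ci.map_snps_to_genes(toy_snps, toy_genes))
    sig = ci.flag_significant_genes(index, 0.05)
    with pytest.raises(MappingError):
        ci.ld_prune(sig, ci.LdTable(), toy_snps[:2])


# ---------------------------------------------------------------------------
# full stage vs brute force


def _random_instance(rng):
    n_genes, n_snps = 5, 20
    genes = []
    for i in range(n_genes):
        chrom = str(rng.integers(1, 3))
        start = int(rng.integers(1, 200_000))
        genes.append(ci.GeneRecord(f"G{i}", chrom, start, start + int(rng.integers(1_000, 30_000))))
    snps = [
        ci.SnpRecord(
            f"rs{i}",
            str(rng.integers(1, 3)),
            int(rng.integers(1, 260_000)),
            float(rng.uniform(1e-6, 1.0)),
        )
        for i in range(n_snps)
    ]
    pairs = []
    for i in range(n_snps):
        for j in range(i + 1, n_snps):
            if rng.uniform() < 0.15:
                pairs.append((f"rs{i}", f"rs{j}", float(rng.uniform())))
    mask = None
    if rng.uniform() < 0.5:
        start = int(rng.integers(1, 150_000))
        mask = ci.RegionMask(intervals=((str(rng.integers(1, 3)), start, start + 50_000),))
    pcut = float(rng.choice([0.05, 0.2, 0.5]))
    return snps, genes, ci.LdTable(pairs), mask, pcut


@pytest.mark.parametrize("seed", range(12))
def test_full_stage_equals_bruteforce_enumeration(seed):
    rng = np.random.default_rng(seed)
    snps, genes, ld, mask, pcut = _random_instance(rng)
    pruned, _ = ci.score_significant_genes(snps, genes, ld, pcut, mask=mask)
    expected = bruteforce_significant_genes(snps, genes, ld, pcut, mask=mask)
    assert pruned.entries == expected


def test_mask_disjoint_from_snps_leaves_lists_identical(toy_snps, toy_genes):
    mask = ci.RegionMask(intervals=(("9", 1, 10**9),))
    with_mask, _ = ci.score_significant_genes(toy_snps, toy_genes, ci.LdTable(), 0.05, mask=mask)
    without, _ = ci.score_significant_genes(toy_snps, toy_genes, ci.LdTable(), 0.05)
    assert with_mask.entries == without.entries
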