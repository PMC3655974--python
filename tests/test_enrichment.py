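"""Bootstrap enrichment: sampling contract, empirical p estimator,
enumeration-oracle equivalence, simulated studies, full runs."""

import math

import numpy as np
import pytest

import candidate_interactome as ci
from candidate_interactome.enrichment import (
    EnrichmentConfig,
    empirical_p,
    replicate_counts,
    sample_random_gene_set,
    simulate_studies,
)
from candidate_interactome.mapping import SignificantGeneList
from candidate_interactome.models import GeneSet, SetSource


def _siglist(genes, pcut=0.05):
    entries = [(g, f"rs_{g}", 0.01) for g in genes]
    return SignificantGeneList(entries=entries, pcut=pcut, pruned=True)


def _set(genes, name="S"):
    return GeneSet(name, SetSource.CURATED, frozenset(genes))


# ---------------------------------------------------------------------------
# observed count


def test_observed_count_intersection_cases():
    pruned = _siglist(["A", "B", "C"])
    assert ci.observed_count(_set(["X", "Y"]), pruned) == 0
    assert ci.observed_count(_set(["A", "B", "C", "D"]), pruned) == 3  # superset
    assert ci.observed_count(_set(["B", "X"]), pruned) == 1


# ---------------------------------------------------------------------------
# weighted sampling without replacement


def test_zero_weight_gene_is_never_drawn(rng):
    universe = ["A", "B", "C", "D"]
    weights = [1.0, 1.0, 0.0, 1.0]
    for _ in range(2_000):
        gs = sample_random_gene_set(2, universe, weights, rng)
        assert "C" not in gs.genes
    with pytest.raises(ValueError, match="positive weight"):
        sample_random_gene_set(4, universe, weights, rng)


def test_inclusion_frequency_tracks_weights_three_to_one(rng):
    universe = ["heavy", "light"]
    weights = [3.0, 1.0]
    n = 20_000
    heavy = sum(
        "heavy" in sample_random_gene_set(1, universe, weights, rng).genes
        for _ in range(n)
    )
    # expected inclusion probability 0.75; allow 4 binomial sigmas
    sigma = math.sqrt(0.75 * 0.25 / n)
    assert abs(heavy / n - 0.75) < 4 * sigma


def test_sampling_whole_universe_returns_it():
    rng = np.random.default_rng(0)
    gs = sample_random_gene_set(3, ["A", "B", "C"], [1, 2, 3], rng)
    assert gs.genes == frozenset({"A", "B", "C"})


# ---------------------------------------------------------------------------
# empirical p estimator


def test_p_is_one_when_nothing_observed(rng):
    counts = replicate_counts(3, np.array([1.0, 0, 0, 0, 0, 0]), np.ones(6), 400, rng)
    assert empirical_p(0, counts) == 1.0


def test_p_hits_floor_when_all_replicates_below_observed():
    counts = np.zeros(500, dtype=int)
    assert empirical_p(1, counts) == pytest.approx(1 / 501)


def test_p_range_and_monotonicity_in_observed(rng):
    counts = replicate_counts(5, np.array([1.0] * 4 + [0.0] * 8), np.ones(12), 300, rng)
    ps = [empirical_p(obs, counts) for obs in range(6)]
    assert all(1 / 301 <= p <= 1.0 for p in ps)
    assert ps == sorted(ps, reverse=True)


def _exact_tail_hypergeom(n_universe, n_sig, set_size, observed):
    """P(overlap >= observed) by summation over the hypergeometric support."""
    total = math.comb(n_universe, set_size)
    acc = 0
    for k in range(observed, min(n_sig, set_size) + 1):
        acc += math.comb(n_sig, k) * math.comb(n_universe - n_sig, set_size - k)
    return acc / total


def test_exact_tail_agrees_with_literal_enumeration():
    """The closed-form tail equals exhaustive enumeration of all subsets."""
    from itertools import combinations

    n, k_sig, m, obs = 10, 4, 3, 2
    sig = set(range(k_sig))
    hits = sum(1 for c in combinations(range(n), m) if len(sig & set(c)) >= obs)
    assert _exact_tail_hypergeom(n, k_sig, m, obs) == pytest.approx(
        hits / math.comb(n, m)
    )


@pytest.mark.parametrize("n_sig,set_size,observed", [(8, 5, 3), (10, 4, 2), (5, 10, 4)])
def test_bootstrap_p_matches_hypergeometric_tail(n_sig, set_size, observed):
    """One SNP per gene, no LD, uniform weights: the replicate-count
    distribution is hypergeometric and the bootstrap p must approach its
    exact tail."""
    n_universe, B = 20, 4000
    universe = [f"G{i}" for i in range(n_universe)]
    sig01 = np.array([1.0] * n_sig + [0.0] * (n_universe - n_sig))
    rng = np.random.default_rng(n_sig * 100 + set_size)
    counts = replicate_counts(set_size, sig01, np.ones(n_universe), B, rng)
    p_hat = empirical_p(observed, counts)
    p_exact = _exact_tail_hypergeom(n_universe, n_sig, set_size, observed)
    tol = 3 * math.sqrt(p_exact * (1 - p_exact) / B) + 1 / (B + 1)
    assert abs(p_hat - p_exact) <= tol


# ---------------------------------------------------------------------------
# simulated studies


def test_no_interactomes_gives_empty_expectation():
    cfg = EnrichmentConfig(n_replicates=10, n_studies=50)
    study = simulate_studies(cfg, {}, 0, np.random.default_rng(0))
    assert study.expected_n_significant_categories == 0.0
    assert study.study_p == 1.0


def test_alpha_one_makes_every_interactome_significant(rng):
    cfg = EnrichmentConfig(n_replicates=50, n_studies=40, alpha_category=1.0)
    counts = {f"S{k}": rng.integers(0, 5, size=50) for k in range(3)}
    study = simulate_studies(cfg, counts, 3, rng)
    assert study.expected_n_significant_categories == 3.0
    assert study.null_counts.min() == 3


def test_pseudo_observed_election_is_conservatively_calibrated(rng):
    """Under a complete null the expected number of significant
    categories is at most n_sets * alpha (ties make the empirical p
    conservative), and not degenerately zero."""
    cfg = EnrichmentConfig(n_replicates=400, n_studies=400, alpha_category=0.05)
    counts = {f"S{k}": rng.binomial(30, 0.3, size=400) for k in range(3)}
    study = simulate_studies(cfg, counts, 0, rng)
    rate = study.expected_n_significant_categories / 3
    mc = 3 * math.sqrt(0.05 * 0.95 / (cfg.n_studies * 3))
    assert rate <= cfg.alpha_category + mc
    assert study.study_p <= 1.0


# ---------------------------------------------------------------------------
# full runs on synthetic data


@pytest.fixture(scope="module")
def small_dataset():
    return ci.generate_dataset(ci.SimConfig(n_genes=80, n_sets=4, seed=9))


def test_run_enrichment_is_deterministic_given_seed(small_dataset):
    ds = small_dataset
    cfg = EnrichmentConfig(seed=5, n_replicates=150, n_studies=60)
    a = ci.run_enrichment(ds.snps, ds.genes, ds.ld, ds.sets, cfg, mask=ds.mask)
    b = ci.run_enrichment(ds.snps, ds.genes, ds.ld, ds.sets, cfg, mask=ds.mask)
    assert [(r.p_masked, r.p_unmasked) for r in a.results] == [
        (r.p_masked, r.p_unmasked) for r in b.results
    ]
    assert a.study_unmasked.study_p == b.study_unmasked.study_p


def test_disjoint_mask_reproduces_unmasked_pvalues(small_dataset):
    ds = small_dataset
    cfg = EnrichmentConfig(seed=2, n_replicates=150, n_studies=60)
    mask = ci.RegionMask(intervals=(("77", 1, 100),))
    run = ci.run_enrichment(ds.snps, ds.genes, ds.ld, ds.sets, cfg, mask=mask)
    for r in run.results:
        assert r.p_masked == r.p_unmasked


def test_tiny_pcut_sends_every_set_to_p_one(small_dataset):
    ds = small_dataset
    cfg = EnrichmentConfig(pcut=1e-12, seed=3, n_replicates=100, n_studies=50)
    run = ci.run_enrichment(ds.snps_null, ds.genes, ds.ld, ds.sets, cfg)
    assert all(r.p_unmasked == 1.0 for r in run.results)
    assert all(r.n_sig_observed == 0 for r in run.results)


def test_sensitivity_scan_emits_all_cutoffs_for_selected_sets(small_dataset):
    ds = small_dataset
    cfg = EnrichmentConfig(seed=4, n_replicates=100, n_studies=50)
    table = ci.sensitivity_scan(
        ds.snps, ds.genes, ds.ld, ds.sets, cfg, mask=ds.mask,
        pcuts=(0.005, 0.03, 0.05), scan_all=True,
    )
    assert set(table["pcut"]) == {0.005, 0.03, 0.05}
    assert set(table["interactome"]) == {s.name for s in ds.sets}
    assert set(table["mask_applied"]) == {True, False}
    assert ((table["p_value"] > 0) & (table["p_value"] <= 1)).all()


def test_single_pcut_scan_matches_run_enrichment(small_dataset):
    ds = small_dataset
    cfg = EnrichmentConfig(seed=6, n_replicates=100, n_studies=50)
    table = ci.sensitivity_scan(
        ds.snps, ds.genes, ds.ld, ds.sets, cfg, pcuts=(cfg.pcut,), scan_all=True
    )
    run = ci.run_enrichment(ds.snps, ds.genes, ds.ld, ds.sets, cfg)
    by_name = dict(zip(table["interactome"], table["p_value"]))
    for r in run.results:
        assert by_name[r.name] == r.p_unmasked
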