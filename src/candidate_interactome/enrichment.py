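"""Two-level bootstrap enrichment of GWAS signals in gene sets.

Level one (per interactome): the observed statistic is the number of
set members on the LD-pruned significant-gene list.  Its null is built
by drawing B random gene sets of the same (mappable) size from the
mappable-gene universe and counting their significant members against
the *same* pruned list.  Random sets are drawn with probability
proportional to each gene's assigned-SNP count by default, which
corrects the gene-size / SNP-density bias: long or SNP-dense genes are
more likely to contain a sub-threshold SNP by chance, and the weighting
gives the random sets the same structural advantage.  The empirical
p-value uses the add-one estimator ``(1 + #{count_b >= observed}) /
(B + 1)``, so it is never 0 and at most 1.

Level two (study-wide): each of S simulated studies elects, per
interactome, one bootstrap replicate as pseudo-observed data, scores it
against counts resampled with replacement from the remaining
replicates, and records how many interactomes reach the category
significance threshold.  Comparing the real number of significant
interactomes with that null distribution yields the study-wide p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np

from .mapping import (
    DEFAULT_DIST_BP,
    DEFAULT_R2_MAX,
    DEFAULT_WINDOW_BP,
    SignificantGeneList,
    score_significant_genes,
)
from .models import GeneRecord, GeneSet, LdTable, RegionMask, SetSource, SnpRecord


@dataclass(frozen=True)
class EnrichmentConfig:
    """Tunable parameters of the bootstrap enrichment analysis.

    ``pcut`` is the SNP-level significance cutoff (P-CUT) used to flag
    genes; ``n_replicates`` (B) the number of random gene sets per
    interactome; ``n_studies`` (S) the number of simulated studies for
    the study-wide comparison; ``alpha_category`` the per-interactome
    significance level used when counting significant categories;
    ``size_weighted`` toggles SNP-count weighting of the random sets.
    """

    pcut: float = 0.05
    n_replicates: int = 5000
    n_studies: int = 1000
    alpha_category: float = 0.05
    seed: int = 0
    size_weighted: bool = True
    window_bp: int = DEFAULT_WINDOW_BP
    r2_max: float = DEFAULT_R2_MAX
    dist_bp: int = DEFAULT_DIST_BP

    def __post_init__(self) -> None:
        if not (0.0 < self.pcut < 1.0):
            raise ValueError(f"pcut must lie in (0, 1), got {self.pcut}")
        if self.n_replicates < 1 or self.n_studies < 1:
            raise ValueError("n_replicates and n_studies must be >= 1")
        if not (0.0 < self.alpha_category <= 1.0):
            raise ValueError("alpha_category must lie in (0, 1]")


@dataclass
class EnrichmentResult:
    """Per-interactome outcome.  ``n_mappable`` and ``n_sig_observed``
    refer to the run on the full SNP panel (no mask); masked-run counts
    are reported in the results sidecar."""

    name: str
    size: int
    source: SetSource
    n_mappable: int
    n_sig_observed: int
    p_masked: Optional[float]
    p_unmasked: float


@dataclass
class StudyWideResult:
    """Outcome of the simulated-study comparison for one analysis arm."""

    observed_n_significant_categories: int
    expected_n_significant_categories: float
    study_p: float
    null_counts: np.ndarray = field(repr=False, default_factory=lambda: np.array([]))


@dataclass
class EnrichmentRun:
    """Bundle returned by :func:`run_enrichment`."""

    results: List[EnrichmentResult]
    study_unmasked: StudyWideResult
    study_masked: Optional[StudyWideResult]
    config: EnrichmentConfig
    arm_details: Dict[str, dict] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Sampling primitives


def _as_weights(weights: Sequence[float], size: int) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if int((w > 0).sum()) < size:
        raise ValueError(
            f"cannot draw {size} genes: only {int((w > 0).sum())} have positive weight"
        )
    return w


def _weighted_sample_indices(
    size: int, weights: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Weighted sampling without replacement via exponential keys
    (Efraimidis–Spirakis): the ``size`` smallest values of
    ``Exp(1)/w_i`` are a sample drawn sequentially with probability
    proportional to the remaining weights."""
    with np.errstate(divide="ignore"):
        keys = rng.exponential(size=weights.shape) / weights
    if size >= keys.shape[0]:
        return np.arange(keys.shape[0])
    return np.argpartition(keys, size - 1)[:size]


def sample_random_gene_set(
    size: int,
    universe: Sequence[str],
    weights: Sequence[float],
    rng: np.random.Generator,
    name: str = "random",
) -> GeneSet:
    """Draw ``size`` distinct genes from ``universe`` with inclusion
    probability increasing in ``weights`` (SNP counts when size
    weighting is on, ones otherwise)."""
    if size > len(universe):
        raise ValueError(f"cannot draw {size} genes from a universe of {len(universe)}")
    w = _as_weights(weights, size)
    idx = _weighted_sample_indices(size, w, rng)
    return GeneSet(
        name=name,
        source=SetSource.CURATED,
        genes=frozenset(universe[i] for i in idx),
    )


def observed_count(gene_set: GeneSet, pruned: SignificantGeneList) -> int:
    """Number of set members on the pruned significant-gene list."""
    sig = set(pruned.genes())
    return len(gene_set.genes & sig)


def replicate_counts(
    set_size: int,
    sig_indicator: np.ndarray,
    weights: Sequence[float],
    n_replicates: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Significant-member counts of ``n_replicates`` random sets of
    ``set_size`` genes, drawn (weighted, without replacement) from a
    universe whose i-th gene is significant iff ``sig_indicator[i]``."""
    sig01 = np.asarray(sig_indicator, dtype=float)
    n = sig01.shape[0]
    if set_size == 0:
        return np.zeros(n_replicates, dtype=np.int64)
    w = _as_weights(weights, set_size)
    if set_size >= n:
        return np.full(n_replicates, int(sig01.sum()), dtype=np.int64)
    with np.errstate(divide="ignore"):
        keys = rng.exponential(size=(n_replicates, n)) / w
    idx = np.argpartition(keys, set_size - 1, axis=1)[:, :set_size]
    return sig01[idx].sum(axis=1).astype(np.int64)


def empirical_p(observed: int, counts: np.ndarray) -> float:
    """Add-one empirical p-value: ``(1 + #{count >= observed}) / (B + 1)``."""
    b = counts.shape[0]
    return float(1 + int((counts >= observed).sum())) / float(b + 1)


def empirical_enrichment_p(
    observed: int,
    set_size: int,
    pruned: SignificantGeneList,
    universe: Sequence[str],
    weights: Sequence[float],
    cfg: EnrichmentConfig,
    rng: np.random.Generator,
) -> float:
    """Empirical enrichment p-value of one gene set against B random
    size-matched sets scored on the same pruned list."""
    sig = set(pruned.genes())
    sig01 = np.fromiter((g in sig for g in universe), dtype=float, count=len(universe))
    counts = replicate_counts(set_size, sig01, weights, cfg.n_replicates, rng)
    return empirical_p(observed, counts)


# ---------------------------------------------------------------------------
# Study-wide simulated studies


def simulate_studies(
    cfg: EnrichmentConfig,
    counts_by_set: Mapping[str, np.ndarray],
    observed_n_significant: int,
    rng: np.random.Generator,
) -> StudyWideResult:
    """Simulate S studies from the per-interactome replicate counts.

    For each study and each interactome, one replicate count is elected
    pseudo-observed and scored against B counts resampled with
    replacement from the remaining replicates; the study records how
    many interactomes reach ``alpha_category``.  The real observed
    number of significant interactomes is then compared with that null
    distribution (add-one estimator, so ``study_p`` is in (0, 1]).
    """
    names = list(counts_by_set)
    n_studies = cfg.n_studies
    if not names:
        return StudyWideResult(
            observed_n_significant_categories=observed_n_significant,
            expected_n_significant_categories=0.0,
            study_p=1.0,
            null_counts=np.zeros(n_studies, dtype=np.int64),
        )
    sig_flags = np.zeros((n_studies, len(names)), dtype=bool)
    for k, name in enumerate(names):
        counts = np.asarray(counts_by_set[name])
        b = counts.shape[0]
        elected = rng.integers(b, size=n_studies)
        if b > 1:
            draws = rng.integers(b - 1, size=(n_studies, b))
            draws += draws >= elected[:, None]
        else:
            draws = np.zeros((n_studies, b), dtype=np.int64)
        exceed = (counts[draws] >= counts[elected][:, None]).sum(axis=1)
        pvals = (1.0 + exceed) / (b + 1.0)
        sig_flags[:, k] = pvals <= cfg.alpha_category
    null_counts = sig_flags.sum(axis=1).astype(np.int64)
    study_p = float(1 + int((null_counts >= observed_n_significant).sum())) / float(
        n_studies + 1
    )
    return StudyWideResult(
        observed_n_significant_categories=observed_n_significant,
        expected_n_significant_categories=float(null_counts.mean()),
        study_p=study_p,
        null_counts=null_counts,
    )


# ---------------------------------------------------------------------------
# Full analysis


def _score_arm(
    snps: Sequence[SnpRecord],
    genes: Sequence[GeneRecord],
    ld: LdTable,
    sets: Sequence[GeneSet],
    cfg: EnrichmentConfig,
    mask: Optional[RegionMask],
    seed_children: Sequence[np.random.SeedSequence],
) -> dict:
    pruned, index = score_significant_genes(
        snps,
        genes,
        ld,
        cfg.pcut,
        mask=mask,
        window_bp=cfg.window_bp,
        r2_max=cfg.r2_max,
        dist_bp=cfg.dist_bp,
    )
    universe = index.mappable_genes
    universe_index = {g: i for i, g in enumerate(universe)}
    weights = (
        np.array([index.snp_count(g) for g in universe], dtype=float)
        if cfg.size_weighted
        else np.ones(len(universe))
    )
    sig = set(pruned.genes())
    sig01 = np.fromiter((g in sig for g in universe), dtype=float, count=len(universe))

    per_set: Dict[str, dict] = {}
    counts_by_set: Dict[str, np.ndarray] = {}
    for k, gs in enumerate(sets):
        rng = np.random.default_rng(seed_children[k])
        mappable = [g for g in gs.genes if g in universe_index]
        obs = len(set(mappable) & sig)
        counts = replicate_counts(len(mappable), sig01, weights, cfg.n_replicates, rng)
        p = empirical_p(obs, counts)
        per_set[gs.name] = {"n_mappable": len(mappable), "n_sig_observed": obs, "p": p}
        counts_by_set[gs.name] = counts
    observed_nsig = sum(1 for d in per_set.values() if d["p"] <= cfg.alpha_category)
    study = simulate_studies(
        cfg, counts_by_set, observed_nsig, np.random.default_rng(seed_children[-1])
    )
    return {
        "pruned": pruned,
        "index": index,
        "per_set": per_set,
        "study": study,
        "n_significant_genes": len(pruned),
        "n_mappable_genes": len(universe),
    }


def run_enrichment(
    snps: Sequence[SnpRecord],
    genes: Sequence[GeneRecord],
    ld: LdTable,
    sets: Sequence[GeneSet],
    cfg: EnrichmentConfig,
    mask: Optional[RegionMask] = None,
) -> EnrichmentRun:
    """Run the full enrichment analysis, twice when a mask is supplied
    (mask applied / not applied).

    Both arms consume identical derived seed streams, so when the mask
    removes no SNP the two arms produce identical p-values and the runs
    stay comparable in general.
    """
    sets = list(sets)
    root = np.random.SeedSequence(cfg.seed)
    children = root.spawn(len(sets) + 1)

    unmasked = _score_arm(snps, genes, ld, sets, cfg, None, children)
    masked = (
        _score_arm(snps, genes, ld, sets, cfg, mask, children)
        if mask is not None
        else None
    )

    results = []
    for gs in sets:
        u = unmasked["per_set"][gs.name]
        m = masked["per_set"][gs.name] if masked is not None else None
        results.append(
            EnrichmentResult(
                name=gs.name,
                size=len(gs),
                source=gs.source,
                n_mappable=u["n_mappable"],
                n_sig_observed=u["n_sig_observed"],
                p_masked=m["p"] if m is not None else None,
                p_unmasked=u["p"],
            )
        )
    return EnrichmentRun(
        results=results,
        study_unmasked=unmasked["study"],
        study_masked=masked["study"] if masked is not None else None,
        config=cfg,
        arm_details={
            "unmasked": {k: v for k, v in unmasked.items() if k in ("per_set", "n_significant_genes", "n_mappable_genes")},
            **(
                {"masked": {k: v for k, v in masked.items() if k in ("per_set", "n_significant_genes", "n_mappable_genes")}}
                if masked is not None
                else {}
            ),
        },
    )


def sensitivity_scan(
    snps: Sequence[SnpRecord],
    genes: Sequence[GeneRecord],
    ld: LdTable,
    sets: Sequence[GeneSet],
    cfg: EnrichmentConfig,
    mask: Optional[RegionMask] = None,
    pcuts: Sequence[float] = (0.005, 0.03, 0.05),
    sets_to_scan: Optional[Sequence[str]] = None,
    scan_all: bool = False,
):
    """Re-run the enrichment analysis at several SNP-level cutoffs.

    By default only the interactomes significant at the primary cutoff
    (``cfg.alpha_category`` in either arm) are re-analysed, mirroring
    the usual sensitivity re-analysis of associated sets;
    ``scan_all=True`` scans every set.  Returns a long-format pandas
    DataFrame with columns interactome, pcut, mask_applied, p_value.
    """
    import pandas as pd

    for pc in pcuts:
        if not (0.0 < pc < 1.0):
            raise ValueError(f"every pcut must lie in (0, 1), got {pc}")
    sets = list(sets)
    if scan_all:
        selected = [gs.name for gs in sets]
    elif sets_to_scan is not None:
        selected = list(sets_to_scan)
    else:
        base = run_enrichment(snps, genes, ld, sets, cfg, mask=mask)
        selected = [
            r.name
            for r in base.results
            if r.p_unmasked <= cfg.alpha_category
            or (r.p_masked is not None and r.p_masked <= cfg.alpha_category)
        ]
    chosen = [gs for gs in sets if gs.name in set(selected)]
    rows = []
    for pc in sorted(pcuts):
        if not chosen:
            break
        run = run_enrichment(snps, genes, ld, chosen, replace(cfg, pcut=pc), mask=mask)
        for r in run.results:
            rows.append(
                {
                    "interactome": r.name,
                    "pcut": pc,
                    "mask_applied": False,
                    "p_value": r.p_unmasked,
                }
            )
            if r.p_masked is not None:
                rows.append(
                    {
                        "interactome": r.name,
                        "pcut": pc,
                        "mask_applied": True,
                        "p_value": r.p_masked,
                    }
                )
    return pd.DataFrame(rows, columns=["interactome", "pcut", "mask_applied", "p_value"])
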