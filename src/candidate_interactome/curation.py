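"""Evidence-based curation of an environmental-factor interactome.

A human gene enters the curated interactome only when its physical,
direct interaction with the environmental factor is supported by at
least two independent sources, or by one source using at least two
distinct experimental approaches.  Indirect or unclassified interaction
records never contribute.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, Tuple

from .errors import CurationError
from .models import EvidenceRecord, GeneSet, InteractionClass, SetSource

logger = logging.getLogger(__name__)


def evaluate_gene_evidence(
    evidence: Iterable[EvidenceRecord],
) -> Dict[str, Tuple[bool, str]]:
    """Apply the curation rule gene by gene.

    Returns ``{gene_symbol: (kept, reason)}`` for every human gene that
    appears in the evidence (symbols compared case-insensitively and
    reported uppercase).  Only records with ``interaction_class ==
    direct`` count; source identifiers are compared after trimming and
    methods case-insensitively after trimming.
    """
    per_gene: Dict[str, Dict[str, set]] = {}
    seen_genes: set = set()
    for rec in evidence:
        gene = rec.human_gene.strip().upper()
        seen_genes.add(gene)
        if rec.interaction_class is not InteractionClass.DIRECT:
            continue
        sources = per_gene.setdefault(gene, {})
        sources.setdefault(rec.source_id.strip(), set()).add(rec.method.strip().lower())

    verdicts: Dict[str, Tuple[bool, str]] = {}
    for gene in sorted(seen_genes):
        sources = per_gene.get(gene, {})
        if len(sources) >= 2:
            verdicts[gene] = (True, f"direct interaction in {len(sources)} sources")
        elif any(len(methods) >= 2 for methods in sources.values()):
            n = max(len(m) for m in sources.values())
            verdicts[gene] = (True, f"one source, {n} distinct methods")
        elif sources:
            verdicts[gene] = (False, "single direct record (one source, one method)")
        else:
            verdicts[gene] = (False, "no direct evidence")
    return verdicts


def curate_interactome(
    evidence: Iterable[EvidenceRecord],
    name: str,
    source: SetSource = SetSource.CURATED,
) -> GeneSet:
    """Build a curated interactome from an evidence table.

    Raises :class:`CurationError` when the evidence is empty or no gene
    satisfies the acceptance rule.  The per-gene verdicts are logged so
    the provenance of every accepted gene is auditable in the run log.
    """
    evidence = list(evidence)
    if not evidence:
        raise CurationError(f"interactome {name!r}: evidence table is empty")
    verdicts = evaluate_gene_evidence(evidence)
    kept = frozenset(g for g, (ok, _) in verdicts.items() if ok)
    for gene, (ok, reason) in verdicts.items():
        logger.info(
            "curation[%s] %s %s: %s", name, "keep" if ok else "drop", gene, reason
        )
    if not kept:
        raise CurationError(
            f"interactome {name!r}: no gene satisfies the curation rule "
            "(two independent sources, or one source with two distinct methods, "
            "direct interactions only)"
        )
    return GeneSet(name=name, source=source, genes=kept)
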