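"""Readers and writers for every external file the pipeline touches.

Formats
-------
* GWAS summary statistics: tab-delimited with a header (column names
  configurable), one row per SNP with rsid, chromosome, position and
  association p-value.
* Gene annotation and region masks: BED (0-based, half-open); converted
  on read to the internal 1-based inclusive convention.
* Gene sets: GMT (set name, description/source, member symbols).
* Pairwise LD: PLINK ``.ld``-style whitespace table with SNP_A, SNP_B, R2.
* Interaction evidence: tab-delimited with the five evidence columns.
* Results: Table-style TSV plus a JSON sidecar holding the resolved
  parameters and per-set counts.

Invalid rows are dropped with a :class:`ValidationWarning` carrying the
rejected-row count (mirroring upstream QC filtering of association
data); ``strict=True`` upgrades every such warning to a
:class:`FormatError`.
"""

from __future__ import annotations

import json
import warnings
from importlib import resources
from pathlib import Path
from typing import Iterable, List, Mapping, Optional, Sequence, Union

import pandas as pd

from .errors import FormatError, ValidationWarning
from .models import (
    EvidenceRecord,
    GeneRecord,
    GeneSet,
    InteractionClass,
    LdTable,
    RegionMask,
    SetSource,
    SnpRecord,
    normalize_chrom,
)

PathLike = Union[str, Path]

_GWAS_COLUMNS = {"rsid": "rsid", "chrom": "chrom", "pos": "pos", "p": "p"}


def _reject(message: str, strict: bool) -> None:
    if strict:
        raise FormatError(message)
    warnings.warn(message, ValidationWarning, stacklevel=3)


# ---------------------------------------------------------------------------
# GWAS summary statistics


def read_gwas_summary(
    path: PathLike,
    columns: Optional[Mapping[str, Union[str, int]]] = None,
    sep: str = "\t",
    strict: bool = False,
) -> List[SnpRecord]:
    """Read per-SNP association p-values.

    ``columns`` maps the logical names ``rsid``/``chrom``/``pos``/``p``
    either to header names (strings) or to 0-based column positions
    (integers, for headerless files).  Rows with an out-of-range
    p-value or position, or a duplicated rsid, are rejected with a
    warning; a missing column is a :class:`FormatError`.
    """
    colmap = dict(_GWAS_COLUMNS)
    if columns:
        colmap.update(columns)
    positional = all(isinstance(v, int) for v in colmap.values())
    try:
        frame = pd.read_csv(path, sep=sep, header=None if positional else 0, dtype=str)
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty GWAS file", ValidationWarning, stacklevel=2)
        return []
    for logical, actual in colmap.items():
        if (positional and actual >= frame.shape[1]) or (
            not positional and actual not in frame.columns
        ):
            raise FormatError(f"{path}: missing GWAS column {actual!r} ({logical})")

    def col(logical):
        actual = colmap[logical]
        return frame.iloc[:, actual] if positional else frame[actual]

    records: List[SnpRecord] = []
    seen: set = set()
    n_rejected = 0
    rows = zip(col("rsid"), col("chrom"), col("pos"), col("p"))
    for rsid, chrom, pos, pval in rows:
        try:
            rec = SnpRecord(
                rsid=str(rsid).strip(),
                chrom=normalize_chrom(chrom),
                pos=int(pos),
                pvalue=float(pval),
            )
        except (TypeError, ValueError):
            n_rejected += 1
            continue
        if rec.rsid in seen:
            n_rejected += 1
            continue
        seen.add(rec.rsid)
        records.append(rec)
    if n_rejected:
        _reject(
            f"{path}: rejected {n_rejected} GWAS row(s) failing validation "
            "(p-value outside (0, 1], bad coordinate, or duplicate rsid)",
            strict,
        )
    return records


def write_gwas_summary(records: Sequence[SnpRecord], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("rsid\tchrom\tpos\tp\n")
        for s in records:
            fh.write(f"{s.rsid}\t{s.chrom}\t{s.pos}\t{s.pvalue:.17g}\n")


# ---------------------------------------------------------------------------
# BED-like inputs (genes, region masks)


def _read_bed(path: PathLike, n_cols: int) -> pd.DataFrame:
    try:
        frame = pd.read_csv(path, sep=r"\s+", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return pd.DataFrame()
    if frame.shape[1] < n_cols:
        raise FormatError(f"{path}: expected at least {n_cols} BED columns")
    return frame


def read_gene_annotation(path: PathLike) -> List[GeneRecord]:
    """Read a BED gene annotation (chrom, start, end, name).

    BED is 0-based half-open; intervals become 1-based inclusive, so a
    BED line ``1 999 2000 G`` yields the interval [1000, 2000].
    """
    frame = _read_bed(path, 4)
    if frame.empty:
        warnings.warn(f"{path}: empty gene annotation", ValidationWarning, stacklevel=2)
        return []
    genes: List[GeneRecord] = []
    seen: set = set()
    for chrom, start, end, name in zip(
        frame.iloc[:, 0], frame.iloc[:, 1], frame.iloc[:, 2], frame.iloc[:, 3]
    ):
        try:
            start_1, end_1 = int(start) + 1, int(end)
        except ValueError as exc:
            raise FormatError(f"{path}: non-integer BED coordinate ({exc})") from exc
        if start_1 > end_1:
            raise FormatError(
                f"{path}: gene {name!r} has an empty or inverted interval "
                f"({start}, {end})"
            )
        symbol = str(name).strip().upper()
        if symbol in seen:
            raise FormatError(f"{path}: duplicate gene symbol {symbol!r}")
        seen.add(symbol)
        genes.append(GeneRecord(symbol, normalize_chrom(chrom), start_1, end_1))
    return genes


def write_gene_annotation(genes: Sequence[GeneRecord], path: PathLike) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.symbol}\n")


def read_region_mask(path: PathLike, label: str = "mask") -> RegionMask:
    """Read a BED region mask; intervals become 1-based inclusive."""
    frame = _read_bed(path, 3)
    if frame.empty:
        warnings.warn(f"{path}: empty region mask", ValidationWarning, stacklevel=2)
        return RegionMask(intervals=(), label=label)
    intervals = []
    for chrom, start, end in zip(frame.iloc[:, 0], frame.iloc[:, 1], frame.iloc[:, 2]):
        start_1, end_1 = int(start) + 1, int(end)
        if start_1 > end_1:
            raise FormatError(f"{path}: empty or inverted mask interval ({start}, {end})")
        intervals.append((normalize_chrom(chrom), start_1, end_1))
    return RegionMask(intervals=tuple(intervals), label=label)


def write_region_mask(mask: RegionMask, path: PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in mask.intervals:
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{mask.label}\n")


# ---------------------------------------------------------------------------
# GMT gene sets

_SOURCE_TO_DESC = {
    SetSource.LITERATURE: "literature",
    SetSource.CURATED: "manually curated",
    SetSource.DATABASE: "database",
}


def _source_from_description(description: str) -> SetSource:
    text = description.lower()
    if "curated" in text:
        return SetSource.CURATED
    if "biogrid" in text or "database" in text:
        return SetSource.DATABASE
    return SetSource.LITERATURE


def read_gene_sets(path: PathLike) -> List[GeneSet]:
    """Read GMT gene sets; duplicate members are deduplicated with a
    warning and an empty set is a :class:`FormatError`."""
    sets: List[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    "at least one member gene"
                )
            name, description = fields[0], fields[1]
            members = [g.strip().upper() for g in fields[2:] if g.strip()]
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
            unique = list(dict.fromkeys(members))
            if len(unique) < len(members):
                warnings.warn(
                    f"{path}:{lineno}: gene set {name!r} lists "
                    f"{len(members) - len(unique)} duplicate member(s); deduplicated",
                    ValidationWarning,
                    stacklevel=2,
                )
            sets.append(
                GeneSet(
                    name=name,
                    source=_source_from_description(description),
                    genes=frozenset(unique),
                )
            )
    return sets


def write_gene_sets(
    sets: Sequence[GeneSet], path: PathLike, append: bool = False
) -> None:
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        for gs in sets:
            members = "\t".join(sorted(gs.genes))
            fh.write(f"{gs.name}\t{_SOURCE_TO_DESC[gs.source]}\t{members}\n")


def load_packaged_interactomes() -> List[GeneSet]:
    """Load the packaged interactome fixture.

    The fixture reproduces the published set names, sizes and provenance
    tags of the thirteen environmental-factor interactomes, but its
    member symbols are synthetic placeholders (the underlying membership
    lists live in supplementary material that is not redistributed
    here); see the filename tag ``synthetic``.
    """
    ref = resources.files("candidate_interactome").joinpath(
        "data/synthetic_interactomes.gmt"
    )
    with resources.as_file(ref) as real_path:
        return read_gene_sets(real_path)


# ---------------------------------------------------------------------------
# Pairwise LD


def read_ld_table(path: PathLike, strict: bool = False) -> LdTable:
    """Read a PLINK ``.ld``-style pairwise r² table (SNP_A, SNP_B, R2).

    Extra columns (CHR_A, BP_A, ...) are ignored; rows with r² outside
    [0, 1] are rejected with a warning.
    """
    try:
        frame = pd.read_csv(path, sep=r"\s+", dtype=str)
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty LD table", ValidationWarning, stacklevel=2)
        return LdTable()
    for needed in ("SNP_A", "SNP_B", "R2"):
        if needed not in frame.columns:
            raise FormatError(f"{path}: missing LD column {needed!r}")
    table = LdTable()
    n_rejected = 0
    for a, b, r2 in zip(frame["SNP_A"], frame["SNP_B"], frame["R2"]):
        try:
            table.add(str(a).strip(), str(b).strip(), float(r2))
        except (TypeError, ValueError):
            n_rejected += 1
    if n_rejected:
        _reject(f"{path}: rejected {n_rejected} LD row(s) with r2 outside [0, 1]", strict)
    return table


def write_ld_table(table: LdTable, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("SNP_A\tSNP_B\tR2\n")
        for a, b, r2 in sorted(table.items()):
            fh.write(f"{a}\t{b}\t{r2:.17g}\n")


# ---------------------------------------------------------------------------
# Interaction evidence

_EVIDENCE_COLUMNS = ("env_protein", "human_gene", "source_id", "method", "interaction_class")


def read_evidence_table(path: PathLike, strict: bool = False) -> List[EvidenceRecord]:
    """Read a tab-delimited interaction-evidence table.

    An unrecognized interaction class is downgraded to ``unknown`` with
    a warning; rows lacking a human gene or a source identifier are
    rejected.
    """
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty evidence table", ValidationWarning, stacklevel=2)
        return []
    for needed in _EVIDENCE_COLUMNS:
        if needed not in frame.columns:
            raise FormatError(f"{path}: missing evidence column {needed!r}")
    records: List[EvidenceRecord] = []
    n_rejected = 0
    n_unknown = 0
    for row in frame.itertuples(index=False):
        klass_text = str(getattr(row, "interaction_class")).strip().lower()
        try:
            klass = InteractionClass(klass_text)
        except ValueError:
            klass = InteractionClass.UNKNOWN
            n_unknown += 1
        try:
            records.append(
                EvidenceRecord(
                    env_protein=str(getattr(row, "env_protein")).strip(),
                    human_gene=str(getattr(row, "human_gene")).strip(),
                    source_id=str(getattr(row, "source_id")).strip(),
                    method=str(getattr(row, "method")).strip(),
                    interaction_class=klass,
                )
            )
        except ValueError:
            n_rejected += 1
    if n_unknown:
        warnings.warn(
            f"{path}: {n_unknown} row(s) carry an unrecognized interaction class; "
            "treated as 'unknown'",
            ValidationWarning,
            stacklevel=2,
        )
    if n_rejected:
        _reject(f"{path}: rejected {n_rejected} incomplete evidence row(s)", strict)
    return records


def write_evidence_table(records: Sequence[EvidenceRecord], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_EVIDENCE_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.env_protein}\t{r.human_gene}\t{r.source_id}\t{r.method}\t"
                f"{r.interaction_class.value}\n"
            )


# ---------------------------------------------------------------------------
# Results


def _format_p(p: Optional[float]) -> str:
    return "NA" if p is None else f"{p:.4f}"


def write_results_table(
    results: Iterable,
    path: PathLike,
    parameters: Optional[Mapping] = None,
    study: Optional[Mapping] = None,
) -> None:
    """Write per-interactome enrichment results.

    The TSV mirrors the published table layout (interactome, size,
    source, empirical p-value with the region mask applied and without
    it, printed to four decimals).  A JSON sidecar at ``<path>.json``
    records the resolved parameters, per-set counts and the study-wide
    summary so a run can be audited and reproduced.
    """
    path = Path(path)
    results = list(results)
    with open(path, "w") as fh:
        fh.write("Interactome\tSize\tSource\tp-value with mask\tp-value without mask\n")
        for r in results:
            fh.write(
                f"{r.name}\t{r.size}\t{r.source.value}\t"
                f"{_format_p(r.p_masked)}\t{_format_p(r.p_unmasked)}\n"
            )
    sidecar = {
        "parameters": dict(parameters) if parameters else {},
        "results": [
            {
                "name": r.name,
                "size": r.size,
                "source": r.source.value,
                "n_mappable": r.n_mappable,
                "n_sig_observed": r.n_sig_observed,
                "p_masked": r.p_masked,
                "p_unmasked": r.p_unmasked,
            }
            for r in results
        ],
        "study_wide": dict(study) if study else {},
    }
    with open(f"{path}.json", "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_results_sidecar(path: PathLike) -> dict:
    """Read back the JSON sidecar written next to a results table."""
    with open(f"{path}.json") as fh:
        return json.load(fh)
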