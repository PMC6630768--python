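"""Readers and writers for every external representation the pipeline touches.

All tabular dialects are tab-separated UTF-8 with a mandatory header row.
Readers validate invariants and fail fast (no silent coercion); writers
round-trip bit-exactly through the corresponding reader.
"""

from __future__ import annotations

import json
import logging
import math
import re
import warnings
from io import StringIO
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SwissProt

from .types import (
    AnnotationEntry,
    AnnotationField,
    CoverageInterval,
    Criterion,
    ExpressionMatrix,
    GeneLocus,
    LinkTable,
    PdbCrossRef,
    ProteinRecord,
    TaxonGroup,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "read_proteins",
    "write_proteins",
    "read_annotations",
    "write_annotations",
    "parse_uniprot_dat_fragment",
    "read_coverage",
    "write_coverage",
    "read_links",
    "write_links",
    "read_gene_positions",
    "write_gene_positions",
    "read_expression",
    "write_expression",
    "write_treemap_json",
    "AREA_CAP_DEFAULT",
]


class FormatError(ValueError):
    """A dialect violation, carrying the offending line number when known."""


def _read_tsv(path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: file not found")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    return df


def _to_int(value: str, path, line: int, column: str) -> int:
    try:
        return int(value)
    except (TypeError, ValueError):
        raise FormatError(f"{path} line {line}: {column}={value!r} is not an integer")


# data rows start on line 2 (line 1 is the header)
def _line(i: int) -> int:
    return i + 2


def read_proteins(path, annotations_path=None) -> list[ProteinRecord]:
    """Read proteins.tsv (accession, organism, taxon_group, length), optionally
    attaching annotations from a companion annotations.tsv."""
    df = _read_tsv(path, ["accession", "organism", "taxon_group", "length"])
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        acc = row.accession
        if not acc:
            raise FormatError(f"{path} line {_line(i)}: empty accession")
        if acc in seen:
            raise FormatError(f"{path} line {_line(i)}: duplicate accession {acc!r}")
        seen.add(acc)
        length = _to_int(row.length, path, _line(i), "length")
        try:
            rec = ProteinRecord(
                accession=acc,
                organism=row.organism,
                taxon_group=TaxonGroup(row.taxon_group),
                length=length,
                sequence=getattr(row, "sequence", None) or None,
            )
        except ValueError as exc:
            raise FormatError(f"{path} line {_line(i)}: {exc}") from exc
        records.append(rec)
    if annotations_path is not None:
        by_acc = {r.accession: r for r in records}
        for acc, entry in read_annotations(annotations_path):
            if acc not in by_acc:
                raise FormatError(
                    f"{annotations_path}: unknown accession {acc!r} in annotations"
                )
            by_acc[acc].annotations.append(entry)
    return records


def write_proteins(records: Iterable[ProteinRecord], path) -> None:
    rows = []
    any_seq = False
    for r in records:
        rows.append(
            {
                "accession": r.accession,
                "organism": r.organism,
                "taxon_group": r.taxon_group.value,
                "length": r.length,
                "sequence": r.sequence or "",
            }
        )
        any_seq = any_seq or bool(r.sequence)
    df = pd.DataFrame(rows, columns=["accession", "organism", "taxon_group", "length", "sequence"])
    if not any_seq:
        df = df.drop(columns=["sequence"])
    df.to_csv(path, sep="\t", index=False)


def read_annotations(path) -> list[tuple[str, AnnotationEntry]]:
    df = _read_tsv(path, ["accession", "field", "subcategory", "text"])
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            entry = AnnotationEntry(
                field=AnnotationField(row.field),
                subcategory=row.subcategory,
                text=row.text,
            )
        except ValueError as exc:
            raise FormatError(f"{path} line {_line(i)}: {exc}") from exc
        out.append((row.accession, entry))
    return out


def write_annotations(records: Iterable[ProteinRecord], path) -> None:
    rows = [
        {
            "accession": r.accession,
            "field": a.field.value,
            "subcategory": a.subcategory,
            "text": a.text,
        }
        for r in records
        for a in r.annotations
    ]
    pd.DataFrame(rows, columns=["accession", "field", "subcategory", "text"]).to_csv(
        path, sep="\t", index=False
    )


_CHAIN_RANGE_RE = re.compile(r"^(?P<chains>[A-Za-z0-9/]+)=(?P<start>\d+)-(?P<end>\d+)$")


def _parse_chain_ranges(text: str) -> list[tuple[int, int]]:
    """Parse a DR PDB chain-range field like ``A=5-60`` or ``A/B=1-50, C=61-90``."""
    text = text.strip().rstrip(".")
    if text in ("-", ""):
        return []
    ranges: list[tuple[int, int]] = []
    for part in text.split(","):
        part = part.strip()
        m = _CHAIN_RANGE_RE.match(part)
        if m is None:
            raise ValueError(f"unparseable chain range {part!r}")
        ranges.append((int(m.group("start")), int(m.group("end"))))
    return ranges


_COMMENT_TOPIC_RE = re.compile(r"^([A-Z ]+?):\s*(.*)$", re.DOTALL)


def parse_uniprot_dat_fragment(text: str) -> ProteinRecord:
    """Build a ProteinRecord from one UniProt flat-file (DAT) record.

    Extracts the primary accession (AC), sequence length (ID line),
    description-family annotations (DE lines and CC comment topics, both as
    field=DE — the comment topic, upper snake case, is the subcategory),
    FT features (field=FT, subcategory = feature key), and DR PDB
    cross-references with parsed chain ranges. Unparseable chain ranges
    skip the cross-reference with a logged warning rather than failing.
    """
    try:
        rec = SwissProt.read(StringIO(text))
    except Exception as exc:  # biopython raises bare ValueError/AssertionError
        raise FormatError(f"not a parseable UniProt DAT record: {exc}") from exc
    if not rec.accessions:
        raise FormatError("DAT record has no AC line")
    annotations: list[AnnotationEntry] = []
    # DE line: "RecName: Full=...; AltName: ..." -> subcategory per name type
    for part in rec.description.split(";"):
        part = part.strip()
        if not part:
            continue
        if ":" in part:
            kind, value = part.split(":", 1)
        elif "=" in part:
            kind, value = part.split("=", 1)
        else:
            kind, value = "NAME", part
        annotations.append(
            AnnotationEntry(AnnotationField.DE, kind.strip().upper().replace(" ", "_"), value.strip())
        )
    for comment in rec.comments:
        m = _COMMENT_TOPIC_RE.match(comment.strip())
        if m:
            topic, body = m.group(1), m.group(2)
        else:
            topic, body = "MISCELLANEOUS", comment.strip()
        annotations.append(
            AnnotationEntry(
                AnnotationField.DE, topic.strip().upper().replace(" ", "_"), body.strip()
            )
        )
    for feat in rec.features:
        note = feat.qualifiers.get("note", "") if feat.qualifiers else ""
        annotations.append(AnnotationEntry(AnnotationField.FT, feat.type, note))
    crossrefs: list[PdbCrossRef] = []
    for xref in rec.cross_references:
        if xref[0] != "PDB":
            continue
        structure_id = xref[1]
        range_field = xref[4] if len(xref) > 4 else "-"
        try:
            ranges = _parse_chain_ranges(range_field)
        except ValueError as exc:
            logger.warning("skipping PDB cross-ref %s: %s", structure_id, exc)
            continue
        if ranges:
            crossrefs.append(PdbCrossRef(structure_id, tuple(ranges)))
    return ProteinRecord(
        accession=rec.accessions[0],
        organism=(rec.organism or "").rstrip("."),
        length=rec.sequence_length,
        annotations=annotations,
        pdb_crossrefs=crossrefs,
        sequence=rec.sequence or None,
    )


def _check_known(
    acc: str, known: Optional[Mapping[str, int]], path, line: int, on_unknown: str
) -> bool:
    """True when the row should be kept."""
    if known is None or acc in known:
        return True
    if on_unknown == "error":
        raise FormatError(f"{path} line {line}: unknown accession {acc!r}")
    warnings.warn(f"{path} line {line}: dropping row with unknown accession {acc!r}")
    return False


def _lengths(proteins: Optional[Iterable[ProteinRecord]]) -> Optional[dict[str, int]]:
    if proteins is None:
        return None
    return {p.accession: p.length for p in proteins}


def read_coverage(path, proteins=None, on_unknown: str = "error") -> list[CoverageInterval]:
    """Read coverage.tsv; intervals are validated against protein lengths when
    ``proteins`` is given (an out-of-range interval is an error, never a clip)."""
    df = _read_tsv(path, ["accession", "start", "end", "criterion", "source_id"])
    lengths = _lengths(proteins)
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        if not _check_known(row.accession, lengths, path, _line(i), on_unknown):
            continue
        start = _to_int(row.start, path, _line(i), "start")
        end = _to_int(row.end, path, _line(i), "end")
        try:
            iv = CoverageInterval(row.accession, start, end, Criterion(row.criterion), row.source_id)
        except ValueError as exc:
            raise FormatError(f"{path} line {_line(i)}: {exc}") from exc
        if lengths is not None and end > lengths[row.accession]:
            raise FormatError(
                f"{path} line {_line(i)}: interval [{start}, {end}] exceeds "
                f"length {lengths[row.accession]} of {row.accession}"
            )
        out.append(iv)
    return out


def write_coverage(intervals: Iterable[CoverageInterval], path) -> None:
    rows = [
        {
            "accession": iv.accession,
            "start": iv.start,
            "end": iv.end,
            "criterion": iv.criterion.value,
            "source_id": iv.source_id,
        }
        for iv in intervals
    ]
    pd.DataFrame(rows, columns=["accession", "start", "end", "criterion", "source_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_links(path, proteins=None, on_unknown: str = "error") -> LinkTable:
    df = _read_tsv(path, ["accession_a", "accession_b", "combined_score"])
    lengths = _lengths(proteins)
    rows = []
    for i, row in enumerate(df.itertuples(index=False)):
        score = _to_int(row.combined_score, path, _line(i), "combined_score")
        if not (0 <= score <= 999):
            raise FormatError(
                f"{path} line {_line(i)}: combined_score {score} outside [0, 999]"
            )
        keep_a = _check_known(row.accession_a, lengths, path, _line(i), on_unknown)
        keep_b = _check_known(row.accession_b, lengths, path, _line(i), on_unknown)
        if keep_a and keep_b:
            rows.append((row.accession_a, row.accession_b, score))
    try:
        return LinkTable(rows)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_links(links: LinkTable, path) -> None:
    links.df.to_csv(path, sep="\t", index=False)


def read_gene_positions(path, proteins=None, on_unknown: str = "error") -> pd.DataFrame:
    """Read genes.tsv into a locus table (accession, chromosome, central_position)."""
    df = _read_tsv(path, ["accession", "chromosome", "central_position"])
    lengths = _lengths(proteins)
    rows = []
    for i, row in enumerate(df.itertuples(index=False)):
        if not _check_known(row.accession, lengths, path, _line(i), on_unknown):
            continue
        pos = _to_int(row.central_position, path, _line(i), "central_position")
        if pos < 0:
            raise FormatError(f"{path} line {_line(i)}: negative central_position")
        rows.append((row.accession, row.chromosome, pos))
    return pd.DataFrame(rows, columns=["accession", "chromosome", "central_position"])


def write_gene_positions(loci: pd.DataFrame, path) -> None:
    loci.loc[:, ["accession", "chromosome", "central_position"]].to_csv(
        path, sep="\t", index=False
    )


def read_expression(path, proteins=None, on_unknown: str = "error") -> ExpressionMatrix:
    """Read expression.tsv (long format: tissue, accession, normalized_intensity).

    An absent (tissue, accession) pair is MISSING (NaN in the matrix), which is
    distinct from a written 0.
    """
    df = _read_tsv(path, ["tissue", "accession", "normalized_intensity"])
    lengths = _lengths(proteins)
    rows = []
    for i, row in enumerate(df.itertuples(index=False)):
        if not _check_known(row.accession, lengths, path, _line(i), on_unknown):
            continue
        try:
            value = float(row.normalized_intensity)
        except ValueError:
            raise FormatError(
                f"{path} line {_line(i)}: normalized_intensity "
                f"{row.normalized_intensity!r} is not a number"
            )
        rows.append((row.tissue, row.accession, value))
    long = pd.DataFrame(rows, columns=["tissue", "accession", "normalized_intensity"])
    if long.duplicated(["tissue", "accession"]).any():
        raise FormatError(f"{path}: duplicate (tissue, accession) pair")
    wide = long.pivot(index="tissue", columns="accession", values="normalized_intensity")
    wide = wide.sort_index().sort_index(axis=1)
    return ExpressionMatrix(wide)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    long = (
        matrix.values.stack(future_stack=True)
        .rename("normalized_intensity")
        .reset_index()
        .dropna(subset=["normalized_intensity"])
    )
    long.to_csv(path, sep="\t", index=False)


AREA_CAP_DEFAULT = 320.0  # ~ -log10 of the smallest positive double


def write_treemap_json(
    results,
    path=None,
    cutoff: float = 0.0,
    area_cap: float = AREA_CAP_DEFAULT,
) -> dict:
    """Serialize enrichment results as a nested treemap document.

    Structure: field -> subcategory -> leaves with {label, area, direction},
    where area = -log10(adjusted p), capped at ``area_cap`` when the adjusted
    p underflows to 0. Leaves with area below ``cutoff`` are excluded for
    readability. Key order is deterministic (sorted; leaves by area
    descending, then label).
    """
    tree: dict = {}
    for res in results:
        p_adj = res.p_adjusted
        area = area_cap if p_adj <= 0.0 else min(-math.log10(p_adj), area_cap)
        if area < cutoff:
            continue
        field = res.annotation.field.value
        sub = res.annotation.subcategory
        tree.setdefault(field, {}).setdefault(sub, []).append(
            {
                "label": res.annotation.text or sub,
                "area": area,
                "direction": res.direction.value,
            }
        )
    doc = {
        "cutoff": cutoff,
        "area_cap": area_cap,
        "children": [
            {
                "name": field,
                "children": [
                    {
                        "name": sub,
                        "children": sorted(
                            leaves, key=lambda d: (-d["area"], d["label"])
                        ),
                    }
                    for sub, leaves in sorted(tree[field].items())
                ],
            }
            for field in sorted(tree)
        ],
    }
    if path is not None:
        Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    return doc
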