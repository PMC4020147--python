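"""Readers and writers: haplotype tables, filter lists, QC reports, graphs.

The haplotype table dialect is tab-separated text with the header
``SampleID<TAB>Haplogroup<TAB>Range<TAB>Haplotype`` (the Haplogroup column
may be omitted), one row per sample, variant tokens space-separated in the
Haplotype column.  Blank lines and ``#`` comments are skipped.  Filter lists
are one canonical token (or bare position) per line with an optional
``#mode=mutation|position`` header.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Union

from Bio import SeqIO

from .qc_checks import QCReport
from .reduce_filter import MUTATION_MODE, POSITION_MODE, FilterList
from .variant_model import (
    Haplotype,
    RangeParseError,
    ReferenceSequence,
    VariantParseError,
    format_variant,
    make_haplotype,
    parse_variant,
)

SCHEMA_VERSION = "1"

PathLike = Union[str, Path]


class LoadError(ValueError):
    """Structured load failure naming the file and row/line."""

    def __init__(self, path: PathLike, line_no: Optional[int], reason: str):
        self.path = str(path)
        self.line_no = line_no
        self.reason = reason
        where = f"{path}" + (f", line {line_no}" if line_no else "")
        super().__init__(f"{where}: {reason}")


@dataclass(frozen=True)
class HaplotypeTable:
    haplotypes: tuple
    source_path: str = ""
    dialect: str = "tsv"

    def __iter__(self):
        return iter(self.haplotypes)

    def __len__(self):
        return len(self.haplotypes)


def read_haplotype_table(path: PathLike, dialect: str = "tsv") -> HaplotypeTable:
    """Read a haplotype table; raw tokens are retained so the notation QC
    check can flag structurally broken indel spellings.

    Raises :class:`LoadError` on missing columns, duplicate sample ids, or
    malformed rows/tokens (with the offending line number).
    """
    if dialect != "tsv":
        raise LoadError(path, None, f"unknown table dialect {dialect!r}")
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    header = None
    col = {}
    haplotypes: List[Haplotype] = []
    seen_ids = set()
    for line_no, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = [f.strip() for f in fields]
            col = {name.lower(): i for i, name in enumerate(header)}
            for required in ("sampleid", "range", "haplotype"):
                if required not in col:
                    raise LoadError(path, line_no,
                                    f"missing column {required!r} in header")
            continue
        if len(fields) < len(header):
            fields = fields + [""] * (len(header) - len(fields))
        sample_id = fields[col["sampleid"]].strip()
        if not sample_id:
            raise LoadError(path, line_no, "empty SampleID")
        if sample_id in seen_ids:
            raise LoadError(path, line_no, f"duplicate sample id {sample_id!r}")
        seen_ids.add(sample_id)
        haplogroup = (fields[col["haplogroup"]].strip() or None
                      if "haplogroup" in col else None)
        range_text = fields[col["range"]].strip()
        tokens = fields[col["haplotype"]].split()
        try:
            haplotypes.append(make_haplotype(
                sample_id, range_text, tokens, haplogroup,
                tolerate_broken_indels=True))
        except (VariantParseError, RangeParseError) as exc:
            raise LoadError(path, line_no, str(exc)) from exc
    if header is None:
        raise LoadError(path, None, "no header line found")
    return HaplotypeTable(tuple(haplotypes), str(path))


def write_haplotype_table(table: Sequence[Haplotype], path: PathLike) -> None:
    """Write the TSV dialect; raw tokens are preserved verbatim when present
    (round-trip fidelity), else canonical tokens are emitted."""
    out = ["SampleID\tHaplogroup\tRange\tHaplotype"]
    for h in table:
        tokens = " ".join(h.raw_tokens) if h.raw_tokens else \
            " ".join(format_variant(v) for v in h.variants)
        out.append(f"{h.sample_id}\t{h.haplogroup or ''}\t{h.range}\t{tokens}")
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


def read_filter_list(path: PathLike) -> FilterList:
    """Read a filter file: one token (or bare position) per line.

    ``#mode=mutation|position`` selects the mode (default mutation); other
    ``#`` lines are comments.  Tokens are canonicalized.
    """
    mode = MUTATION_MODE
    entries = []
    for line_no, raw in enumerate(
            Path(path).read_text(encoding="utf-8").splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            directive = line[1:].strip().replace(" ", "").lower()
            if directive.startswith("mode="):
                mode = directive[5:]
                if mode not in (MUTATION_MODE, POSITION_MODE):
                    raise LoadError(path, line_no, f"unknown mode {mode!r}")
            continue
        if mode == POSITION_MODE:
            if not line.isdigit():
                raise LoadError(path, line_no,
                                f"position-mode entry {line!r} is not a position")
            entries.append(line)
        else:
            try:
                entries.append(format_variant(parse_variant(line)))
            except VariantParseError as exc:
                raise LoadError(path, line_no, str(exc)) from exc
    return FilterList(name=Path(path).stem, entries=frozenset(entries), mode=mode)


def write_filter_list(f: FilterList, path: PathLike) -> None:
    lines = [f"#mode={f.mode}"]
    lines.extend(sorted(f.entries, key=_entry_sort_key))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _entry_sort_key(entry: str) -> tuple:
    digits = "".join(ch for ch in entry if ch.isdigit())
    return (int(digits[:5]) if digits else 0, entry)


def read_fasta_reference(path: PathLike,
                         source_label: Optional[str] = None) -> ReferenceSequence:
    """Load a single-record FASTA reference (16569 bases, rCRS numbering)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise LoadError(path, None,
                        f"expected exactly 1 FASTA record, found {len(records)}")
    rec = records[0]
    try:
        return ReferenceSequence(str(rec.seq), source_label or rec.id)
    except ValueError as exc:
        raise LoadError(path, None, str(exc)) from exc


QC_TSV_COLUMNS = ("sample_id", "code", "severity", "token", "message")


def qc_report_to_tsv(report: QCReport) -> str:
    """One finding per row; fixed column order."""
    lines = ["\t".join(QC_TSV_COLUMNS)]
    for f in report.findings:
        lines.append("\t".join((f.sample_id, f.code, f.severity,
                                f.variant_token, f.message)))
    return "\n".join(lines) + "\n"


def qc_report_to_json(report: QCReport) -> str:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "samples_checked": report.samples_checked,
        "samples_flagged": report.samples_flagged,
        "findings": [
            {"sample_id": f.sample_id, "code": f.code, "severity": f.severity,
             "token": f.variant_token, "message": f.message}
            for f in report.findings],
    }
    return json.dumps(doc, indent=2, sort_keys=True) + "\n"


def write_outputs(obj, path: PathLike, fmt: str) -> None:
    """Serialize a QC report, graph, or node listing deterministically.

    ``fmt``: qc-tsv, qc-json, graphml, dot, svg-ready objects are written by
    the caller (render); json listings get a schema_version wrapper.
    """
    from . import render  # local import to avoid cycles
    path = Path(path)
    if fmt == "qc-tsv":
        path.write_text(qc_report_to_tsv(obj), encoding="utf-8")
    elif fmt == "qc-json":
        path.write_text(qc_report_to_json(obj), encoding="utf-8")
    elif fmt == "graphml":
        path.write_text(render.export_graphml(obj), encoding="utf-8")
    elif fmt == "dot":
        path.write_text(render.export_dot(obj), encoding="utf-8")
    elif fmt == "json-graph":
        path.write_text(render.graph_to_json(obj), encoding="utf-8")
    elif fmt == "json-listing":
        doc = {"schema_version": SCHEMA_VERSION, "items": list(obj)}
        path.write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")
    else:
        raise ValueError(f"unknown output format {fmt!r}")
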