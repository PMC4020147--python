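"""Plausibility checks applied to every haplotype before network construction.

The battery covers the classic tabulation errors of forensic mtDNA data:

* ``RANGE_VIOLATION`` — a variant outside the sample's sequenced range;
* ``REFERENCE_BIAS`` — a "difference" whose derived state equals the
  reference state (e.g. ``A263A``);
* ``DOUBLE_SPECIFICATION`` — the same position (and insertion index) stated
  twice, whether identically or contradictorily;
* ``INDEL_NOTATION`` — structurally broken insertion/deletion tokens
  (``315.1`` without a base, ``16038G-`` with a derived base);
* ``CSTRETCH_CONVENTION`` — heuristic signals that the HVS-2 C-tract around
  position 309 was not reported in 3' convention: ``C311T`` without the
  expected ``315.1C``, or an insertion anchored off the tract's 3' ends.

The first four are errors; the C-tract check is a warning because only the
raw electropherograms can confirm it.  Checks flag — they never repair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Mapping, Optional, Sequence, Union

from .variant_model import (
    DELETION,
    INSERTION,
    SUBSTITUTION,
    Haplotype,
    ReferenceSequence,
    Variant,
    format_variant,
    looks_indel_like,
    parse_variant,
    VariantParseError,
)

RANGE_VIOLATION = "RANGE_VIOLATION"
REFERENCE_BIAS = "REFERENCE_BIAS"
DOUBLE_SPECIFICATION = "DOUBLE_SPECIFICATION"
INDEL_NOTATION = "INDEL_NOTATION"
CSTRETCH_CONVENTION = "CSTRETCH_CONVENTION"

CODES = (RANGE_VIOLATION, REFERENCE_BIAS, DOUBLE_SPECIFICATION,
         INDEL_NOTATION, CSTRETCH_CONVENTION)

ERROR = "error"
WARNING = "warning"


@dataclass(frozen=True)
class QCFinding:
    sample_id: str
    code: str
    severity: str
    variant_token: str
    message: str

    def __post_init__(self):
        if self.code not in CODES:
            raise ValueError(f"unknown QC code {self.code!r}")
        if self.severity not in (ERROR, WARNING):
            raise ValueError(f"unknown severity {self.severity!r}")


@dataclass(frozen=True)
class QCReport:
    findings: tuple
    samples_checked: int

    @property
    def samples_flagged(self) -> int:
        return len({f.sample_id for f in self.findings})

    @property
    def has_errors(self) -> bool:
        return any(f.severity == ERROR for f in self.findings)


RefLike = Union[ReferenceSequence, Mapping[int, str], None]


def _ref_base(ref: RefLike, position: int) -> Optional[str]:
    if ref is None:
        return None
    if isinstance(ref, ReferenceSequence):
        return ref.base_at(position)
    return ref.get(position)


def check_range_violation(h: Haplotype) -> List[QCFinding]:
    """One error per variant whose position falls outside the sequenced range.

    Insertions are judged by their anchor position.
    """
    findings = []
    for v in h.variants:
        if not h.range.covers(v.position):
            findings.append(QCFinding(
                h.sample_id, RANGE_VIOLATION, ERROR, format_variant(v),
                f"variant {format_variant(v)} outside sequenced range {h.range}"))
    return findings


def check_reference_bias(h: Haplotype, ref: RefLike = None) -> List[QCFinding]:
    """One error per substitution whose derived state equals its reference state.

    The reference state is the token's own ref letter when written, otherwise
    the supplied (or inferred) reference sequence; bare tokens with no
    resolvable reference are not flaggable.
    """
    findings = []
    for v in h.variants:
        if v.kind != SUBSTITUTION:
            continue
        ref_state = v.ref_state or _ref_base(ref, v.position)
        if ref_state is not None and ref_state == v.derived_state:
            findings.append(QCFinding(
                h.sample_id, REFERENCE_BIAS, ERROR, format_variant(v),
                f"{format_variant(v)} restates the reference "
                f"({ref_state} at {v.position})"))
    return findings


def check_double_specification(h: Haplotype) -> List[QCFinding]:
    """One error per position/insertion-index specified more than once.

    Identical duplicates (``T152C T152C``) and contradictions
    (``T152C T152A``) are both flagged; distinct insertion indices
    (``309.1C 309.2C``) are legal.
    """
    by_site: dict = {}
    for v in h.variants:
        by_site.setdefault((v.position, v.insertion_index), []).append(v)
    findings = []
    for (pos, idx), variants in sorted(by_site.items(),
                                       key=lambda kv: (kv[0][0], kv[0][1] or 0)):
        if len(variants) > 1:
            tokens = ",".join(format_variant(v) for v in variants)
            findings.append(QCFinding(
                h.sample_id, DOUBLE_SPECIFICATION, ERROR, tokens,
                f"position {pos}{f'.{idx}' if idx else ''} specified "
                f"{len(variants)} times ({tokens})"))
    return findings


def check_indel_notation(h: Haplotype) -> List[QCFinding]:
    """One error per raw token with a structurally broken indel notation.

    Examples: ``315.1`` (missing inserted base), ``315.C`` (missing index),
    ``16038G-`` (deletion carrying a derived base).  Well-formed tokens and
    non-indel tokens never fire here.
    """
    findings = []
    for tok in h.raw_tokens:
        if not looks_indel_like(tok):
            continue
        try:
            parse_variant(tok)
        except VariantParseError as exc:
            findings.append(QCFinding(
                h.sample_id, INDEL_NOTATION, ERROR, tok.strip(),
                f"broken insertion/deletion notation: {exc.reason}"))
    return findings


#: HVS-2 C-tract span and its legal 3'-convention insertion anchors.
CTRACT_SPAN = (303, 315)
CTRACT_ANCHORS = (309, 315)


def check_cstretch_convention(h: Haplotype) -> List[QCFinding]:
    """Warnings for HVS-2 C-tract reporting that violates the 3' convention.

    Fires when ``C311T`` is present without the expected ``315.1C``
    insertion, and for any insertion anchored between 303 and 315 at a
    position other than 309 or 315.
    """
    findings = []
    has_311T = any(v.kind == SUBSTITUTION and v.position == 311
                   and v.derived_state == "T" for v in h.variants)
    has_315_1C = any(v.kind == INSERTION and v.position == 315
                     and v.insertion_index == 1 and v.derived_state == "C"
                     for v in h.variants)
    if has_311T and not has_315_1C:
        findings.append(QCFinding(
            h.sample_id, CSTRETCH_CONVENTION, WARNING, "C311T",
            "C311T without the expected 315.1C insertion suggests the "
            "HVS-2 C-tract was not reported in 3' convention"))
    for v in h.variants:
        if (v.kind == INSERTION and CTRACT_SPAN[0] <= v.position <= CTRACT_SPAN[1]
                and v.position not in CTRACT_ANCHORS):
            findings.append(QCFinding(
                h.sample_id, CSTRETCH_CONVENTION, WARNING, format_variant(v),
                f"insertion {format_variant(v)} anchored inside the HVS-2 "
                f"C-tract off the 3' ends (expected anchor 309 or 315)"))
    return findings


_CHECK_ORDER = (
    check_range_violation,
    check_reference_bias,
    check_double_specification,
    check_indel_notation,
    check_cstretch_convention,
)


def run_all_checks(table: Sequence[Haplotype],
                   ref: RefLike = None) -> QCReport:
    """Run the full battery over a table; deterministic finding order.

    Findings are ordered by sample (input order), then by check in the order
    range / reference bias / double specification / indel notation /
    C-tract convention, then by position within a check.
    """
    findings: List[QCFinding] = []
    for h in table:
        for check in _CHECK_ORDER:
            if check is check_reference_bias:
                findings.extend(check(h, ref))
            else:
                findings.extend(check(h))
    return QCReport(tuple(findings), samples_checked=len(table))
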