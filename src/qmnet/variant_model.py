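"""Data model and parser for rCRS-coded mitochondrial control-region variants.

Haplotypes are coded forensically as lists of differences to the revised
Cambridge Reference Sequence (rCRS), e.g. ``A263G 315.1C 16038DEL`` within a
stated sequenced range such as ``16024-576``.  This module defines the
variant, range and haplotype records and the tolerant token dialect used
throughout the package:

* substitutions: ``A263G`` or bare ``263G``; IUPAC ambiguity codes in the
  derived state denote point heteroplasmy (``16214S``);
* insertions: anchor position, dot, 1-based index, inserted base —
  ``315.1C``, ``309.2C``;
* deletions: ``16038DEL``, ``16038del``, ``16038-`` or ``A16038-``.

Parsing is case-insensitive and whitespace inside numbers ("16 038") is
tolerated.  Coordinates are 1-based inclusive rCRS positions (1..16569); no
re-alignment is attempted — tokens are taken at the submitter's alignment.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Tuple

MT_LENGTH = 16569

#: IUPAC single-nucleotide codes accepted as states.
IUPAC_CODES = frozenset("ACGTRYSWKMBDHVN")
#: Ambiguity codes — a derived state in this set marks point heteroplasmy.
IUPAC_AMBIGUOUS = frozenset("RYSWKMBDHVN")
#: Expansion of each IUPAC code to the set of plain bases it covers.
IUPAC_EXPAND: Mapping[str, frozenset] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

SUBSTITUTION = "substitution"
INSERTION = "insertion"
DELETION = "deletion"


class VariantParseError(ValueError):
    """A variant token could not be parsed; names the token and the problem."""

    def __init__(self, token: str, reason: str):
        self.token = token
        self.reason = reason
        super().__init__(f"cannot parse variant token {token!r}: {reason}")


class RangeParseError(ValueError):
    """A sequenced-range expression could not be parsed."""


@dataclass(frozen=True, order=True)
class Variant:
    """One rCRS-coded difference: substitution, insertion or deletion."""

    position: int
    insertion_index: Optional[int] = None
    kind: str = SUBSTITUTION
    ref_state: Optional[str] = None
    derived_state: Optional[str] = None

    def __post_init__(self):
        if not 1 <= self.position <= MT_LENGTH:
            raise VariantParseError(
                str(self.position), f"position outside 1..{MT_LENGTH}")
        if self.kind == INSERTION:
            if self.insertion_index is None or self.insertion_index < 1:
                raise VariantParseError(
                    self.token_guess(), "insertion requires a positive .N index")
            if not self.derived_state:
                raise VariantParseError(
                    self.token_guess(), "insertion requires an inserted base")
        elif self.insertion_index is not None:
            raise VariantParseError(
                self.token_guess(), "insertion index on a non-insertion")
        if self.kind == DELETION:
            if self.derived_state is not None:
                raise VariantParseError(
                    self.token_guess(), "deletion must not carry a derived state")
        elif self.derived_state is None:
            raise VariantParseError(self.token_guess(), "missing derived state")
        for state, label in ((self.ref_state, "reference"),
                             (self.derived_state, "derived")):
            if state is not None and state not in IUPAC_CODES:
                raise VariantParseError(
                    self.token_guess(), f"illegal {label} state {state!r}")

    def token_guess(self) -> str:
        return f"<variant at {self.position}>"

    @property
    def heteroplasmic(self) -> bool:
        """True when the derived state is an IUPAC ambiguity code."""
        return self.derived_state in IUPAC_AMBIGUOUS

    @property
    def sort_key(self) -> Tuple[int, int]:
        return (self.position, self.insertion_index or 0)


_WS = re.compile(r"\s+")
_INSERTION_RE = re.compile(r"^([ACGTRYSWKMBDHVN]?)(\d+)\.(\d+)([A-Z]?)$")
_DELETION_RE = re.compile(r"^([ACGTRYSWKMBDHVN]?)(\d+)(DEL|-)$")
_SUBSTITUTION_RE = re.compile(r"^([ACGTRYSWKMBDHVN]?)(\d+)([A-Z])$")


def _normalize_token(token: str) -> str:
    # typography in submissions: "16 038" and stray case
    return _WS.sub("", token.strip()).upper()


def parse_variant(token: str) -> Variant:
    """Parse one rCRS difference token into a :class:`Variant`.

    Raises :class:`VariantParseError` for malformed tokens, naming the token
    and the offending part.
    """
    text = _normalize_token(token)
    if not text:
        raise VariantParseError(token, "empty token")
    if not any(ch.isdigit() for ch in text):
        raise VariantParseError(token, "no position digits")

    m = _INSERTION_RE.match(text)
    if m:
        ref, pos, idx, base = m.groups()
        if not base:
            raise VariantParseError(token, "insertion missing inserted base")
        if base not in IUPAC_CODES:
            raise VariantParseError(token, f"illegal inserted base {base!r}")
        if int(idx) < 1:
            raise VariantParseError(token, "insertion index must be >= 1")
        return Variant(position=_checked_pos(token, pos), kind=INSERTION,
                       insertion_index=int(idx),
                       ref_state=ref or None, derived_state=base)
    if "." in text:
        raise VariantParseError(token, "malformed insertion (expect <pos>.<idx><base>)")

    m = _DELETION_RE.match(text)
    if m:
        ref, pos, _suffix = m.groups()
        return Variant(position=_checked_pos(token, pos), kind=DELETION,
                       ref_state=ref or None, derived_state=None)
    if text.endswith(("-", "DEL")):
        raise VariantParseError(token, "malformed deletion token")

    m = _SUBSTITUTION_RE.match(text)
    if m:
        ref, pos, derived = m.groups()
        if derived not in IUPAC_CODES:
            raise VariantParseError(token, f"illegal derived state {derived!r}")
        return Variant(position=_checked_pos(token, pos),
                       ref_state=ref or None, derived_state=derived)
    raise VariantParseError(token, "unrecognized token shape")


def _checked_pos(token: str, digits: str) -> int:
    pos = int(digits)
    if not 1 <= pos <= MT_LENGTH:
        raise VariantParseError(token, f"position {pos} outside 1..{MT_LENGTH}")
    return pos


def format_variant(v: Variant) -> str:
    """Canonical uppercase token; inverse of :func:`parse_variant`."""
    ref = v.ref_state or ""
    if v.kind == INSERTION:
        return f"{v.position}.{v.insertion_index}{v.derived_state}"
    if v.kind == DELETION:
        return f"{ref}{v.position}DEL"
    return f"{ref}{v.position}{v.derived_state}"


_INDEL_HINT = re.compile(r"[.\-]|DEL", re.IGNORECASE)


def looks_indel_like(token: str) -> bool:
    """Heuristic: does the raw token try to denote an insertion/deletion?"""
    return bool(_INDEL_HINT.search(_normalize_token(token)))


@dataclass(frozen=True)
class SequenceRange:
    """Sequenced range as ordered, non-overlapping 1-based inclusive intervals.

    The control-region origin wrap (``16024-576``) is stored split as two
    intervals ``(16024, 16569), (1, 576)``.
    """

    intervals: Tuple[Tuple[int, int], ...]

    def __post_init__(self):
        seen = []
        for start, end in self.intervals:
            if not (1 <= start <= MT_LENGTH and 1 <= end <= MT_LENGTH):
                raise RangeParseError(
                    f"interval {start}-{end} outside 1..{MT_LENGTH}")
            if start > end:
                raise RangeParseError(
                    f"interval {start}-{end} not normalized (start > end)")
            for s, e in seen:
                if start <= e and s <= end:
                    raise RangeParseError(
                        f"interval {start}-{end} overlaps {s}-{e}")
            seen.append((start, end))

    def covers(self, position: int) -> bool:
        return any(s <= position <= e for s, e in self.intervals)

    def __str__(self) -> str:
        return "; ".join(f"{s}-{e}" for s, e in self.intervals)


def parse_range(text: str) -> SequenceRange:
    """Parse ``"73-340"`` / ``"16024-576"`` / ``"16024-16365; 73-340"``.

    An interval written with start > end wraps the 16569/1 origin and is
    split into two intervals.
    """
    if not text or not text.strip():
        raise RangeParseError("empty range expression")
    parts = [p for chunk in text.split(";") for p in chunk.split()] \
        if ";" in text else text.split()
    intervals = []
    for part in parts:
        part = part.strip()
        if not part:
            continue
        m = re.match(r"^(\d+)\s*-\s*(\d+)$", part)
        if not m:
            raise RangeParseError(f"malformed interval {part!r}")
        start, end = int(m.group(1)), int(m.group(2))
        if not (1 <= start <= MT_LENGTH and 1 <= end <= MT_LENGTH):
            raise RangeParseError(
                f"interval {part!r} outside 1..{MT_LENGTH}")
        if start > end:  # origin wrap
            intervals.append((start, MT_LENGTH))
            intervals.append((1, end))
        else:
            intervals.append((start, end))
    if not intervals:
        raise RangeParseError("empty range expression")
    return SequenceRange(tuple(intervals))


def covers(rng: SequenceRange, position: int) -> bool:
    """True iff *position* lies inside some interval of *rng* (inclusive)."""
    return rng.covers(position)


@dataclass(frozen=True)
class Haplotype:
    """One sample: id, sequenced range, variants, optional haplogroup label.

    ``raw_tokens`` retains the submitter's spelling of every token, including
    structurally broken indel notations that could not be parsed; these are
    inspected by the notation QC check.
    """

    sample_id: str
    range: SequenceRange
    variants: Tuple[Variant, ...]
    haplogroup: Optional[str] = None
    raw_tokens: Tuple[str, ...] = ()

    def __post_init__(self):
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")
        object.__setattr__(
            self, "variants",
            tuple(sorted(self.variants, key=lambda v: v.sort_key)))

    def with_variants(self, variants: Iterable[Variant]) -> "Haplotype":
        return Haplotype(self.sample_id, self.range, tuple(variants),
                         self.haplogroup, self.raw_tokens)


def make_haplotype(sample_id: str, range_text: str, tokens: Sequence[str],
                   haplogroup: Optional[str] = None,
                   tolerate_broken_indels: bool = False) -> Haplotype:
    """Build a haplotype from raw text fields.

    With ``tolerate_broken_indels`` a token that looks indel-like but fails
    to parse is kept in ``raw_tokens`` only, so the QC battery can flag it;
    any other malformed token raises :class:`VariantParseError`.
    """
    variants = []
    for tok in tokens:
        try:
            variants.append(parse_variant(tok))
        except VariantParseError:
            if tolerate_broken_indels and looks_indel_like(tok):
                continue
            raise
    return Haplotype(sample_id, parse_range(range_text), tuple(variants),
                     haplogroup, tuple(tokens))


@dataclass(frozen=True)
class ReferenceSequence:
    """Full-length (16569 nt) reference, e.g. the rCRS from a FASTA file."""

    bases: str
    source_label: str = "reference"

    def __post_init__(self):
        if len(self.bases) != MT_LENGTH:
            raise ValueError(
                f"reference must be {MT_LENGTH} bases, got {len(self.bases)}")
        bad = set(self.bases.upper()) - set("ACGTN")
        if bad:
            raise ValueError(f"illegal reference characters: {sorted(bad)}")
        object.__setattr__(self, "bases", self.bases.upper())

    def base_at(self, position: int) -> str:
        return self.bases[position - 1]


def infer_reference_states(haplotypes: Sequence[Haplotype]) -> Mapping[int, str]:
    """Per-position reference states inferred from ref-prefixed tokens.

    When no FASTA reference is supplied, the consensus of the reference
    letters that submitters wrote (the ``A`` of ``A263G``) stands in; a
    position is mapped only when all stated letters agree.
    """
    votes: dict = {}
    for h in haplotypes:
        for v in h.variants:
            if v.kind != INSERTION and v.ref_state:
                votes.setdefault(v.position, set()).add(v.ref_state)
    return {pos: states.pop() for pos, states in votes.items()
            if len(states) == 1}
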