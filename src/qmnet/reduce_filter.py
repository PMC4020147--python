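"""Filter passage and reduction to a condensed character matrix.

Quasi-median networks of raw control-region tables are unreadable: highly
recurrent, well-documented mutations generate reticulations that carry no
quality signal.  The pipeline therefore first removes every variant matched
by a filter list (the EMPOPall/EMPOPspeedy idea), then turns the surviving
variants into a character matrix (one column per variable site), and finally
condenses characters that split the samples identically into single weighted
characters.  Only the condensed matrix enters the quasi-median closure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .variant_model import (
    DELETION,
    INSERTION,
    IUPAC_EXPAND,
    SUBSTITUTION,
    Haplotype,
    Variant,
    format_variant,
    infer_reference_states,
    parse_variant,
)

logger = logging.getLogger("qmnet")

MUTATION_MODE = "mutation"
POSITION_MODE = "position"

#: State used for "insertion absent" / "base deleted" in indel characters.
ABSENT = "-"
#: Baseline state when the reference letter at a position is unknown: all
#: non-carriers share the (single, definite) rCRS state there even when no
#: token or reference sequence reveals its letter.
UNKNOWN_REF = "?"


@dataclass(frozen=True)
class FilterList:
    """Set of documented mutations (or positions) to remove before networking."""

    name: str
    entries: frozenset
    mode: str = MUTATION_MODE

    def __post_init__(self):
        if self.mode not in (MUTATION_MODE, POSITION_MODE):
            raise ValueError(f"unknown filter mode {self.mode!r}")
        if self.mode == POSITION_MODE:
            bad = [e for e in self.entries if not str(e).isdigit()]
            if bad:
                raise ValueError(f"position-mode entries must be bare positions: {bad}")

    @property
    def is_empty(self) -> bool:
        return not self.entries


def _match_key(v: Variant) -> tuple:
    # mutation-mode identity: position + kind + insertion index + derived state
    return (v.position, v.kind, v.insertion_index, v.derived_state)


def apply_filter(table: Sequence[Haplotype], f: FilterList,
                 match_iupac: bool = False) -> List[Haplotype]:
    """Return copies of the haplotypes with every filter-matched variant removed.

    Mutation mode matches position + kind + derived state (insertions also by
    index); position mode removes any variant at a listed position.  With
    ``match_iupac`` an ambiguous derived state (point heteroplasmy, e.g.
    ``366R``) is also removed when a filter entry's plain derived state is
    among the bases it covers.  Sample set and order are unchanged.
    """
    if f.mode == POSITION_MODE:
        positions = {int(e) for e in f.entries}

        def hits(v: Variant) -> bool:
            return v.position in positions
    else:
        keys = set()
        by_site: Dict[tuple, set] = {}
        for entry in f.entries:
            ev = parse_variant(str(entry))
            keys.add(_match_key(ev))
            if ev.derived_state:
                by_site.setdefault(
                    (ev.position, ev.kind, ev.insertion_index), set()
                ).add(ev.derived_state)

        def hits(v: Variant) -> bool:
            if _match_key(v) in keys:
                return True
            if match_iupac and v.derived_state:
                entry_states = by_site.get(
                    (v.position, v.kind, v.insertion_index), ())
                covered = IUPAC_EXPAND.get(v.derived_state, frozenset())
                return any(s in covered for s in entry_states)
            return False

    return [h.with_variants(v for v in h.variants if not hits(v))
            for h in table]


@dataclass(frozen=True)
class Character:
    """One variable site: a substitution position, an indexed insertion slot,
    or a deletion, with its observed state alphabet and baseline state."""

    position: int
    insertion_index: Optional[int]
    kind: str
    alphabet: Tuple[str, ...]
    baseline: str

    @property
    def key(self) -> tuple:
        return (self.position, self.insertion_index or 0,
                {SUBSTITUTION: 0, DELETION: 1, INSERTION: 2}[self.kind])

    def token(self, from_state: str, to_state: str) -> str:
        """Display label for the transition between two of this character's states."""
        if self.kind == INSERTION:
            if from_state == ABSENT:
                return f"{self.position}.{self.insertion_index}{to_state}"
            if to_state == ABSENT:
                return f"{self.position}.{self.insertion_index}{from_state}"
            return f"{self.position}.{self.insertion_index}{from_state}>{to_state}"
        if self.kind == DELETION:
            ref = from_state if from_state != ABSENT else to_state
            ref = "" if ref in (ABSENT, UNKNOWN_REF) else ref
            return f"{ref}{self.position}DEL"
        if from_state == UNKNOWN_REF:
            return f"{self.position}{to_state}"
        if to_state == UNKNOWN_REF:
            return f"{self.position}{from_state}"
        return f"{from_state}{self.position}{to_state}"


@dataclass(frozen=True)
class CharacterMatrix:
    """Sample-by-character state matrix; constant characters already removed."""

    characters: Tuple[Character, ...]
    rows: Mapping[str, Tuple[str, ...]]
    sample_order: Tuple[str, ...]


def build_character_matrix(table: Sequence[Haplotype],
                           ref: Optional[Mapping[int, str]] = None) -> CharacterMatrix:
    """Turn post-filter haplotypes into a character matrix.

    One character per substitution position / (position, insertion index) /
    deletion position with at least one carrier; a sample's state is its
    derived state there, otherwise the baseline (token-stated reference when
    consistently known, else the majority state).  A sample whose sequenced
    range does not cover a character's position also receives the baseline
    state — closure over a missing-data alphabet is undefined — and a
    warning is logged.  Constant characters are dropped.
    """
    sample_order = tuple(h.sample_id for h in table)
    inferred = dict(infer_reference_states(table))
    if ref:
        inferred.update(ref)

    # collect carriers per site
    sites: Dict[tuple, Dict[str, str]] = {}
    site_kind: Dict[tuple, tuple] = {}
    for h in table:
        for v in h.variants:
            key = (v.position, v.insertion_index or 0,
                   {SUBSTITUTION: 0, DELETION: 1, INSERTION: 2}[v.kind])
            state = ABSENT if v.kind == DELETION else v.derived_state
            sites.setdefault(key, {})[h.sample_id] = state
            site_kind[key] = (v.position, v.insertion_index, v.kind)

    ranges = {h.sample_id: h.range for h in table}
    characters: List[Character] = []
    columns: List[Dict[str, str]] = []
    for key in sorted(sites):
        position, insertion_index, kind = site_kind[key]
        carriers = sites[key]
        if kind == INSERTION:
            baseline = ABSENT
        else:
            # non-carriers share the rCRS state: its letter comes from the
            # reference sequence or the consensus of ref-prefixed tokens,
            # else stays a placeholder (labels then print bare, e.g. "320T")
            baseline = inferred.get(position, UNKNOWN_REF)
        states = {}
        uncovered = []
        for sid in sample_order:
            if sid in carriers:
                states[sid] = carriers[sid]
            else:
                if not ranges[sid].covers(position):
                    uncovered.append(sid)
                states[sid] = baseline
        if uncovered:
            logger.warning(
                "character %s: %d sample(s) do not cover position %d; "
                "baseline state %r assumed (e.g. %s)",
                key, len(uncovered), position, baseline, uncovered[0])
        alphabet = tuple(sorted(set(states.values())))
        if len(alphabet) < 2:
            continue  # constant after filtering
        characters.append(Character(position, insertion_index, kind,
                                    alphabet, baseline))
        columns.append(states)

    rows = {sid: tuple(col[sid] for col in columns) for sid in sample_order}
    return CharacterMatrix(tuple(characters), rows, sample_order)


@dataclass(frozen=True)
class CondensedCharacter:
    """Characters merged because they split the samples identically.

    ``weight`` is the member count; condensed states are the strings
    "0", "1", ... assigned by first appearance in sample order, and
    ``state_map`` records, per member character, the member state behind
    each condensed state.
    """

    members: Tuple[Character, ...]
    state_map: Tuple[Mapping[str, str], ...]  # per member: condensed -> member state

    @property
    def weight(self) -> int:
        return len(self.members)

    def label(self, from_state: str, to_state: str) -> str:
        """Branch label for a condensed-state transition, members joined by '+'.

        Edges are undirected; for display each member transition is oriented
        baseline -> derived when the baseline participates.
        """
        parts = []
        for member, smap in zip(self.members, self.state_map):
            mf, mt = smap[from_state], smap[to_state]
            if mt == member.baseline:
                mf, mt = mt, mf
            parts.append(member.token(mf, mt))
        return "+".join(parts)

    @property
    def alphabet(self) -> Tuple[str, ...]:
        return tuple(self.state_map[0].keys())


@dataclass(frozen=True)
class CondensedMatrix:
    """Distinct reduced state vectors with the samples sharing each."""

    characters: Tuple[CondensedCharacter, ...]
    row_vectors: Tuple[Tuple[str, ...], ...]
    row_samples: Tuple[Tuple[str, ...], ...]  # parallel to row_vectors

    @property
    def n_samples(self) -> int:
        return sum(len(s) for s in self.row_samples)


def _partition_signature(column: Sequence[str]) -> Tuple[int, ...]:
    """Canonical label-free partition: class index by first appearance."""
    seen: Dict[str, int] = {}
    out = []
    for state in column:
        if state not in seen:
            seen[state] = len(seen)
        out.append(seen[state])
    return tuple(out)


def condense(m: CharacterMatrix) -> Tuple[CondensedMatrix, Tuple[CondensedCharacter, ...]]:
    """Merge identically-partitioning characters; group identical rows.

    Characters inducing the same partition of samples into state classes
    become one condensed character whose weight is the member count.
    Distinct reduced state vectors become distinct rows, each keeping the
    ordered list of sample ids sharing it.
    """
    columns = [[m.rows[sid][i] for sid in m.sample_order]
               for i in range(len(m.characters))]
    groups: Dict[Tuple[int, ...], List[int]] = {}
    order: List[Tuple[int, ...]] = []
    for i, col in enumerate(columns):
        sig = _partition_signature(col)
        if sig not in groups:
            groups[sig] = []
            order.append(sig)
        groups[sig].append(i)

    condensed: List[CondensedCharacter] = []
    cond_columns: List[List[str]] = []
    for sig in order:
        member_idx = groups[sig]
        members = tuple(m.characters[i] for i in member_idx)
        # condensed state "k" = partition class k; per member, the member
        # state seen in that class
        state_map = []
        for i in member_idx:
            cmap: Dict[str, str] = {}
            for cls, st in zip(sig, columns[i]):
                cmap.setdefault(str(cls), st)
            state_map.append(cmap)
        condensed.append(CondensedCharacter(members, tuple(state_map)))
        cond_columns.append([str(cls) for cls in sig])

    row_vectors: List[Tuple[str, ...]] = []
    row_samples: List[List[str]] = []
    index: Dict[Tuple[str, ...], int] = {}
    for j, sid in enumerate(m.sample_order):
        vec = tuple(col[j] for col in cond_columns)
        if vec not in index:
            index[vec] = len(row_vectors)
            row_vectors.append(vec)
            row_samples.append([])
        row_samples[index[vec]].append(sid)

    cm = CondensedMatrix(tuple(condensed), tuple(row_vectors),
                         tuple(tuple(s) for s in row_samples))
    return cm, tuple(condensed)


def reduce_table(table: Sequence[Haplotype], f: FilterList,
                 match_iupac: bool = False,
                 ref: Optional[Mapping[int, str]] = None) -> CondensedMatrix:
    """Convenience: filter, build the character matrix, condense."""
    filtered = apply_filter(table, f, match_iupac=match_iupac)
    matrix = build_character_matrix(filtered, ref=ref)
    cm, _ = condense(matrix)
    return cm
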