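"""Synthetic haplotype tables emulating submission-QC scenarios.

Real submission data sets are confidential, so tests and demonstrations run
on generated tables with a known truth log: a tree-like backbone of
haplogroup lineages built from "documented" variants (which the emitted
filter list removes exactly), plus planted novelties and errors —

* phantom mutations shared across several lineages (the position-366
  pattern: an artifact recurring in unrelated haplogroups),
* range violations, reference-bias tokens, duplicated tokens, structurally
  broken indel notations,
* length-heteroplasmy reporting artifacts (C311T without the expected
  315.1C insertion),
* a high-frequency artifactual deletion (the 16038 pattern).

Because the filter removes exactly the backbone, the post-filter network
structure is fully predicted by the truth log: samples group by their set of
planted distinguishing variants.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from . import qc_checks
from .reduce_filter import FilterList, MUTATION_MODE
from .table_io import HaplotypeTable
from .variant_model import (
    SUBSTITUTION,
    Haplotype,
    Variant,
    format_variant,
    make_haplotype,
    parse_variant,
)

DEFAULT_RANGE = "16024-576"  # full control region, wrapped at the origin

#: positions reserved for planted signals; backbone variants avoid them
_BACKBONE_POOL = tuple(range(16051, 16569, 7))


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic data set (all plants deterministic in seed)."""

    n_samples: int
    n_backbone_lineages: int = 5
    backbone_variants_per_lineage: int = 2
    seed: int = 0
    range_text: str = DEFAULT_RANGE
    #: (token, carrier count); carriers spread across >= 2 lineages
    phantoms: Tuple[Tuple[str, int], ...] = ()
    #: (token, host token): planted in the first carrier of the host phantom
    overlap_phantoms: Tuple[Tuple[str, str], ...] = ()
    #: each token planted once, in a sample whose range does not cover it
    range_violations: Tuple[str, ...] = ()
    #: reference-restating tokens such as "A263A", one sample each
    reference_bias: Tuple[str, ...] = ()
    #: number of samples whose first backbone token is written twice
    duplicate_tokens: int = 0
    #: raw, structurally broken indel tokens, one sample each
    broken_indels: Tuple[str, ...] = ()
    #: samples given C311T without the expected 315.1C insertion
    cstretch_count: int = 0
    #: (deletion token, carrier count)
    deletions: Tuple[Tuple[str, int], ...] = ()

    def __post_init__(self):
        counts = [n for _, n in self.phantoms] + [n for _, n in self.deletions]
        counts += [self.cstretch_count, self.duplicate_tokens,
                   len(self.range_violations), len(self.reference_bias),
                   len(self.broken_indels)]
        if any(c > self.n_samples for c in counts):
            raise ValueError("planted carrier count exceeds n_samples")
        if self.n_samples < 1 or self.n_backbone_lineages < 1:
            raise ValueError("need at least one sample and one lineage")


@dataclass(frozen=True)
class FixtureTruth:
    """Ground truth: predicts every QC finding and every post-filter node."""

    seed: int
    #: (sample_id, QC code, token) per planted error/warning instance
    planted_findings: Tuple[Tuple[str, str, str], ...]
    #: canonical token -> carrier sample ids, for every planted variant
    carriers: Mapping[str, Tuple[str, ...]]
    #: (sorted distinguishing tokens, sample ids) per expected network node
    node_groups: Tuple[Tuple[Tuple[str, ...], Tuple[str, ...]], ...]
    filter_entries: Tuple[str, ...]

    def group_for(self, tokens: Sequence[str]) -> Tuple[str, ...]:
        want = tuple(sorted(tokens))
        for toks, samples in self.node_groups:
            if toks == want:
                return samples
        raise KeyError(f"no planted group {want}")


class _Cursor:
    """Deterministic without-replacement sample picker (wraps when exhausted)."""

    def __init__(self, sample_ids: Sequence[str], rng: random.Random):
        self._order = list(sample_ids)
        rng.shuffle(self._order)
        self._pos = 0

    def take(self, count: int) -> List[str]:
        out = []
        for _ in range(count):
            out.append(self._order[self._pos % len(self._order)])
            self._pos += 1
        return out


def generate(spec: FixtureSpec) -> Tuple[HaplotypeTable, FilterList, FixtureTruth]:
    """Build the table, the filter that removes exactly the backbone, and truth."""
    rng = random.Random(spec.seed)
    n = spec.n_samples
    sample_ids = [f"S{i:04d}" for i in range(1, n + 1)]
    lineage_of = {sid: i % spec.n_backbone_lineages
                  for i, sid in enumerate(sample_ids)}

    reserved = set()
    for token, _ in spec.phantoms:
        reserved.add(parse_variant(token).position)
    for token, _ in spec.overlap_phantoms:
        reserved.add(parse_variant(token).position)
    for token in spec.range_violations + spec.reference_bias:
        reserved.add(parse_variant(token).position)
    for token, _ in spec.deletions:
        reserved.add(parse_variant(token).position)
    reserved.update((311, 315))

    pool = [p for p in _BACKBONE_POOL if p not in reserved]
    need = spec.n_backbone_lineages * spec.backbone_variants_per_lineage
    if need > len(pool):
        raise ValueError("backbone pool exhausted; fewer lineages/variants needed")
    positions = rng.sample(pool, need)
    backbone: List[List[str]] = []
    for l in range(spec.n_backbone_lineages):
        tokens = []
        for j in range(spec.backbone_variants_per_lineage):
            pos = positions[l * spec.backbone_variants_per_lineage + j]
            tokens.append(f"{pos}{rng.choice('ACGT')}")
        backbone.append(tokens)

    extra: Dict[str, List[str]] = {sid: [] for sid in sample_ids}
    findings: List[Tuple[str, str, str]] = []
    carriers: Dict[str, Tuple[str, ...]] = {}
    cursor = _Cursor(sample_ids, rng)

    def spread_lineages(chosen: List[str]) -> List[str]:
        # planted phantoms must recur across lineages to mimic artifacts
        if len(chosen) >= 2 and len({lineage_of[s] for s in chosen}) < 2:
            for sid in sample_ids:
                if lineage_of[sid] != lineage_of[chosen[0]] and sid not in chosen:
                    chosen[-1] = sid
                    break
        return chosen

    for token, count in spec.phantoms:
        canon = format_variant(parse_variant(token))
        chosen = spread_lineages(cursor.take(count))
        for sid in chosen:
            extra[sid].append(token)
        carriers[canon] = tuple(chosen)
    for token, host in spec.overlap_phantoms:
        canon = format_variant(parse_variant(token))
        host_canon = format_variant(parse_variant(host))
        sid = carriers[host_canon][0]
        extra[sid].append(token)
        carriers[canon] = (sid,)
    for token, count in spec.deletions:
        canon = format_variant(parse_variant(token))
        chosen = cursor.take(count)
        for sid in chosen:
            extra[sid].append(token)
        carriers[canon] = tuple(chosen)
    for sid in cursor.take(spec.cstretch_count):
        extra[sid].append("C311T")
        findings.append((sid, qc_checks.CSTRETCH_CONVENTION, "C311T"))
        carriers.setdefault("C311T", ())
        carriers["C311T"] = carriers["C311T"] + (sid,)
    for token in spec.range_violations:
        canon = format_variant(parse_variant(token))
        sid = cursor.take(1)[0]
        extra[sid].append(token)
        findings.append((sid, qc_checks.RANGE_VIOLATION, canon))
        carriers[canon] = (sid,)
    for token in spec.reference_bias:
        canon = format_variant(parse_variant(token))
        sid = cursor.take(1)[0]
        extra[sid].append(token)
        findings.append((sid, qc_checks.REFERENCE_BIAS, canon))
        carriers[canon] = (sid,)
    for sid in cursor.take(spec.duplicate_tokens):
        dup = backbone[lineage_of[sid]][0]
        extra[sid].append(dup)  # second copy of an existing backbone token
        canon = format_variant(parse_variant(dup))
        findings.append((sid, qc_checks.DOUBLE_SPECIFICATION,
                         f"{canon},{canon}"))
    for token in spec.broken_indels:
        sid = cursor.take(1)[0]
        extra[sid].append(token)
        findings.append((sid, qc_checks.INDEL_NOTATION, token))

    haplotypes = []
    for sid in sample_ids:
        tokens = list(backbone[lineage_of[sid]]) + extra[sid]
        haplotypes.append(make_haplotype(
            sid, spec.range_text, tokens, haplogroup=f"L{lineage_of[sid]}",
            tolerate_broken_indels=True))

    filter_entries = frozenset(
        format_variant(parse_variant(t)) for lin in backbone for t in lin)
    flt = FilterList(name=f"backbone_seed{spec.seed}", entries=filter_entries,
                     mode=MUTATION_MODE)

    node_groups = _predict_node_groups(spec, sample_ids, extra, filter_entries)
    truth = FixtureTruth(
        seed=spec.seed,
        planted_findings=tuple(findings),
        carriers=carriers,
        node_groups=node_groups,
        filter_entries=tuple(sorted(filter_entries)))
    return HaplotypeTable(tuple(haplotypes), source_path="<generated>"), flt, truth


def _predict_node_groups(spec, sample_ids, extra, filter_entries):
    """Group samples by their distinguishing post-filter variant sets.

    Distinguishing = parseable, not filtered, and not reference-restating
    (a token like A263A leaves the carrier in the baseline state, so it
    cannot separate a node).
    """
    groups: Dict[Tuple[str, ...], List[str]] = {}
    order: List[Tuple[str, ...]] = []
    for sid in sample_ids:
        keep = set()
        for token in extra[sid]:
            try:
                v = parse_variant(token)
            except Exception:
                continue  # broken indel notation never reaches the matrix
            canon = format_variant(v)
            if canon in filter_entries:
                continue
            if (v.kind == SUBSTITUTION and v.ref_state is not None
                    and v.ref_state == v.derived_state):
                continue
            keep.add(canon)
        key = tuple(sorted(keep))
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(sid)
    return tuple((key, tuple(groups[key])) for key in order)


def conflict_quartet(k: int) -> HaplotypeTable:
    """Table whose reduced matrix is k pairwise-incompatible binary characters
    with all 2^k state combinations sampled (closure = the k-hypercube)."""
    if not 1 <= k <= 10:
        raise ValueError("k must be in 1..10")
    haplotypes = []
    for i in range(2 ** k):
        tokens = [f"{16101 + j}T" for j in range(k) if (i >> j) & 1]
        haplotypes.append(make_haplotype(
            f"S{i + 1:04d}", "16024-16569", tokens))
    return HaplotypeTable(tuple(haplotypes), source_path="<conflict_quartet>")


def preset_spec(name: str, seed: int = 0) -> FixtureSpec:
    """Named scenario templates.

    ``fig1b``: 201 samples whose documented backbone is fully filtered plus
    five singleton novel variants — a six-node star.  ``datasetA_like``: 320
    samples with the recurring position-366 phantom in 18 carriers (17
    sharing one node, 1 set apart by a companion novelty) and the 320T/320G
    phantom pair.  ``datasetB_like``: 230 samples with a 173-carrier
    artifactual deletion at 16038 and 106 samples reporting C311T without
    315.1C.
    """
    if name == "fig1b":
        return FixtureSpec(
            n_samples=201, n_backbone_lineages=5,
            backbone_variants_per_lineage=2, seed=seed,
            phantoms=(("16214S", 1), ("T16092C", 1), ("A16166G", 1),
                      ("C16364T", 1), ("G16129A", 1)))
    if name == "datasetA_like":
        return FixtureSpec(
            n_samples=320, n_backbone_lineages=8,
            backbone_variants_per_lineage=3, seed=seed,
            phantoms=(("A366G", 18), ("C320T", 2), ("C320G", 2)),
            overlap_phantoms=(("C16261T", "A366G"),))
    if name == "datasetB_like":
        return FixtureSpec(
            n_samples=230, n_backbone_lineages=6,
            backbone_variants_per_lineage=3, seed=seed,
            phantoms=(("A366G", 5),),
            deletions=(("A16038-", 173),),
            cstretch_count=106)
    raise ValueError(f"unknown preset {name!r} "
                     "(expected fig1b, datasetA_like or datasetB_like)")


PRESETS = ("fig1b", "datasetA_like", "datasetB_like")
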