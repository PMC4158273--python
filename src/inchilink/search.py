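"""Connectivity search: key_search / cpd_search under the A-H criteria.

A query resolves to a :class:`QueryContext` (its FIKHB, and where available
its full key and parsed InChI), then :func:`execute` matches registry
structures under one of four component-mapping relations (criterion C):

=====  ==========================================  ==================================
code   relation                                    lookup
=====  ==========================================  ==================================
0      Matches                                     pattern match on the query itself
1      Matches a component of                      parents of the query FIKHB
2      Has a component which matches               pattern match per query component
3      Has a component which matches a component   parents of each query component
=====  ==========================================  ==================================

C=4 runs all four simultaneously.  The pattern (criterion B) is either the
14-character FIKHB (connectivity only) or the key minus its proton flag
(first 25 characters, i.e. identical stereochemistry and isotopes too).
Component sub-queries — the parents-of lookups of relations 1 and 3 — are
blocked for components that occur in too many compounds (criterion D) or
whose connectivity string is too short (criterion E), so that querying a
hydrochloride does not fan out to every hydrochloride salt in the registry.

Every hit is one src_compound_id-to-structure assignment, annotated with
its mapping relation, optional salt/mixture labels, and per-layer
p/b/t/m/s/i differences between the retrieved InChI and the query InChI.
Each unique retrieved InChI is parsed and compared exactly once per query.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import inchi_core, keys
from .inchi_core import LayerDiff, ParsedInChI
from .store import Registry, StructureRow

logger = logging.getLogger(__name__)

#: Table of component-mapping relations (criterion C codes 0-3)
MAPPING_RELATIONS = {
    0: "Matches",
    1: "Matches a component of",
    2: "Has a component which matches",
    3: "Has a component which matches a component of",
}

DEFAULT_FREQUENCY_BLOCK = 200
FREQUENCY_HARD_CAP = 100_000


class CriteriaError(ValueError):
    """Raised for an out-of-range search criterion value."""


@dataclass
class SearchCriteria:
    """The eight user-settable criteria A-H, all defaulting to 0.

    A: source filter (0 = all sources, else a src_id).
    B: pattern (0 = FIKHB, 1 = InChIKey minus proton flag).
    C: component mapping (0-3 = one relation, 4 = all four).
    D: frequency-block level (threshold = 200·10^D, capped).
    E: connectivity-length block (components with connectivity length <= E
       are skipped in sub-queries; 0 blocks nothing).
    F: labels (0 = attach, 1 = suppress).
    G: assignment scope (0 = current only, 1 = current and obsolete).
    H: output shape (0 = flat, 1 = grouped by source; serialization-level).
    """

    A: int = 0
    B: int = 0
    C: int = 0
    D: int = 0
    E: int = 0
    F: int = 0
    G: int = 0
    H: int = 0

    def __post_init__(self) -> None:
        checks = [
            ("A", self.A >= 0),
            ("B", self.B in (0, 1)),
            ("C", self.C in (0, 1, 2, 3, 4)),
            ("D", self.D >= 0),
            ("E", self.E >= 0),
            ("F", self.F in (0, 1)),
            ("G", self.G in (0, 1)),
            ("H", self.H in (0, 1)),
        ]
        for name, ok in checks:
            if not ok:
                raise CriteriaError(
                    f"criterion {name}={getattr(self, name)} out of range"
                )


#: number of user-settable search criteria
N_CRITERIA = 8


@dataclass
class QueryContext:
    """A resolved query term: its FIKHB, and, when the registry holds an
    InChI for it, the parsed query InChI and (lazily) its components."""

    query_fikhb: str
    query_key: str | None = None
    query_inchi: ParsedInChI | None = None
    components: list[tuple[ParsedInChI, str]] | None = None
    status: str | None = None

    @property
    def runnable(self) -> bool:
        return self.status is None


@dataclass
class HitRecord:
    """One matching src_compound_id-to-structure assignment."""

    src_compound_id: str
    src_id: int
    source_name: str
    standardinchi: str
    standardinchikey: str
    relation: int
    labels: list[str] = field(default_factory=list)
    diff: LayerDiff | None = None
    current: int = 1

    def sort_key(self) -> tuple:
        return (self.relation, self.src_id, self.src_compound_id)


@dataclass
class SearchStats:
    """Instrumentation filled in by execute(); the parse-once contract is
    checked against ``retrieved_parses``."""

    retrieved_parses: int = 0
    unique_hit_inchis: int = 0
    blocked_components: list[str] = field(default_factory=list)


def freq_threshold(d: int) -> int:
    """Frequency-block threshold for criterion D: 200 by default, one decade
    per level, and never above a hard cap (the block cannot be fully
    overridden)."""
    if d < 0:
        raise CriteriaError("criterion D must be non-negative")
    return min(DEFAULT_FREQUENCY_BLOCK * 10**d, FREQUENCY_HARD_CAP)


def resolve_key_query(reg: Registry, term: str) -> QueryContext:
    """Resolve a key_search term: a full 27-character Standard InChIKey or
    a bare 14-character FIKHB.

    A full key is looked up in the registry; without a stored InChI for it
    the query cannot run (status "no query InChI") because layer
    comparisons need both a query and a retrieved InChI.  A bare FIKHB
    queries on connectivity alone: the context carries no query InChI and
    hits will carry no diff columns.
    """
    term = term.strip()
    if len(term) == keys.FIKHB_LENGTH:
        return QueryContext(query_fikhb=keys.fikhb_of(term))
    keys.validate_key(term)
    structure = reg.structure_by_key(term)
    if structure is None or structure.standardinchi is None:
        return QueryContext(
            query_fikhb=keys.fikhb_of(term),
            query_key=term,
            status="no query InChI",
        )
    return QueryContext(
        query_fikhb=structure.fikhb,
        query_key=structure.standardinchikey,
        query_inchi=inchi_core.parse(structure.standardinchi),
    )


def resolve_cpd_query(reg: Registry, src_compound_id: str, src_id: int) -> QueryContext:
    """Resolve a cpd_search term: a source's own compound identifier plus
    the src_id that disambiguates the source."""
    reg.source(src_id)  # raises RegistryError for an unknown source
    uci = reg.current_assignment(src_compound_id, src_id)
    if uci is None:
        return QueryContext(query_fikhb="", status="unknown src_compound_id")
    structure = reg.structure_by_uci(uci)
    assert structure is not None
    if structure.standardinchi is None:
        return QueryContext(
            query_fikhb=structure.fikhb,
            query_key=structure.standardinchikey,
            status="no query InChI",
        )
    return QueryContext(
        query_fikhb=structure.fikhb,
        query_key=structure.standardinchikey,
        query_inchi=inchi_core.parse(structure.standardinchi),
    )


def load_label_table(path: str | Path) -> dict[str, str]:
    """Read the FIKHB -> label TSV used to tag common salts and mixtures."""
    table: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("fikhb"):
                continue
            fikhb, _, label = line.partition("\t")
            if label:
                table[fikhb.strip()] = label.strip()
    return table


def annotate_labels(
    component_fikhbs: list[str], label_table: dict[str, str]
) -> list[str]:
    """Label texts for every component FIKHB present in the label table."""
    return [label_table[f] for f in component_fikhbs if f in label_table]


def _query_components(
    reg: Registry, ctx: QueryContext
) -> list[tuple[ParsedInChI, str]]:
    """The query's single-component InChIs with their keys, computed once
    and cached on the context.  A single-component query is its own only
    component; without a query InChI there are no components to search."""
    if ctx.components is not None:
        return ctx.components
    if ctx.query_inchi is None:
        ctx.components = []
    elif ctx.query_inchi.n_components < 2:
        key = ctx.query_key or keys.key_for_parsed(ctx.query_inchi, reg.provider)
        ctx.components = [(ctx.query_inchi, key)]
    else:
        ctx.components = [
            (c.inchi, keys.key_for_parsed(c.inchi, reg.provider))
            for c in inchi_core.split(ctx.query_inchi)
        ]
    return ctx.components


def _pattern_matches(reg: Registry, key_or_fikhb: str, b: int) -> list[StructureRow]:
    pattern = keys.pattern_of(key_or_fikhb, b)
    if b == 0:
        return reg.structures_by_fikhb(pattern)
    return reg.structures_by_key_prefix(pattern)


def execute(
    reg: Registry,
    ctx: QueryContext,
    crit: SearchCriteria,
    label_table: dict[str, str] | None = None,
    stats: SearchStats | None = None,
) -> list[HitRecord]:
    """Run a connectivity search and return one record per matching
    (assignment, relation), ordered by (relation, src_id, src_compound_id).

    Matching follows the criterion-C relations described in the module
    docstring; assignments are filtered by source (A) and currency (G);
    hits whose structure lacks an InChI are skipped; each unique retrieved
    InChI is parsed and diffed against the query exactly once; labels are
    attached (F=0) for any labelled FIKHB among a hit's components.  A
    context whose query could not be resolved returns an empty list.
    """
    if not ctx.runnable:
        return []
    relations = [0, 1, 2, 3] if crit.C == 4 else [crit.C]
    threshold = freq_threshold(crit.D)
    if stats is None:
        stats = SearchStats()

    # (uci, relation) -> StructureRow; dict preserves discovery, order fixed later
    matches: dict[tuple[int, int], StructureRow] = {}

    def add(structure: StructureRow, relation: int) -> None:
        matches.setdefault((structure.uci, relation), structure)

    for relation in relations:
        if relation == 0:
            for s in _pattern_matches(reg, ctx.query_key or ctx.query_fikhb, crit.B):
                add(s, 0)
        elif relation == 1:
            if _blocked(reg, ctx.query_fikhb, ctx.query_inchi, threshold, crit.E, stats):
                continue
            for parent in reg.parents_of(ctx.query_fikhb):
                for s in reg.structures_by_fikhb(parent):
                    add(s, 1)
        elif relation == 2:
            for comp, comp_key in _query_components(reg, ctx):
                for s in _pattern_matches(reg, comp_key, crit.B):
                    add(s, 2)
        elif relation == 3:
            for comp, comp_key in _query_components(reg, ctx):
                comp_fikhb = keys.fikhb_of(comp_key)
                if _blocked(reg, comp_fikhb, comp, threshold, crit.E, stats):
                    continue
                for parent in reg.parents_of(comp_fikhb):
                    for s in reg.structures_by_fikhb(parent):
                        add(s, 3)

    # a single-component query is its own only component: relations 2/3
    # duplicate 0/1 and collapse to the lower relation code
    if ctx.query_inchi is not None and ctx.query_inchi.n_components < 2:
        for (uci, relation) in list(matches):
            if relation in (2, 3) and (uci, relation - 2) in matches:
                del matches[(uci, relation)]

    # parse-once cache over unique retrieved InChIs (the query InChI, when
    # it is among the hits, is reused rather than re-parsed)
    cache: dict[str, tuple[ParsedInChI, LayerDiff | None]] = {}
    if ctx.query_inchi is not None:
        cache[inchi_core.serialize(ctx.query_inchi)] = (
            ctx.query_inchi,
            inchi_core.layer_diff(ctx.query_inchi, ctx.query_inchi),
        )

    records: list[HitRecord] = []
    for (uci, relation), structure in matches.items():
        if structure.standardinchi is None:
            continue  # no retrieved InChI, no comparison: record skipped
        kept = [
            a
            for a in reg.assignments_for_uci(uci)
            if not (crit.A and a.src_id != crit.A)
            and not (crit.G == 0 and not a.current)
        ]
        if not kept:
            continue  # filtered out entirely: never retrieved, never parsed
        diff = None
        if ctx.query_inchi is not None:
            if structure.standardinchi not in cache:
                parsed = inchi_core.parse(structure.standardinchi)
                stats.retrieved_parses += 1
                cache[structure.standardinchi] = (
                    parsed,
                    inchi_core.layer_diff(ctx.query_inchi, parsed),
                )
            diff = cache[structure.standardinchi][1]
        labels: list[str] = []
        if crit.F == 0 and label_table:
            components = reg.children_of(structure.fikhb) or [structure.fikhb]
            labels = annotate_labels(components, label_table)
        for a in kept:
            records.append(
                HitRecord(
                    src_compound_id=a.src_compound_id,
                    src_id=a.src_id,
                    source_name=a.source_name,
                    standardinchi=structure.standardinchi,
                    standardinchikey=structure.standardinchikey,
                    relation=relation,
                    labels=labels,
                    diff=diff,
                    current=a.current,
                )
            )
    stats.unique_hit_inchis = len(
        {r.standardinchi for r in records}
    )
    records.sort(key=HitRecord.sort_key)
    return records


def _blocked(
    reg: Registry,
    fikhb: str,
    parsed: ParsedInChI | None,
    threshold: int,
    e: int,
    stats: SearchStats,
) -> bool:
    """Sub-query blocking for the parents-of lookups (criteria D and E)."""
    if reg.component_frequency(fikhb) > threshold:
        stats.blocked_components.append(fikhb)
        return True
    if e > 0 and parsed is not None and inchi_core.connectivity_length(parsed) <= e:
        stats.blocked_components.append(fikhb)
        return True
    return False
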