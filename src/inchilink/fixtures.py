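"""Deterministic synthetic fixtures and the brute-force search oracle.

The generator emits families of related structures of the kinds a compound
cross-reference registry has to reconcile: a parent skeleton, its salt and
mixture forms with common counter-ions, stereoisomers, isotopically
labelled forms and different protonation states.  The InChI strings are
built from templated formula/c/h/q/b/t/m/s/i layers: they are syntactically
valid Standard InChIs (they parse, round-trip and split correctly) but
chemically meaningful only to the surrogate key provider — real-chemistry
behaviour is exercised separately by a handful of genuine InChIs under the
toolkit provider.

:func:`oracle_search` is the verification twin of ``search.execute``: it
splits every structure by brute force at query time, uses no hierarchy
table and no caching, and returns a comparable hit set.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

from . import inchi_core, keys
from .inchi_core import ParsedInChI
from .search import QueryContext, SearchCriteria, freq_threshold
from .store import AssignmentRow

# counter-ion catalogue: name -> (formula segment, extra layers)
COUNTER_IONS: dict[str, tuple[str, dict[str, str]]] = {
    "Na": ("Na", {"q": "+1"}),
    "K": ("K", {"q": "+1"}),
    "ClH": ("ClH", {"h": "1H"}),
    "BrH": ("BrH", {"h": "1H"}),
    "Li": ("Li", {"q": "+1"}),
}


@dataclass
class FamilySpec:
    """Parameters of one synthetic structure-family fixture.

    The same seed always produces byte-identical output files.
    """

    n_skeletons: int = 4
    counter_ions: list[str] = field(default_factory=lambda: ["Na", "ClH"])
    stereo_variants: int = 1
    isotope_variants: int = 1
    proton_variants: int = 1
    seed: int = 0
    n_sources: int = 2
    mixture_multiplicity: int = 2

    def __post_init__(self) -> None:
        if self.n_skeletons < 1:
            raise ValueError("need at least one skeleton")
        unknown = set(self.counter_ions) - set(COUNTER_IONS)
        if unknown:
            raise ValueError(f"unknown counter-ions {sorted(unknown)}")
        if not 1 <= self.mixture_multiplicity <= 99:
            raise ValueError(
                "mixture multiplicity must be 1-99 (two-digit repeat counts are "
                "the most the layer grammar supports)"
            )


def _skeleton(rng: random.Random, index: int) -> ParsedInChI:
    """A synthetic single-component skeleton with c and h layers.

    The index goes into the nitrogen count so every skeleton in a family
    has a distinct formula, hence a distinct FIKHB."""
    n_carbon = rng.randint(4, 12)
    n_h = rng.randint(5, 2 * n_carbon)
    formula = f"C{n_carbon}H{n_h}N{index + 1}O"
    n_atoms = n_carbon + 2
    # a random spanning chain with occasional branches, in c-layer style
    parts = []
    for i in range(2, n_atoms + 1):
        if rng.random() < 0.25 and i > 2:
            parts.append(f"({i})")
        else:
            parts.append(f"-{i}" if parts else str(i))
    c_layer = f"{n_atoms}-" + "".join(parts)
    h_layer = f"1-{max(2, n_atoms // 2)}H,{n_h - 2}H2"
    return ParsedInChI("1S", [(1, formula)], {"c": c_layer, "h": h_layer})


def skeleton(index: int, seed: int = 0) -> ParsedInChI:
    """A deterministic, index-distinct single-component skeleton."""
    return _skeleton(random.Random(seed * 100003 + index), index)


def counter_ion(name: str) -> ParsedInChI:
    """A catalogue counter-ion as a single-component InChI."""
    return _ion_inchi(name)


def _ion_inchi(name: str) -> ParsedInChI:
    seg, layers = COUNTER_IONS[name]
    return ParsedInChI("1S", [(1, seg)], dict(layers))


def make_salt(
    skeleton: ParsedInChI, ion: ParsedInChI, multiplicity: int = 1
) -> ParsedInChI:
    """Combine a skeleton and a counter-ion into a multi-component InChI,
    optionally repeating the skeleton ``multiplicity`` times (exercising the
    leading-count formula grammar and the ``N*`` sublayer grammar)."""
    formula = [(multiplicity, skeleton.formula[0][1]), (1, ion.formula[0][1])]
    layers: dict[str, str] = {}
    for code in inchi_core.COMPONENT_LAYERS:
        skel = skeleton.layers.get(code, "")
        ion_text = ion.layers.get(code, "")
        if not skel and not ion_text:
            continue
        if multiplicity > 1 and skel:
            skel_part = f"{multiplicity}*{skel}"
        else:
            skel_part = skel
        layers[code] = f"{skel_part};{ion_text}"
    return ParsedInChI("1S", [(c, s) for c, s in formula if True], layers)


def _with_layers(base: ParsedInChI, extra: dict[str, str]) -> ParsedInChI:
    merged = dict(base.layers)
    merged.update(extra)
    ordered = {c: merged[c] for c in inchi_core.LAYER_ORDER if c in merged}
    return ParsedInChI(base.version_tag, list(base.formula), ordered)


def generate(spec: FamilySpec, out_dir: str | Path) -> dict:
    """Write source TSVs, a label table and a ground-truth manifest.

    The manifest lists the sources, every expected hierarchy edge
    (parent FIKHB -> child FIKHB, computed by construction with the
    surrogate provider), and a designated probe query with its expected
    (assignment, relation, diff-flag) hit set computed by the brute-force
    oracle.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = random.Random(spec.seed)
    provider = keys.SurrogateKeyProvider()

    compounds: list[tuple[str, ParsedInChI]] = []
    serial = 0

    def new_id() -> str:
        nonlocal serial
        serial += 1
        return f"SYN{serial:05d}"

    skeletons = [_skeleton(rng, i) for i in range(spec.n_skeletons)]
    for sk_index, skeleton in enumerate(skeletons):
        compounds.append((new_id(), skeleton))
        for ion_name in spec.counter_ions:
            compounds.append((new_id(), make_salt(skeleton, _ion_inchi(ion_name))))
        for v in range(spec.stereo_variants):
            compounds.append(
                (
                    new_id(),
                    _with_layers(
                        skeleton,
                        {"t": f"{2 + v}-", "m": str(v % 2), "s": "1"},
                    ),
                )
            )
        for v in range(spec.isotope_variants):
            compounds.append((new_id(), _with_layers(skeleton, {"i": f"1+{v + 1}"})))
        for v in range(spec.proton_variants):
            compounds.append((new_id(), _with_layers(skeleton, {"p": f"+{v + 1}"})))
        if sk_index == 0 and spec.mixture_multiplicity > 1:
            compounds.append(
                (
                    new_id(),
                    make_salt(
                        skeleton,
                        _ion_inchi(spec.counter_ions[0]),
                        multiplicity=spec.mixture_multiplicity,
                    ),
                )
            )

    # round-robin assignment of compounds to sources
    sources = [
        {
            "src_id": i + 1,
            "name": f"synsrc{i + 1}",
            "keys_only": 0,
            "file": f"src{i + 1}.tsv",
        }
        for i in range(spec.n_sources)
    ]
    rows_per_source: dict[int, list[str]] = {s["src_id"]: [] for s in sources}
    dump: list[AssignmentRow] = []
    structures: dict[str, tuple[str, str]] = {}  # inchi -> (key, fikhb)
    for i, (cid, parsed) in enumerate(compounds):
        inchi = inchi_core.serialize(parsed)
        if inchi not in structures:
            key = keys.key_for_parsed(parsed, provider)
            structures[inchi] = (key, keys.fikhb_of(key))
        key, fikhb = structures[inchi]
        src = sources[i % spec.n_sources]
        rows_per_source[src["src_id"]].append(f"{cid}\t{inchi}\t{key}")
        dump.append(
            AssignmentRow(
                src_compound_id=cid,
                src_id=src["src_id"],
                source_name=src["name"],
                uci=0,
                current=1,
                standardinchi=inchi,
                standardinchikey=key,
                fikhb=fikhb,
            )
        )

    for src in sources:
        path = out / src["file"]
        lines = ["src_compound_id\tstandardinchi\tstandardinchikey"]
        lines += rows_per_source[src["src_id"]]
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")

    # label table: tag the counter-ions by name
    label_lines = ["fikhb\tlabel"]
    for ion_name in spec.counter_ions:
        ion_key = keys.key_for_parsed(_ion_inchi(ion_name), provider)
        label_lines.append(f"{keys.fikhb_of(ion_key)}\t{ion_name}")
    (out / "labels.tsv").write_text("\n".join(label_lines) + "\n", encoding="utf-8")

    expected_edges = [
        list(e) for e in sorted(expected_hierarchy_edges(list(structures), provider))
    ]

    # probe: the first salt of the first skeleton, queried at C=4
    probe_inchi = inchi_core.serialize(
        make_salt(skeletons[0], _ion_inchi(spec.counter_ions[0]))
    )
    probe_key = structures[probe_inchi][0]
    probe_crit = SearchCriteria(C=4)
    ctx = QueryContext(
        query_fikhb=structures[probe_inchi][1],
        query_key=probe_key,
        query_inchi=inchi_core.parse(probe_inchi),
    )
    probe_expected = sorted(oracle_search(dump, ctx, probe_crit, provider))

    freqs = component_frequencies(list(structures), provider)
    blocked = [
        fikhb
        for fikhb, freq in freqs.items()
        if freq > freq_threshold(probe_crit.D)
    ]

    manifest = {
        "seed": spec.seed,
        "sources": sources,
        "label_table": "labels.tsv",
        "n_structures": len(structures),
        "expected_edges": expected_edges,
        "blocked_components_default_D": sorted(blocked),
        "probe": {
            "key": probe_key,
            "criteria": {"C": 4},
            "expected": [list(t) for t in probe_expected],
        },
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest


def expected_hierarchy_edges(
    inchis: list[str], provider: keys.KeyProvider
) -> set[tuple[str, str]]:
    """Ground-truth hierarchy: split every multi-component InChI."""
    edges: set[tuple[str, str]] = set()
    for inchi in inchis:
        parsed = inchi_core.parse(inchi)
        if parsed.n_components < 2:
            continue
        parent = keys.fikhb_of(keys.key_for_parsed(parsed, provider))
        for comp in inchi_core.split(parsed):
            child = keys.fikhb_of(keys.key_for_parsed(comp.inchi, provider))
            edges.add((parent, child))
    return edges


# ---------------------------------------------------------------------------
# brute-force oracle


def _brute_components(inchi: str, provider: keys.KeyProvider) -> list[tuple[ParsedInChI, str]]:
    parsed = inchi_core.parse(inchi)
    if parsed.n_components < 2:
        return [(parsed, keys.key_for_parsed(parsed, provider))]
    return [
        (c.inchi, keys.key_for_parsed(c.inchi, provider))
        for c in inchi_core.split(parsed)
    ]


def component_frequencies(
    inchis: list[str], provider: keys.KeyProvider
) -> dict[str, int]:
    """Distinct multi-component parent FIKHBs per child FIKHB, by splitting
    every InChI (single pass; the brute-force twin of the hierarchy count)."""
    parents_by_child: dict[str, set[str]] = {}
    for inchi in inchis:
        parsed = inchi_core.parse(inchi)
        if parsed.n_components < 2:
            continue
        parent = keys.fikhb_of(keys.key_for_parsed(parsed, provider))
        for c in inchi_core.split(parsed):
            child = keys.fikhb_of(keys.key_for_parsed(c.inchi, provider))
            parents_by_child.setdefault(child, set()).add(parent)
    return {child: len(p) for child, p in parents_by_child.items()}


def _brute_frequency(
    child_fikhb: str, inchis: list[str], provider: keys.KeyProvider
) -> int:
    """Distinct multi-component parent FIKHBs containing ``child_fikhb``."""
    return component_frequencies(inchis, provider).get(child_fikhb, 0)


def hit_tuple(
    src_compound_id: str,
    src_id: int,
    key: str,
    relation: int,
    current: int,
    diff_flags: str,
) -> tuple:
    return (src_compound_id, src_id, key, relation, current, diff_flags)


def oracle_search(
    dump: list[AssignmentRow],
    ctx: QueryContext,
    crit: SearchCriteria,
    provider: keys.KeyProvider,
) -> set[tuple]:
    """Brute-force twin of ``search.execute``.

    Works from a flat assignment dump, splits every structure at query
    time, compares patterns directly and returns the expected
    (assignment, relation) set as tuples of (src_compound_id, src_id,
    standardinchikey, relation, current, diff-flag string).
    """
    if not ctx.runnable:
        return set()
    relations = [0, 1, 2, 3] if crit.C == 4 else [crit.C]
    threshold = freq_threshold(crit.D)
    all_inchis = sorted(
        {a.standardinchi for a in dump if a.standardinchi is not None}
    )

    q_pattern = keys.pattern_of(ctx.query_key or ctx.query_fikhb, crit.B) if (
        0 in relations or 2 in relations
    ) else None
    q_components: list[tuple[ParsedInChI, str]] = []
    if ctx.query_inchi is not None:
        q_components = _brute_components(
            inchi_core.serialize(ctx.query_inchi), provider
        )

    freqs = component_frequencies(all_inchis, provider)

    def blocked(fikhb: str, parsed: ParsedInChI | None) -> bool:
        if freqs.get(fikhb, 0) > threshold:
            return True
        return (
            crit.E > 0
            and parsed is not None
            and inchi_core.connectivity_length(parsed) <= crit.E
        )

    query_blocked = blocked(ctx.query_fikhb, ctx.query_inchi)
    comp_allowed = [
        (comp, key)
        for comp, key in q_components
        if not blocked(keys.fikhb_of(key), comp)
    ]

    hits: set[tuple] = set()
    for a in dump:
        if a.standardinchi is None:
            continue
        if crit.A and a.src_id != crit.A:
            continue
        if crit.G == 0 and not a.current:
            continue
        parsed = inchi_core.parse(a.standardinchi)
        struct_child_fikhbs = (
            {
                keys.fikhb_of(k)
                for _, k in _brute_components(a.standardinchi, provider)
            }
            if parsed.n_components >= 2
            else set()
        )
        matched: set[int] = set()
        for relation in relations:
            if relation == 0:
                if keys.pattern_of(a.standardinchikey, crit.B) == q_pattern:
                    matched.add(0)
            elif relation == 1:
                if not query_blocked and ctx.query_fikhb in struct_child_fikhbs:
                    matched.add(1)
            elif relation == 2:
                for _, comp_key in q_components:
                    if keys.pattern_of(a.standardinchikey, crit.B) == keys.pattern_of(
                        comp_key, crit.B
                    ):
                        matched.add(2)
                        break
            elif relation == 3:
                for _, comp_key in comp_allowed:
                    if keys.fikhb_of(comp_key) in struct_child_fikhbs:
                        matched.add(3)
                        break
        if ctx.query_inchi is not None and ctx.query_inchi.n_components < 2:
            matched -= {r for r in (2, 3) if r - 2 in matched}
        if ctx.query_inchi is not None:
            diff = inchi_core.layer_diff(ctx.query_inchi, parsed)
            diff_flags = "".join(str(diff.flags[c]) for c in inchi_core.DIFF_LAYERS)
        else:
            diff_flags = ""
        for relation in matched:
            hits.add(
                hit_tuple(
                    a.src_compound_id,
                    a.src_id,
                    a.standardinchikey,
                    relation,
                    a.current,
                    diff_flags,
                )
            )
    return hits


def hit_set(records) -> set[tuple]:
    """Convert ``search.execute`` output to the oracle's tuple form."""
    out = set()
    for r in records:
        if r.diff is None:
            flags = ""
        else:
            flags = "".join(str(r.diff.flags[c]) for c in inchi_core.DIFF_LAYERS)
        out.add(
            hit_tuple(
                r.src_compound_id,
                r.src_id,
                r.standardinchikey,
                r.relation,
                r.current,
                flags,
            )
        )
    return out
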