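"""Layer-level parsing, serialization, splitting and comparison of Standard InChIs.

A Standard InChI is a '/'-delimited string: a version tag (``1S``), a
molecular formula, and a sequence of one-letter-coded layers in the fixed
order c (connections), h (hydrogens), q (charge), p (protons), b/t/m/s
(stereo) and i (isotopic).  In a multi-component InChI (a salt or mixture)
the formula joins component formulae with '.', and the c/h/q/b/t layers
carry one ';'-separated sublayer per component, with ``N*`` abbreviating N
identical repeats and a leading count abbreviating repeated formula
segments.

This module treats the InChI purely as that grammar: it never interprets
the chemistry, and it guarantees a byte-identical ``serialize(parse(x))``
round trip for every valid input.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

#: canonical layer order after the formula segment
LAYER_ORDER = "chqpbtmsi"

#: layers that carry per-component sublayers in a multi-component InChI
COMPONENT_LAYERS = "chqbt"

#: layer codes compared by :func:`layer_diff` (the result-table diff columns)
DIFF_LAYERS = "pbtmsi"


class InChIParseError(ValueError):
    """Raised when a string is not a syntactically valid Standard InChI."""


class StructureError(ValueError):
    """Raised when a parsed InChI's sublayer structure is inconsistent."""


# module-level instrumentation: every call to parse() increments this.
# The search engine's parse-once contract is asserted against it.
class ParseCounter:
    __slots__ = ("value",)

    def __init__(self) -> None:
        self.value = 0


parse_counter = ParseCounter()


@dataclass
class ParsedInChI:
    """A Standard InChI decomposed into formula segments and named layers.

    ``formula`` holds (count, segment) pairs with the leading repeat count
    expanded ("2ClH" -> (2, "ClH")).  ``layers`` maps layer code to raw
    layer text (without the "/x" prefix); the i entry holds everything from
    the i layer to the end of the string as one opaque unit.
    """

    version_tag: str
    formula: list[tuple[int, str]]
    layers: dict[str, str] = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return sum(count for count, _ in self.formula)

    def formula_text(self) -> str:
        return ".".join(
            f"{count}{seg}" if count > 1 else seg for count, seg in self.formula
        )

    def basic_layer(self) -> str:
        """Formula + c + h + q — the part of the InChI hashed into the FIKHB."""
        parts = [self.formula_text()]
        for code in "chq":
            if code in self.layers:
                parts.append(f"/{code}{self.layers[code]}")
        return "".join(parts)


@dataclass
class ComponentTable:
    """Per-component sublayers of a (possibly multi-component) InChI.

    All ``N*`` repeats and formula counts are expanded, so every list has
    exactly ``n_components`` entries; absent sublayers are empty strings.
    """

    n_components: int
    per_layer: dict[str, list[str]]
    m_chars: list[str]
    s_value: str
    i_text: str


@dataclass
class LayerDiff:
    """Per-layer difference flags between a query and a hit InChI.

    A flag is 1 iff the raw text of that layer differs; a layer absent from
    both counts as identical.  Exactly the p, b, t, m, s, i columns of the
    connectivity-search result table.
    """

    flags: dict[str, int]

    def __iter__(self):
        return iter(self.flags.items())

    def any(self) -> bool:
        return any(self.flags.values())


@dataclass
class SplitComponent:
    """One unique single-component child of a multi-component InChI."""

    inchi: ParsedInChI
    multiplicity: int


_FORMULA_SEG_RE = re.compile(r"^(\d*)(.+)$")
_MULT_RE = re.compile(r"^(\d+)\*(.*)$")


def parse(inchi_string: str) -> ParsedInChI:
    """Parse a Standard InChI string into its formula and named layers.

    Raises :class:`InChIParseError` on a malformed prefix, a non-standard
    version tag, an unknown or duplicated layer code, or layers out of
    canonical order.
    """
    parse_counter.value += 1
    if not inchi_string.startswith("InChI="):
        raise InChIParseError(f"missing 'InChI=' prefix: {inchi_string[:20]!r}")
    body = inchi_string[len("InChI=") :]
    segments = body.split("/")
    version_tag = segments[0]
    if version_tag != "1S":
        raise InChIParseError(
            f"non-standard version tag {version_tag!r} (only Standard InChI '1S' accepted)"
        )
    if len(segments) < 2 or not segments[1]:
        raise InChIParseError("missing molecular formula segment")

    formula = _parse_formula(segments[1])

    layers: dict[str, str] = {}
    idx = 2
    last_rank = -1
    while idx < len(segments):
        seg = segments[idx]
        if not seg:
            raise InChIParseError("empty layer segment ('//')")
        code = seg[0]
        rank = LAYER_ORDER.find(code)
        if rank < 0:
            raise InChIParseError(f"unknown layer code in segment {seg!r}")
        if code in layers:
            raise InChIParseError(f"duplicated layer /{code} in segment {seg!r}")
        if rank <= last_rank:
            raise InChIParseError(f"layer /{code} out of canonical order at {seg!r}")
        if code == "i":
            # the isotopic layer is kept opaque: everything to end of string
            layers["i"] = "/".join([seg[1:]] + segments[idx + 1 :])
            break
        layers[code] = seg[1:]
        last_rank = rank
        idx += 1
    return ParsedInChI(version_tag=version_tag, formula=formula, layers=layers)


def _parse_formula(text: str) -> list[tuple[int, str]]:
    formula: list[tuple[int, str]] = []
    for seg in text.split("."):
        m = _FORMULA_SEG_RE.match(seg)
        if not m:
            raise InChIParseError(f"malformed formula segment {seg!r}")
        count = int(m.group(1)) if m.group(1) else 1
        if count < 1:
            raise InChIParseError(f"formula segment count must be positive: {seg!r}")
        formula.append((count, m.group(2)))
    return formula


def serialize(p: ParsedInChI) -> str:
    """Render a :class:`ParsedInChI` back to text; exact inverse of :func:`parse`."""
    parts = [f"InChI={p.version_tag}", p.formula_text()]
    for code in LAYER_ORDER:
        if code in p.layers:
            parts.append(f"{code}{p.layers[code]}")
    return "/".join(parts)


def _expand_sublayers(text: str, n: int, code: str) -> list[str]:
    out: list[str] = []
    for token in text.split(";"):
        m = _MULT_RE.match(token)
        if m:
            out.extend([m.group(2)] * int(m.group(1)))
        else:
            out.append(token)
    if len(out) > n:
        raise StructureError(
            f"layer /{code} expands to {len(out)} sublayers but formula has {n} components"
        )
    out.extend([""] * (n - len(out)))
    return out


def expand_components(p: ParsedInChI) -> ComponentTable:
    """Expand a parsed InChI into one column of sublayers per component.

    Sublayers are split on ';' with ``N*`` repeats expanded and trailing
    omitted entries filled with empty text.  The /m layer is split one
    character per component (padded with '.'), /s is kept global and /i
    opaque.
    """
    n = p.n_components
    per_layer: dict[str, list[str]] = {}
    for code in COMPONENT_LAYERS:
        text = p.layers.get(code)
        if text is None:
            per_layer[code] = [""] * n
        else:
            per_layer[code] = _expand_sublayers(text, n, code)
    m_text = p.layers.get("m", "")
    if len(m_text) > n:
        raise StructureError(
            f"/m layer has {len(m_text)} characters but formula has {n} components"
        )
    m_chars = list(m_text) + ["."] * (n - len(m_text))
    return ComponentTable(
        n_components=n,
        per_layer=per_layer,
        m_chars=m_chars,
        s_value=p.layers.get("s", ""),
        i_text=p.layers.get("i", ""),
    )


def split(p: ParsedInChI) -> list[SplitComponent]:
    """Split a multi-component InChI into its unique single-component InChIs.

    Each child is assembled from one expanded formula segment and its
    c/h/q/b/t sublayers.  A component with a /m character in {0,1} receives
    that character as its /m layer plus an /s layer (the parent's /s value
    for /s2 and /s3 parents, otherwise /s1).  The /p layer is never copied
    to children: it only feeds the InChIKey proton flag, which takes part in
    neither the FIKHB nor the minus-proton-flag pattern.  An isotopic parent
    yields children from its non-isotopic layers only (with a warning), the
    /i layer being opaque here.

    Duplicate components are returned once, with their multiplicity.
    """
    if p.n_components < 2:
        raise StructureError("split() requires a multi-component InChI")
    table = expand_components(p)
    if table.i_text:
        logger.warning(
            "splitting isotopic multi-component InChI %s: children derived "
            "from non-isotopic layers only",
            serialize(p),
        )
    segments: list[str] = []
    for count, seg in p.formula:
        segments.extend([seg] * count)

    children: list[SplitComponent] = []
    seen: dict[str, int] = {}
    for k, seg in enumerate(segments):
        layers: dict[str, str] = {}
        for code in COMPONENT_LAYERS:
            text = table.per_layer[code][k]
            if text:
                layers[code] = text
        if table.m_chars[k] in "01":
            layers["m"] = table.m_chars[k]
            layers["s"] = table.s_value if table.s_value in ("2", "3") else "1"
        # canonical ordering of the assembled layer map
        layers = {c: layers[c] for c in LAYER_ORDER if c in layers}
        child = ParsedInChI(version_tag="1S", formula=[(1, seg)], layers=layers)
        key = serialize(child)
        if key in seen:
            children[seen[key]].multiplicity += 1
        else:
            seen[key] = len(children)
            children.append(SplitComponent(inchi=child, multiplicity=1))
    return children


def connectivity_length(p: ParsedInChI) -> int:
    """Length of the InChI from the first formula character to the end of
    the connection (c) layer — the quantity the length-block criterion
    thresholds on.  Without a c layer this is just the formula length."""
    n = len(p.formula_text())
    if "c" in p.layers:
        n += 2 + len(p.layers["c"])  # the "/c" separator counts
    return n


def layer_diff(query: ParsedInChI, hit: ParsedInChI) -> LayerDiff:
    """Flag, per p/b/t/m/s/i layer, whether query and hit differ.

    Absent and absent compare equal; absent and present differ.
    """
    flags = {
        code: int(query.layers.get(code, "") != hit.layers.get(code, ""))
        for code in DIFF_LAYERS
    }
    return LayerDiff(flags=flags)
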