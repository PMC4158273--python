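# Methods

This note records the model implemented by `inchilink`, the parameters and
defaults it uses, what the synthetic fixture generator does and does not
emulate, the numerical/representational choices made, and the known
limitations. It makes no empirical claims beyond what the test suite and
`scripts/acceptance.py` compute.

## InChI grammar model

`inchi_core` treats a Standard InChI as text with a fixed layered grammar; it
performs no chemistry (no valence, no canonicalization). A string is the
prefix `InChI=`, the version tag (which must be `1S`; non-standard InChIs are
rejected), a formula, and zero or more layers introduced by `/<code>`. The
recognised layer codes, in the only order accepted, are
`c h q p b t m s i`; an unknown code, a duplicated layer or an out-of-order
layer is a parse error naming the offending segment. The formula is split on
`.` into segments, each with an optional leading repeat count
(`2C2H4O2.Cu` = two acetate units and one copper).

Everything from `/i` to the end of the string is kept as one opaque layer:
the isotopic block may itself contain `/t /m /s` sublayers with
isotopic-only meaning, and the package never needs to interpret them —
only to detect that the block differs between two InChIs.

Serialization is the exact inverse of parsing; the suite checks
`serialize(parse(x)) == x` byte-for-byte on printed and generated corpora
and on randomly assembled layer structures.

### Components, splitting

Multi-component layers use `;`-separated sublayers aligned with the
*expanded* formula (repeat counts unrolled), with the `N*text` abbreviation
for repeated sublayers and trailing empties omitted. Splitting a
multi-component InChI produces one single-component child per distinct
component, with a multiplicity:

- each child receives its own `c`, `h`, `q`, `b`, `t` sublayers;
- the `m` layer is one character per stereo-bearing component; a child with
  `m` in `{0,1}` also receives an `s` layer (the parent's `s` if it is an
  absolute/relative marker, else `1`);
- the `/p` (protonation) layer is **never** copied to children. This is what
  makes the sodium 4-aminobenzoate → 4-aminobenzoic acid split byte-exact,
  and equally what makes the sodium 5-methyltetrazolide child a `/q-1` anion
  distinct from the neutral parent: protonation recorded via `/p` is
  reversible on split, protonation recorded via `/q` is not.
- isotopic parents are split with a warning: the opaque `/i` block cannot be
  distributed reliably, so children omit it.

`connectivity_length` is the character length of the formula plus the `/c`
layer text — a size proxy used by blocking criterion `E`.

## Keys and providers

A Standard InChIKey is 27 characters: 14 (hash of the *basic layer* =
formula + `/c` + `/h` + `/q`), `-`, 8 (hash of the remaining layers), the
standard flag `SA`, `-`, and a protonation flag character (`N` for `/p`
absent, `M`/`O`/… for ±1, …). The **FIKHB** is the first 14-character
block; structures sharing a basic layer share a FIKHB.

Match patterns: `B=0` matches on the FIKHB (connectivity); `B=1` matches on
the first 25 characters, i.e. the full key minus the protonation flag
(exact structure up to protonation).

Two providers implement key generation:

- `toolkit`: RDKit's InChI-to-InChIKey function — real keys.
- `surrogate`: SHA-256 of the basic layer mapped to 14 uppercase letters,
  SHA-256 of the remaining layers mapped to 8 letters, then `SA` and a
  protonation flag computed from `/p`. This preserves every property the
  engine relies on (determinism, fixed shape, FIKHB ⇔ basic-layer
  equivalence, proton-flag behaviour) without a chemistry dependency, but
  its keys are **not** real InChIKeys: a registry stores its provider name
  and refuses to operate under a different one.

## Registry and hierarchy

SQLite schema: sources, structures (unique key, FIKHB indexed, InChI
nullable for keys-only sources), assignments with a currency flag, and a
parent→child FIKHB hierarchy table. On loading a multi-component InChI
whose parent FIKHB is novel, the structure is split and one edge per child
FIKHB is stored; the split children themselves are *not* registered as
structures. A structure whose FIKHB is already known contributes no new
edges (a stereoisomer of a known salt shares the basic layer, hence the
same children). Keys-only records merge with InChI-bearing records through
the shared unique key; the InChI is filled in—and the hierarchy maintained—
whenever it first arrives. Reloading a source reconciles assignments:
missing ones are marked obsolete, returning ones reinstated.

## Search semantics

Eight integer criteria, all defaulting to 0:

- `A` — restrict hits to one source id (0 = all sources).
- `B` — key match pattern: 0 = FIKHB, 1 = key minus proton flag.
- `C` — mapping mode 0–3 as in the README table; 4 = union of all four.
  For a single-component query, relations 2/3 duplicate 0/1 and collapse to
  the lower code.
- `D` — component frequency threshold `min(200·10^D, 100000)`: a
  parents-of sub-query (relations 1 and 3) is skipped when the FIKHB being
  looked up occurs as a component of more than that many parents.
- `E` — minimum connectivity length: a sub-query is skipped when the
  component's connectivity length is ≤ `E` (0 disables; not applied to
  bare-FIKHB queries, which carry no parsed InChI).
- `F` — 0 attaches labels from a label table to any labelled FIKHB among a
  hit's components; 1 disables. Labels are attached in sorted child-FIKHB
  order.
- `G` — 0 restricts to current assignments; 1 includes obsolete ones.
- `H` — output grouping by source (a serialization concern; grouped output
  requires JSON).

Queries resolve from a full key, a bare 14-character FIKHB, or a
(source, compound-id) pair. A query that resolves to no stored InChI still
runs FIKHB-level relations but produces no diff annotation and cannot use
`B=1`.

**Parse-once contract.** Each unique retrieved InChI is parsed and diffed
against the query exactly once per query, via a per-query cache pre-seeded
with the query's own InChI; structures whose assignments are all filtered
out by `A`/`G` are never parsed. The instrumented module-level parse
counter is asserted ≤ (unique hit InChIs + 1) for every query in the
acceptance grid.

The diff annotation reports six binary flags — `p b t m s i` — set when
the corresponding layer text differs between query and hit (absent and
empty are equivalent). Under `B=1`, direct matches can differ only in `p`.

## Synthetic fixture generator

`fixtures.generate` emits deterministic families: skeletons with an index
embedded in the formula (guaranteeing distinct basic layers, hence distinct
FIKHBs), their salts with counter-ions from a small catalogue
(Na, K, ClH, BrH, Li), optional stereo/isotope/protonation variants and
mixtures, distributed across sources as TSV files with a JSON manifest of
ground truth (expected hierarchy edges, blocked components at default `D`,
a probe query with its expected hit set). The same seed yields
byte-identical files.

The generator emulates *structural* variety only. It does not produce
chemically meaningful molecules, realistic key distributions, or the layer
pathologies of real InChI output (complex `/b` sublayers, mobile-H groups
beyond simple `(H,…)` patterns, isotopic stereo blocks). The oracle used
against it (`fixtures.oracle_search`) is a brute-force reimplementation of
the search semantics over a full registry dump, splitting everything at
query time with no caches or hierarchy — deliberately sharing no code paths
with `search.execute`.

## Problem sizes and measurements

- Oracle-equivalence grid: 20 seeded registries (≈15–40 structures each),
  three query kinds (multi-component key, single-component key, bare
  FIKHB), criteria grid `{A,B,G} ∈ {0,1}³ × C ∈ {0..4}` — 2000 searches,
  each compared set-exact against the oracle.
- Frequency boundary: registries of 200 and 201 salts of one counter-ion;
  the component sub-query executes at 200 and is blocked at 201 under
  defaults. `scripts/acceptance.py` re-measures this from scratch over a
  sweep dense in 190–210.

## Limitations

- Text-grammar model only: malformed-but-plausible InChIs that a real
  toolkit would reject can be accepted, and no normalization beyond the
  grammar is attempted.
- The `/i` block is opaque; isotopic parents split lossily (children drop
  the block, with a warning) and isotopic sublayer differences all collapse
  into the single `i` diff flag.
- Surrogate keys are structurally faithful but not interoperable with real
  InChIKeys; cross-provider registries are refused rather than translated.
- Label order follows sorted child FIKHBs, not the hit InChI's component
  order.
- The store targets correctness at test scale (SQLite, simple indexes); no
  claims are made about production-scale ingestion throughput.
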