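# inchilink

A compound cross-reference registry with **connectivity search**: queries
return not only the database records that share a query molecule's exact
Standard InChI, but also its salts, mixtures, stereoisomers, isotopologues and
alternative protonation states — anything that shares the same *atom
connectivity* — with a per-layer annotation of how each hit differs from the
query.

## The idea

A Standard InChI is a layered, canonical text representation of a molecule:
a formula, a connectivity layer (`/c`), a hydrogen layer (`/h`), then optional
charge (`/q`), protonation (`/p`), stereo (`/b`, `/t`, `/m`, `/s`) and isotope
(`/i`) layers. The Standard InChIKey hashes this text into a fixed-length
key whose **first block (14 characters)** is derived only from the formula,
connectivity, hydrogen and charge layers. Two molecules with the same first
key block therefore share a skeleton even if they differ in stereochemistry,
isotopic labelling or protonation.

`inchilink` keys every registered structure on this
**First-InChIKey-Hash-Block (FIKHB)** and, for every multi-component InChI
(salts, mixtures), splits the InChI into its single-component children and
stores parent→child FIKHB edges in a hierarchy table. A connectivity search
then walks this hierarchy in four directions (the mapping criterion `C`):

| C | relation | meaning |
|---|----------|---------|
| 0 | Matches | same FIKHB (or same key under the exact pattern `B=1`) |
| 1 | Matches a component of | registry structures that *contain* the query as a component |
| 2 | Has a component which matches | query components matched directly |
| 3 | component ↔ component | other structures sharing a component with the query |
| 4 | — | all four at once |

Eight user criteria `A`–`H` (all defaulting to 0) control source filtering,
exact-vs-connectivity key matching, the mapping mode, frequency and size
blocking of over-common components (e.g. sodium, chloride), label annotation,
obsolete-assignment scope and output grouping. By default a component shared
by more than 200 parents is considered uninformative and its sub-query is
skipped.

Every hit that carries an InChI is parsed **once** per query and diffed
against the query InChI layer-by-layer, producing six flags
(`p b t m s i`) that say *how* the hit differs: protonation, double-bond
stereo, tetrahedral stereo, stereo parity, stereo type, isotopes.

Two InChIKey providers are available: `toolkit` (RDKit's InChI
implementation) and `surrogate` (a deterministic SHA-256-based stand-in that
preserves the structural properties of real keys — same shape, same
basic-layer⇔FIKHB equivalence — without a chemistry toolkit). Keys from
different providers are incomparable, so a registry records its provider and
refuses to mix.

## Worked example

4-aminobenzoic acid and its sodium salt. The salt's InChI splits into the
acid (byte-identical) and a sodium cation, so the two records share a
hierarchy and find each other.

`sources.tsv`:

```
src_compound_id	standardinchi
CPD-AMINOBENZOIC	InChI=1S/C7H7NO2/c8-6-3-1-5(2-4-6)7(9)10/h1-4H,8H2,(H,9,10)
CPD-AMINOBENZOATE-NA	InChI=1S/C7H7NO2.Na/c8-6-3-1-5(2-4-6)7(9)10;/h1-4H,8H2,(H,9,10);/q;+1/p-1
```

`config.txt`:

```
registry = demo.sqlite
provider = toolkit
source.1 = demo_source|0|sources.tsv
```

Load, then search for the acid's key with all mapping modes (`--C 4`):

```
$ inchilink load --config config.txt --src 1
source 1: read 2 records (0 rejected)
  structures added:      2
  hierarchy edges added: 2
  assignments new:       2
  assignments unchanged: 0
  assignments obsoleted: 0
  structures still lacking an InChI: 0

$ inchilink search key "ALYNCZNDIQEVRV-UHFFFAOYSA-N" --config config.txt --C 4
src_compound_id	source	inchikey	relation	labels	p	b	t	m	s	i
CPD-AMINOBENZOIC	demo_source	ALYNCZNDIQEVRV-UHFFFAOYSA-N	0		0	0	0	0	0	0
CPD-AMINOBENZOATE-NA	demo_source	XETSAYZRDCRPJY-UHFFFAOYSA-M	1		1	0	0	0	0	0
```

The acid matches itself (relation 0, no layer differences); the salt is
found because the acid matches one of its components (relation 1), and the
diff flags show it differs from the query only in the protonation layer
(`p = 1`).

The same search is available from Python:

```python
from inchilink import keys, search, store

reg = store.Registry("demo.sqlite", keys.get_provider("toolkit"))
ctx = search.resolve_key_query(reg, "ALYNCZNDIQEVRV-UHFFFAOYSA-N")
for hit in search.execute(reg, ctx, search.SearchCriteria(C=4)):
    print(hit.src_compound_id, hit.relation, hit.diff.flags)
```

Not every salt behaves this way: for 5-methyltetrazole the sodium salt's
anionic component (`…/q-1`) is *not* the neutral parent's InChI, so the two
have different FIKHBs and exact-component matching cannot link them — the
hierarchy walk at `C=3` still can, when both are registered as salts of a
common ion. See `docs/methods.md` for the full model.

## Layout

- `src/inchilink/inchi_core.py` — InChI grammar: parse, serialize, component
  expansion, splitting, connectivity length, layer diff.
- `src/inchilink/keys.py` — key validation, FIKHB, match patterns, the two
  key providers.
- `src/inchilink/store.py` — SQLite-backed registry: sources, structures,
  assignments with currency tracking, FIKHB hierarchy, keys-only merging.
- `src/inchilink/search.py` — criteria A–H, the four mapping relations,
  sub-query blocking, parse-once diff annotation, labels.
- `src/inchilink/cli_io.py` — config files, the `inchilink` command, TSV and
  JSON output.
- `src/inchilink/fixtures.py` — deterministic synthetic family generator and
  the brute-force search oracle used by the tests.
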