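"""The compound registry: sources, structures, assignments and the FIKHB
parent-child hierarchy, backed by an embedded SQLite database.

The schema mirrors the classic compound cross-reference layout — a source
catalogue (UC_SOURCE), one row per unique structure keyed on Standard
InChIKey (UC_STRUCTURE, carrying a FIKHB column), and identifier
assignments from each source to a structure (UC_XREF) — extended with the
two-column UC_FIKHB_HIERARCHY table that records, for every multi-component
structure ever loaded, which single-component FIKHBs it contains.  The
FIKHB's fixed 14-character length makes it an efficient indexed lookup key,
which is why the hierarchy stores hashed blocks rather than connectivity
layers.

Hierarchy rows are written at load time only when a multi-component InChI
arrives with a FIKHB not yet present as a parent; later salts with the same
connectivity but different stereochemistry or isotopes reuse the existing
rows.  The single-component InChIs produced during splitting are *not*
stored as structures.
"""

from __future__ import annotations

import logging
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from . import inchi_core, keys

logger = logging.getLogger(__name__)

_SCHEMA = """
CREATE TABLE IF NOT EXISTS UC_META (
    key   TEXT PRIMARY KEY,
    value TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS UC_SOURCE (
    src_id    INTEGER PRIMARY KEY,
    name      TEXT NOT NULL,
    keys_only INTEGER NOT NULL DEFAULT 0
);
CREATE TABLE IF NOT EXISTS UC_STRUCTURE (
    uci              INTEGER PRIMARY KEY AUTOINCREMENT,
    standardinchi    TEXT,
    standardinchikey TEXT NOT NULL UNIQUE,
    fikhb            TEXT NOT NULL
);
CREATE INDEX IF NOT EXISTS idx_structure_fikhb ON UC_STRUCTURE(fikhb);
CREATE TABLE IF NOT EXISTS UC_XREF (
    src_compound_id TEXT NOT NULL,
    src_id          INTEGER NOT NULL REFERENCES UC_SOURCE(src_id),
    uci             INTEGER NOT NULL REFERENCES UC_STRUCTURE(uci),
    current         INTEGER NOT NULL DEFAULT 1
);
CREATE UNIQUE INDEX IF NOT EXISTS idx_xref_unique
    ON UC_XREF(src_compound_id, src_id, uci);
CREATE INDEX IF NOT EXISTS idx_xref_uci ON UC_XREF(uci);
CREATE TABLE IF NOT EXISTS UC_FIKHB_HIERARCHY (
    parent TEXT NOT NULL,
    child  TEXT NOT NULL,
    PRIMARY KEY (parent, child)
);
CREATE INDEX IF NOT EXISTS idx_hierarchy_child ON UC_FIKHB_HIERARCHY(child);
"""


class RegistryError(RuntimeError):
    """Raised on registry misuse (unknown source, provider mismatch, ...)."""


@dataclass
class LoadReport:
    """Counts from one load_source() run."""

    src_id: int
    records_read: int = 0
    records_rejected: int = 0
    structures_added: int = 0
    edges_added: int = 0
    assignments_new: int = 0
    assignments_unchanged: int = 0
    assignments_obsoleted: int = 0

    def lines(self) -> list[str]:
        return [
            f"source {self.src_id}: read {self.records_read} records "
            f"({self.records_rejected} rejected)",
            f"  structures added:      {self.structures_added}",
            f"  hierarchy edges added: {self.edges_added}",
            f"  assignments new:       {self.assignments_new}",
            f"  assignments unchanged: {self.assignments_unchanged}",
            f"  assignments obsoleted: {self.assignments_obsoleted}",
        ]


@dataclass
class StructureRow:
    uci: int
    standardinchi: str | None
    standardinchikey: str
    fikhb: str


@dataclass
class AssignmentRow:
    src_compound_id: str
    src_id: int
    source_name: str
    uci: int
    current: int
    standardinchi: str | None = None
    standardinchikey: str = ""
    fikhb: str = ""


class Registry:
    """An open registry database plus the key provider that built it.

    The provider's name is recorded in the database on creation; reopening
    with a different provider is refused, because FIKHBs from different
    providers are incomparable.
    """

    def __init__(self, path: str | Path, provider: keys.KeyProvider):
        self.path = Path(path)
        self.provider = provider
        self.con = sqlite3.connect(str(path))
        self.con.executescript(_SCHEMA)
        row = self.con.execute(
            "SELECT value FROM UC_META WHERE key='provider'"
        ).fetchone()
        if row is None:
            self.con.execute(
                "INSERT INTO UC_META(key, value) VALUES ('provider', ?)",
                (provider.name,),
            )
            self.con.commit()
        elif row[0] != provider.name:
            self.con.close()
            raise RegistryError(
                f"registry {path} was built with provider {row[0]!r}; refusing to "
                f"mix with provider {provider.name!r} (FIKHBs are incomparable)"
            )

    def close(self) -> None:
        self.con.close()

    def __enter__(self) -> "Registry":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- sources ---------------------------------------------------------

    def add_source(self, src_id: int, name: str, keys_only: bool = False) -> None:
        self.con.execute(
            "INSERT OR REPLACE INTO UC_SOURCE(src_id, name, keys_only) VALUES (?,?,?)",
            (src_id, name, int(keys_only)),
        )
        self.con.commit()

    def source(self, src_id: int) -> tuple[str, bool]:
        row = self.con.execute(
            "SELECT name, keys_only FROM UC_SOURCE WHERE src_id=?", (src_id,)
        ).fetchone()
        if row is None:
            raise RegistryError(f"source {src_id} is not registered")
        return row[0], bool(row[1])

    # -- loading ---------------------------------------------------------

    def load_source(
        self, src_id: int, records: Iterable[Sequence[str]]
    ) -> LoadReport:
        """Load one source's assignment records, maintaining structures,
        hierarchy edges and assignment currency.

        Records are (src_compound_id, standard_inchi[, standard_inchikey])
        tuples, or (src_compound_id, standard_inchikey) for a keys-only
        source.  A supplied key that contradicts the provider-computed key
        rejects the record.  Re-loading marks assignments that vanished from
        the stream obsolete and reinstates ones that reappear.
        """
        _, keys_only = self.source(src_id)
        report = LoadReport(src_id=src_id)
        new_assignments: dict[str, int] = {}

        for record in records:
            report.records_read += 1
            try:
                uci = self._ingest_record(record, keys_only, report)
            except (
                keys.KeyValidationError,
                keys.ProviderError,
                inchi_core.InChIParseError,
                inchi_core.StructureError,
                ValueError,
            ) as exc:
                logger.warning("source %d: rejected record %r: %s", src_id, record, exc)
                report.records_rejected += 1
                continue
            new_assignments[str(record[0])] = uci

        self._reconcile_assignments(src_id, new_assignments, report)
        self.con.commit()
        return report

    def _ingest_record(
        self, record: Sequence[str], keys_only: bool, report: LoadReport
    ) -> int:
        if keys_only:
            if len(record) != 2:
                raise ValueError(
                    "keys-only record must be (src_compound_id, standardinchikey)"
                )
            key = keys.validate_key(record[1].strip())
            return self._structure_for_key(key, None, report)

        if len(record) not in (2, 3):
            raise ValueError(
                "record must be (src_compound_id, inchi[, inchikey]); "
                "keys-only records are only accepted for keys-only sources"
            )
        inchi = record[1].strip()
        computed = keys.key_for(inchi, self.provider)
        if len(record) == 3 and record[2].strip():
            supplied = record[2].strip()
            if supplied != computed:
                raise ValueError(
                    f"supplied key {supplied} contradicts computed key {computed}"
                )
        return self._structure_for_key(computed, inchi, report)

    def _structure_for_key(
        self, key: str, inchi: str | None, report: LoadReport
    ) -> int:
        fikhb = keys.fikhb_of(key)
        row = self.con.execute(
            "SELECT uci, standardinchi FROM UC_STRUCTURE WHERE standardinchikey=?",
            (key,),
        ).fetchone()
        if row is None:
            cur = self.con.execute(
                "INSERT INTO UC_STRUCTURE(standardinchi, standardinchikey, fikhb) "
                "VALUES (?,?,?)",
                (inchi, key, fikhb),
            )
            report.structures_added += 1
            uci = cur.lastrowid
            if inchi is not None:
                report.edges_added += self._maintain_hierarchy(inchi, fikhb)
            return uci
        uci, existing_inchi = row
        if inchi is not None and existing_inchi is None:
            # a keys-only structure gains its InChI from an InChI-bearing source
            self.con.execute(
                "UPDATE UC_STRUCTURE SET standardinchi=? WHERE uci=?", (inchi, uci)
            )
            report.edges_added += self._maintain_hierarchy(inchi, fikhb)
        return uci

    def _maintain_hierarchy(self, inchi: str, fikhb: str) -> int:
        """Insert parent->child edges for a multi-component InChI whose FIKHB
        is not yet a hierarchy parent.  Returns the number of edges added."""
        parsed = inchi_core.parse(inchi)
        if parsed.n_components < 2:
            return 0
        known = self.con.execute(
            "SELECT 1 FROM UC_FIKHB_HIERARCHY WHERE parent=? LIMIT 1", (fikhb,)
        ).fetchone()
        if known:
            return 0
        added = 0
        for component in inchi_core.split(parsed):
            child_key = keys.key_for_parsed(component.inchi, self.provider)
            cur = self.con.execute(
                "INSERT OR IGNORE INTO UC_FIKHB_HIERARCHY(parent, child) VALUES (?,?)",
                (fikhb, keys.fikhb_of(child_key)),
            )
            added += cur.rowcount
        return added

    def _reconcile_assignments(
        self, src_id: int, new: dict[str, int], report: LoadReport
    ) -> None:
        old_current = dict(
            self.con.execute(
                "SELECT src_compound_id, uci FROM UC_XREF WHERE src_id=? AND current=1",
                (src_id,),
            ).fetchall()
        )
        for cid, uci in new.items():
            if old_current.get(cid) == uci:
                report.assignments_unchanged += 1
                continue
            if cid in old_current:
                self.con.execute(
                    "UPDATE UC_XREF SET current=0 "
                    "WHERE src_compound_id=? AND src_id=? AND uci=?",
                    (cid, src_id, old_current[cid]),
                )
                report.assignments_obsoleted += 1
            cur = self.con.execute(
                "UPDATE UC_XREF SET current=1 "
                "WHERE src_compound_id=? AND src_id=? AND uci=?",
                (cid, src_id, uci),
            )
            if cur.rowcount == 0:
                self.con.execute(
                    "INSERT INTO UC_XREF(src_compound_id, src_id, uci, current) "
                    "VALUES (?,?,?,1)",
                    (cid, src_id, uci),
                )
            report.assignments_new += 1
        for cid, uci in old_current.items():
            if cid not in new:
                self.con.execute(
                    "UPDATE UC_XREF SET current=0 "
                    "WHERE src_compound_id=? AND src_id=? AND uci=?",
                    (cid, src_id, uci),
                )
                report.assignments_obsoleted += 1

    def backfill_keys_only(self) -> int:
        """Reconcile keys-only structures with InChI-bearing ones.

        Structure identity is keyed on the full InChIKey, so a keys-only
        record whose key matches an InChI-bearing structure already shares
        that structure's row (the merge happens at insert/update time in
        load_source).  This pass returns the number of structures still
        lacking an InChI — the keys that are unique to keys-only sources.
        """
        (n,) = self.con.execute(
            "SELECT COUNT(*) FROM UC_STRUCTURE WHERE standardinchi IS NULL"
        ).fetchone()
        return n

    # -- hierarchy queries ----------------------------------------------

    def children_of(self, parent: str) -> list[str]:
        return [
            r[0]
            for r in self.con.execute(
                "SELECT child FROM UC_FIKHB_HIERARCHY WHERE parent=? ORDER BY child",
                (parent,),
            )
        ]

    def parents_of(self, child: str) -> list[str]:
        return [
            r[0]
            for r in self.con.execute(
                "SELECT parent FROM UC_FIKHB_HIERARCHY WHERE child=? ORDER BY parent",
                (child,),
            )
        ]

    def component_frequency(self, child: str) -> int:
        """Number of distinct parent FIKHBs containing ``child`` — the
        quantity the frequency-block criterion thresholds on."""
        (n,) = self.con.execute(
            "SELECT COUNT(DISTINCT parent) FROM UC_FIKHB_HIERARCHY WHERE child=?",
            (child,),
        ).fetchone()
        return n

    # -- structure / assignment queries ---------------------------------

    def structure_by_key(self, key: str) -> StructureRow | None:
        row = self.con.execute(
            "SELECT uci, standardinchi, standardinchikey, fikhb "
            "FROM UC_STRUCTURE WHERE standardinchikey=?",
            (key,),
        ).fetchone()
        return StructureRow(*row) if row else None

    def structure_by_uci(self, uci: int) -> StructureRow | None:
        row = self.con.execute(
            "SELECT uci, standardinchi, standardinchikey, fikhb "
            "FROM UC_STRUCTURE WHERE uci=?",
            (uci,),
        ).fetchone()
        return StructureRow(*row) if row else None

    def structures_by_fikhb(self, fikhb: str) -> list[StructureRow]:
        return [
            StructureRow(*row)
            for row in self.con.execute(
                "SELECT uci, standardinchi, standardinchikey, fikhb "
                "FROM UC_STRUCTURE WHERE fikhb=? ORDER BY uci",
                (fikhb,),
            )
        ]

    def structures_by_key_prefix(self, prefix: str) -> list[StructureRow]:
        """Structures whose InChIKey starts with ``prefix`` (used for the
        minus-proton-flag pattern; served by the unique key index)."""
        return [
            StructureRow(*row)
            for row in self.con.execute(
                "SELECT uci, standardinchi, standardinchikey, fikhb "
                "FROM UC_STRUCTURE WHERE standardinchikey GLOB ? ORDER BY uci",
                (prefix + "*",),
            )
        ]

    def assignments_for_uci(self, uci: int) -> list[AssignmentRow]:
        return [
            AssignmentRow(*row)
            for row in self.con.execute(
                "SELECT x.src_compound_id, x.src_id, s.name, x.uci, x.current "
                "FROM UC_XREF x JOIN UC_SOURCE s ON s.src_id = x.src_id "
                "WHERE x.uci=? ORDER BY x.src_id, x.src_compound_id",
                (uci,),
            )
        ]

    def current_assignment(self, src_compound_id: str, src_id: int) -> int | None:
        row = self.con.execute(
            "SELECT uci FROM UC_XREF "
            "WHERE src_compound_id=? AND src_id=? AND current=1",
            (src_compound_id, src_id),
        ).fetchone()
        return row[0] if row else None

    def dump_assignments(self) -> list[AssignmentRow]:
        """Every assignment joined to its structure — the flat registry view
        a brute-force search oracle works from."""
        return [
            AssignmentRow(*row)
            for row in self.con.execute(
                "SELECT x.src_compound_id, x.src_id, s.name, x.uci, x.current, "
                "       t.standardinchi, t.standardinchikey, t.fikhb "
                "FROM UC_XREF x "
                "JOIN UC_SOURCE s ON s.src_id = x.src_id "
                "JOIN UC_STRUCTURE t ON t.uci = x.uci "
                "ORDER BY x.src_id, x.src_compound_id, x.uci"
            )
        ]


def read_source_file(path: str | Path) -> Iterator[tuple[str, ...]]:
    """Iterate the tab-separated records of a source assignment file.

    Columns are src_compound_id, standard_inchi[, standard_inchikey] — or
    src_compound_id, standard_inchikey for the keys-only dialect.  An
    optional header line is detected by the literal prefix
    ``src_compound_id``.  Blank lines are skipped; malformed lines are
    yielded as-is so the loader rejects, logs and counts them.
    """
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if lineno == 1 and line.startswith("src_compound_id"):
                continue
            yield tuple(f.strip() for f in line.split("\t"))
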