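"""Batch name resolution and the ragged synonym-CSV format.

The output format is deliberately simple: a headerless CSV where the
first column of each row is the input species name and each successive
column is one candidate synonym.  Rows are ragged (a name with no
synonyms occupies a single field).  Within a row the accepted
("canonical") name comes first, then the source's current name if
distinct, then the remaining synonyms in source order — a fixed ordering
so that repeated runs are byte-identical and diffable.
"""

from __future__ import annotations

import csv
import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy

from .names import DEFAULT_RULES, SubstitutionRule, normalize
from .synonym_store import SynonymRecord, SynonymSource, resolve_with_fallback

__all__ = [
    "SynonymTable",
    "EmptyInputError",
    "read_target_names",
    "run_queries",
    "write_synonym_csv",
    "read_synonym_csv",
]

logger = logging.getLogger(__name__)

DEFAULT_WORKERS = 4

#: header words recognised (case-insensitively) in the first cell of a
#: name-list file; such a first row is skipped.
_HEADER_WORDS = {
    "species", "name", "taxon", "taxa", "scientific_name", "scientificname",
    "species_name", "binomial", "tip", "label",
}

_NEWICK_SUFFIXES = {".nwk", ".newick", ".tre", ".tree", ".nex", ".phy"}


class EmptyInputError(ValueError):
    """The name source contained no usable names."""


def _looks_like_newick(path: Path) -> bool:
    if path.suffix.lower() in _NEWICK_SUFFIXES:
        return True
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                return line.lstrip().startswith("(")
    return False


def read_target_names(path: str | Path) -> list[str]:
    """Read target species names from a text/CSV list or a Newick tree.

    Newick input (detected by extension or a leading ``(``) yields the
    leaf labels in tree order, with quoted labels unquoted and
    underscores preserved byte-for-byte.  Text/CSV input yields
    first-column values, skipping blank lines and an optional
    header row whose first cell is a recognised header word.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _looks_like_newick(path):
        try:
            tree = dendropy.Tree.get(
                path=str(path),
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:
            raise ValueError(f"malformed Newick in {path}: {exc}") from exc
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon]
        if not labels:
            raise EmptyInputError(f"no leaf labels in {path}")
        return labels
    names: list[str] = []
    with path.open(encoding="utf-8", newline="") as fh:
        for i, row in enumerate(csv.reader(fh)):
            if not row or not row[0].strip():
                continue
            first = row[0].strip()
            if i == 0 and normalize(first).replace(" ", "_") in _HEADER_WORDS:
                continue
            names.append(first)
    if not names:
        raise EmptyInputError(f"empty input: {path}")
    return names


@dataclass
class SynonymTable:
    """Ordered batch-resolution result: one row per distinct input name."""

    rows: list[SynonymRecord]
    source: str = ""
    rule_set: tuple[SubstitutionRule, ...] = DEFAULT_RULES

    @property
    def n_matched(self) -> int:
        return sum(r.matched for r in self.rows)

    @property
    def n_via_variant(self) -> int:
        return sum(r.via_variant is not None for r in self.rows)

    def __len__(self) -> int:
        return len(self.rows)


def run_queries(
    names: Sequence[str],
    source: SynonymSource,
    workers: int = DEFAULT_WORKERS,
    rules: Sequence[SubstitutionRule] = DEFAULT_RULES,
) -> SynonymTable:
    """Resolve every distinct input name against a source, in input order.

    Duplicate inputs (under the normalization key) collapse to one row
    and are logged.  Queries run on a thread pool (``workers`` threads,
    default 4) but results are keyed by input position, so the output is
    identical regardless of scheduling.  A backend exception marks that
    row unmatched and retryable instead of aborting the batch.
    """
    if not names:
        raise EmptyInputError("no input names")
    if workers < 1:
        raise ValueError("workers must be >= 1")
    distinct: list[str] = []
    seen: set[str] = set()
    for n in names:
        k = normalize(n)
        if k in seen:
            logger.info("duplicate input name collapsed: %r", n)
            continue
        seen.add(k)
        distinct.append(n)

    def one(name: str) -> SynonymRecord:
        try:
            return resolve_with_fallback(source, name, rules)
        except Exception as exc:  # transport failure: mark retryable
            logger.warning("backend failure for %r: %s", name, exc)
            return SynonymRecord(query=name, source=getattr(source, "name", ""), retryable=True)

    if workers == 1:
        rows = [one(n) for n in distinct]
    else:
        with ThreadPoolExecutor(max_workers=workers) as pool:
            rows = list(pool.map(one, distinct))
    table = SynonymTable(rows, source=getattr(source, "name", ""), rule_set=tuple(rules))
    logger.info(
        "resolved %d names: %d matched (%d via variant), %d unmatched",
        len(table), table.n_matched, table.n_via_variant, len(table) - table.n_matched,
    )
    return table


def _row_fields(record: SynonymRecord) -> list[str]:
    qkey = normalize(record.query)
    fields, seen = [record.query], {qkey}
    for n in [record.canonical, record.current, *record.synonyms]:
        if n is None:
            continue
        k = normalize(n)
        if k not in seen:
            seen.add(k)
            fields.append(n)
    return fields


def write_synonym_csv(table: SynonymTable, path: str | Path) -> Path:
    """Write the ragged synonym CSV (no header; row = query, syn1, ...)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        for record in table.rows:
            writer.writerow(_row_fields(record))
    return path


def read_synonym_csv(path: str | Path) -> SynonymTable:
    """Read a ragged synonym CSV back into a SynonymTable.

    The first field of each row is the query; the rest are its synonyms
    (the list-of-lists the reconciler consumes).  Blank lines are skipped
    with a warning; an empty file is an error.
    """
    path = Path(path)
    rows: list[SynonymRecord] = []
    with path.open(encoding="utf-8", newline="") as fh:
        for i, fields in enumerate(csv.reader(fh), start=1):
            if not fields or not any(f.strip() for f in fields):
                logger.warning("%s:%d: blank line skipped", path, i)
                continue
            query, syns = fields[0], [f for f in fields[1:] if f.strip()]
            if syns:
                rows.append(SynonymRecord(query=query, matched=True,
                                          canonical=syns[0], synonyms=syns[1:]))
            else:
                rows.append(SynonymRecord(query=query))
    if not rows:
        raise EmptyInputError(f"empty synonym CSV: {path}")
    return SynonymTable(rows)
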