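"""Rewrite comparative trait tables to match phylogeny tip labels.

The tree is the reference naming frame: trait-table species names are
mapped onto tip labels through the synonym table (a list of name
"clouds", each cloud one row of the ragged synonym CSV), and the matched
tip label — in the tree's exact spelling — is written into a new column.
Every row is preserved; names that cannot be placed are reported, not
dropped, and names whose synonym cloud touches two or more distinct tips
are flagged ambiguous rather than silently assigned.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .names import MalformedNameError, normalize, parse_name
from .query import SynonymTable

__all__ = [
    "TraitTable",
    "MatchIndex",
    "ReconcileReport",
    "read_trait_csv",
    "build_match_index",
    "reconcile_table",
    "write_reconciled",
    "DIRECT",
    "RECOVERED",
    "AMBIGUOUS",
    "UNMATCHED",
]

logger = logging.getLogger(__name__)

DIRECT = "direct"
RECOVERED = "recovered"
AMBIGUOUS = "ambiguous"
UNMATCHED = "unmatched"

MATCHED_COLUMN = "tree_name"


@dataclass
class TraitTable:
    """A comparative data table whose first column is a species binomial.

    All non-name fields are opaque: reconciliation passes them through
    byte-identical and conserves row order and row count.
    """

    header: list[str]
    rows: list[list[str]]

    def __len__(self) -> int:
        return len(self.rows)


def read_trait_csv(path: str | Path) -> TraitTable:
    """Read a trait CSV (header row required, species name in column 1)."""
    path = Path(path)
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"empty trait file: {path}") from None
        rows = [row for row in reader if row and any(f.strip() for f in row)]
    if not rows:
        raise ValueError(f"no data rows in trait file: {path}")
    return TraitTable(header=header, rows=rows)


@dataclass
class MatchIndex:
    """Mapping from name keys to tip labels, plus the ambiguity set.

    ``mapping`` sends the normalization key of a name to the tip label it
    resolves to (tips map to themselves).  Keys whose synonym clouds
    touch two or more distinct tips, or that are claimed by clouds
    pointing at different tips, live in ``ambiguous`` instead.
    """

    mapping: dict[str, str] = field(default_factory=dict)
    ambiguous: dict[str, tuple[str, ...]] = field(default_factory=dict)
    tip_keys: dict[str, str] = field(default_factory=dict)


def build_match_index(synonyms: SynonymTable | None, tips: Sequence[str]) -> MatchIndex:
    """Index every synonym cloud against the tip-label set.

    For each cloud (query plus its synonyms): if exactly one member keys
    to a tip, every other member maps to that tip; if two or more
    distinct tips are touched, the non-tip members are flagged ambiguous.
    A name that is itself a tip always maps to itself (direct identity
    overrides any cloud membership).  An empty synonym table yields the
    identity-on-tips mapping.
    """
    if not tips:
        raise ValueError("tip set is empty")
    tip_by_key: dict[str, str] = {}
    for t in tips:
        k = normalize(t)
        if k in tip_by_key and tip_by_key[k] != t:
            logger.warning("tip labels %r and %r share a key; first kept", tip_by_key[k], t)
            continue
        tip_by_key[k] = t

    candidates: dict[str, set[str]] = {}
    rows = synonyms.rows if synonyms is not None else []
    for record in rows:
        cloud = record.all_names()
        cloud_tips = {tip_by_key[k] for n in cloud if (k := normalize(n)) in tip_by_key}
        if len(cloud_tips) != 1:
            if len(cloud_tips) > 1:
                for n in cloud:
                    k = normalize(n)
                    if k not in tip_by_key:
                        candidates.setdefault(k, set()).update(cloud_tips)
            continue
        (tip,) = cloud_tips
        for n in cloud:
            k = normalize(n)
            if k not in tip_by_key:
                candidates.setdefault(k, set()).add(tip)

    index = MatchIndex(tip_keys=tip_by_key)
    index.mapping.update(tip_by_key)
    for k, tipset in candidates.items():
        if len(tipset) == 1:
            index.mapping[k] = next(iter(tipset))
        else:
            index.ambiguous[k] = tuple(sorted(tipset))
    return index


@dataclass
class ReconcileReport:
    """Per-run accounting of how each distinct trait name was placed.

    The four categories partition the distinct input names:
    ``n_direct + n_recovered + n_ambiguous + n_unmatched == n_input``.
    ``collisions`` lists tip labels claimed by more than one distinct
    original name (taxonomic lumping) — allowed and reported, all rows
    kept.  ``ledger`` maps each original name to its resolved tip and
    outcome class, in first-occurrence order.
    """

    n_input: int = 0
    n_rows: int = 0
    n_direct: int = 0
    n_recovered: int = 0
    n_ambiguous: int = 0
    n_unmatched: int = 0
    collisions: dict[str, tuple[str, ...]] = field(default_factory=dict)
    ledger: list[tuple[str, str, str]] = field(default_factory=list)  # (name, tip-or-empty, class)

    def counts(self) -> tuple[int, int, int, int]:
        return (self.n_direct, self.n_recovered, self.n_ambiguous, self.n_unmatched)

    def check_partition(self) -> None:
        total = self.n_direct + self.n_recovered + self.n_ambiguous + self.n_unmatched
        if total != self.n_input:
            raise AssertionError(
                f"partition broken: {self.counts()} sums to {total}, n_input={self.n_input}"
            )


def reconcile_table(
    traits: TraitTable,
    index: MatchIndex,
    sentinel: str = "",
    in_place: bool = False,
    collapse_trinomials: bool = True,
    matched_column: str = MATCHED_COLUMN,
) -> tuple[TraitTable, ReconcileReport]:
    """Attach the phylogeny-matched name to every trait row.

    Each row's species name is looked up in the match index; the matched
    tip label (tree spelling, byte-for-byte) is written into a new
    ``matched_column`` — or over the name column when ``in_place``.
    Ambiguous and unmatched names receive the ``sentinel`` (default
    empty, so no legitimate name can collide with it).  Trinomials are
    collapsed to the binomial before matching by default (with a log
    message); malformed names count as unmatched.  Accounting is over
    distinct name keys; row count and non-name fields are conserved.

    Reconciliation is idempotent: feeding the matched column back
    through the same index changes nothing, because every matched value
    is a tip label and tips map to themselves.
    """
    if not traits.rows:
        raise ValueError("trait table has no data rows")

    out_rows: list[list[str]] = []
    outcome_by_key: dict[str, tuple[str, str, str]] = {}
    order: list[str] = []
    tip_claims: dict[str, set[str]] = {}

    for row in traits.rows:
        name = row[0]
        key = normalize(name)
        try:
            parsed = parse_name(name)
            if collapse_trinomials and parsed.is_trinomial:
                logger.info("trinomial %r collapsed to binomial for matching", name)
                key = normalize(parsed.binomial())
        except MalformedNameError:
            parsed = None

        if key not in outcome_by_key:
            if parsed is None:
                outcome = (name, sentinel, UNMATCHED)
                logger.warning("malformed species name %r counted unmatched", name)
            elif key in index.tip_keys:
                tip = index.tip_keys[key]
                outcome = (name, tip, DIRECT)
            elif key in index.mapping:
                tip = index.mapping[key]
                outcome = (name, tip, RECOVERED)
            elif key in index.ambiguous:
                outcome = (name, sentinel, AMBIGUOUS)
            else:
                outcome = (name, sentinel, UNMATCHED)
            outcome_by_key[key] = outcome
            order.append(key)
            if outcome[2] in (DIRECT, RECOVERED):
                tip_claims.setdefault(outcome[1], set()).add(key)

        _, tip_value, cls = outcome_by_key[key]
        new_row = list(row)
        if in_place:
            if cls in (DIRECT, RECOVERED):
                new_row[0] = tip_value
        else:
            new_row.append(tip_value)
        out_rows.append(new_row)

    report = ReconcileReport(n_input=len(outcome_by_key), n_rows=len(traits.rows))
    for key in order:
        name, tip, cls = outcome_by_key[key]
        report.ledger.append((name, tip if cls in (DIRECT, RECOVERED) else "", cls))
        if cls == DIRECT:
            report.n_direct += 1
        elif cls == RECOVERED:
            report.n_recovered += 1
        elif cls == AMBIGUOUS:
            report.n_ambiguous += 1
        else:
            report.n_unmatched += 1
    report.collisions = {
        tip: tuple(sorted(keys)) for tip, keys in tip_claims.items() if len(keys) > 1
    }
    report.check_partition()

    header = list(traits.header)
    if not in_place:
        header.append(matched_column)
    return TraitTable(header=header, rows=out_rows), report


def write_reconciled(
    table: TraitTable,
    report: ReconcileReport,
    trait_path: str | Path,
    report_path: str | Path | None = None,
    ledger_path: str | Path | None = None,
) -> None:
    """Write the reconciled trait CSV plus report summary and ledger TSVs."""
    trait_path = Path(trait_path)
    with trait_path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(table.header)
        writer.writerows(table.rows)
    if report_path is not None:
        with Path(report_path).open("w", encoding="utf-8", newline="") as fh:
            fh.write("metric\tvalue\n")
            for k in ("n_input", "n_rows", "n_direct", "n_recovered", "n_ambiguous", "n_unmatched"):
                fh.write(f"{k}\t{getattr(report, k)}\n")
            fh.write(f"n_collision_tips\t{len(report.collisions)}\n")
    if ledger_path is not None:
        with Path(ledger_path).open("w", encoding="utf-8", newline="") as fh:
            fh.write("original_name\tresolved_tip\toutcome\n")
            for name, tip, cls in report.ledger:
                fh.write(f"{name}\t{tip}\t{cls}\n")


def format_report(report: ReconcileReport) -> str:
    """One-paragraph human-readable summary for logs and the CLI."""
    lines = [
        f"{report.n_rows} rows, {report.n_input} distinct names: "
        f"{report.n_direct} direct, {report.n_recovered} recovered via synonyms, "
        f"{report.n_ambiguous} ambiguous, {report.n_unmatched} unmatched",
    ]
    if report.collisions:
        lines.append(f"{len(report.collisions)} tip(s) claimed by multiple input names")
    return "\n".join(lines)
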