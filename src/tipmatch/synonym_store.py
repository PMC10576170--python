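"""Synonym lookup behind a uniform source contract.

The resolving backends share one operation: ``resolve(query) ->
SynonymRecord``.  Three backends are provided:

* :class:`LocalBackboneSource` — a deterministic, offline synonym table
  loaded from a flat TSV (accepted name, synonym, status).  This is the
  workhorse for testing and for users who ship their own backbone export.
* :class:`GbifSource` — mirrors the GBIF flow: resolve the backbone
  identity of the query, then expand its synonym list by usage key.
* :class:`NcbiSource` — mirrors the NCBI Taxonomy flow: search for
  identifiers (falling back to orthographic variants on failure), drop
  duplicate identifiers, batch-fetch the records, and exhaustively
  harvest every name field.

The remote backends talk through an injectable *transport* callable, so
they are normally exercised against recorded responses replayed from
disk (:func:`replay_transport`); live HTTP is a thin optional layer.

Failure to match is never an exception: it is a record with
``matched=False``.  Homonym collisions (one name claimed by two accepted
names) are surfaced on the record, never silently resolved.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Protocol, Sequence

from .names import (
    DEFAULT_RULES,
    MalformedNameError,
    SubstitutionRule,
    format_name,
    generate_variants,
    normalize,
    parse_name,
)

__all__ = [
    "SynonymRecord",
    "BackboneTable",
    "SynonymSource",
    "BackboneFormatError",
    "LocalBackboneSource",
    "GbifSource",
    "NcbiSource",
    "load_backbone",
    "write_backbone",
    "resolve_local",
    "resolve_with_fallback",
    "dedupe_identifiers",
    "harvest_names",
    "replay_transport",
    "STATUS_FLAGS",
]

logger = logging.getLogger(__name__)

STATUS_FLAGS = ("homotypic", "heterotypic", "orthographic", "unknown")


class BackboneFormatError(ValueError):
    """A malformed backbone TSV row; the message names the offending line."""


@dataclass
class SynonymRecord:
    """The resolved identity of one query name.

    ``canonical`` is the accepted name the source settled on; ``current``
    the name the source currently uses (for the local backbone these
    coincide).  ``synonyms`` holds every *other* name in the taxon's
    cloud, deduplicated under the normalization key, never containing the
    query's own key.  ``via_variant`` records the orthographic variant
    that succeeded when the verbatim query failed.
    """

    query: str
    matched: bool = False
    canonical: str | None = None
    current: str | None = None
    synonyms: list[str] = field(default_factory=list)
    source: str = ""
    via_variant: str | None = None
    ambiguous: bool = False
    ambiguous_candidates: tuple[str, ...] = ()
    retryable: bool = False

    def __post_init__(self) -> None:
        if not self.matched:
            assert self.canonical is None and self.current is None
            assert not self.synonyms
        qkey = normalize(self.query)
        seen = {qkey}
        deduped = []
        for s in self.synonyms:
            k = normalize(s)
            if k not in seen:
                seen.add(k)
                deduped.append(s)
        self.synonyms = deduped

    def all_names(self) -> list[str]:
        """Query plus every resolved name, in record order, key-deduplicated."""
        out, seen = [], set()
        for n in [self.query, self.canonical, self.current, *self.synonyms]:
            if n is None:
                continue
            k = normalize(n)
            if k not in seen:
                seen.add(k)
                out.append(n)
        return out


class SynonymSource(Protocol):
    """The contract every backend implements.

    ``resolve`` must be deterministic for a fixed backend state and must
    express lookup failure as ``matched=False``, not as an exception.
    """

    name: str

    def resolve(self, query: str) -> SynonymRecord: ...


# ---------------------------------------------------------------------------
# Local backbone
# ---------------------------------------------------------------------------

_BACKBONE_HEADER = ("accepted_name", "synonym", "status")


@dataclass
class BackboneTable:
    """In-memory synonym table with a reverse index for O(1) lookup.

    ``entries`` maps each accepted name to its ordered ``(synonym,
    status)`` list; ``reverse`` maps the normalization key of every name
    (accepted or synonym) to its accepted name.  Keys claimed by more
    than one accepted name live in ``collisions`` instead and resolve as
    ambiguous.
    """

    entries: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    reverse: dict[str, str] = field(default_factory=dict)
    collisions: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def accepted_names(self) -> list[str]:
        return list(self.entries)


def load_backbone(path: str | Path, strict: bool = False) -> BackboneTable:
    """Load a backbone TSV (``accepted_name<TAB>synonym<TAB>status``).

    One row per (accepted, synonym) pair; an accepted name with no
    synonyms appears once with an empty synonym field.  Duplicate
    accepted-name rows merge with synonym-set union.  A synonym key
    claimed by two different accepted names is a cross-code homonym: it
    is recorded in ``collisions`` (and resolves as ambiguous), or raises
    if ``strict``.
    """
    path = Path(path)
    table = BackboneTable()
    claimed: dict[str, set[str]] = {}
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if lineno == 1 and tuple(c.strip().lower() for c in cols[:3]) == _BACKBONE_HEADER:
                continue
            if len(cols) not in (2, 3):
                raise BackboneFormatError(
                    f"{path}:{lineno}: expected 2-3 tab-separated columns, got {len(cols)}"
                )
            accepted = cols[0].strip()
            synonym = cols[1].strip() if len(cols) > 1 else ""
            status = cols[2].strip().lower() if len(cols) > 2 and cols[2].strip() else "unknown"
            if not accepted:
                raise BackboneFormatError(f"{path}:{lineno}: empty accepted name")
            if status not in STATUS_FLAGS:
                raise BackboneFormatError(
                    f"{path}:{lineno}: unknown status {status!r} (expected one of {STATUS_FLAGS})"
                )
            entry = table.entries.setdefault(accepted, [])
            claimed.setdefault(normalize(accepted), set()).add(accepted)
            if synonym:
                if normalize(synonym) == normalize(accepted):
                    continue  # an accepted name never lists itself
                if normalize(synonym) not in {normalize(s) for s, _ in entry}:
                    entry.append((synonym, status))
                claimed.setdefault(normalize(synonym), set()).add(accepted)
    for key, owners in claimed.items():
        if len(owners) > 1:
            pair = tuple(sorted(owners))
            if strict:
                raise BackboneFormatError(
                    f"{path}: homonym collision: key {key!r} claimed by {pair}"
                )
            warnings.warn(
                f"backbone homonym: {key!r} claimed by {pair}; lookups will be ambiguous",
                stacklevel=2,
            )
            table.collisions[key] = pair
        else:
            table.reverse[key] = next(iter(owners))
    return table


def write_backbone(table: BackboneTable, path: str | Path) -> Path:
    """Serialize a backbone back to TSV (round-trips with load_backbone)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write("\t".join(_BACKBONE_HEADER) + "\n")
        for accepted, syns in table.entries.items():
            if not syns:
                fh.write(f"{accepted}\t\t\n")
            for syn, status in syns:
                fh.write(f"{accepted}\t{syn}\t{status}\n")
    return path


def resolve_local(table: BackboneTable, query: str) -> SynonymRecord:
    """Resolve a query against the backbone via the reverse index.

    A hit on either an accepted name or any synonym returns the accepted
    name as canonical and the rest of that taxon's name cloud as the
    synonym list.  A key in the collision set returns an unmatched record
    flagged ambiguous, carrying both candidate accepted names.
    """
    key = normalize(query)
    if key in table.collisions:
        return SynonymRecord(
            query=query,
            source="local",
            ambiguous=True,
            ambiguous_candidates=table.collisions[key],
        )
    accepted = table.reverse.get(key)
    if accepted is None:
        return SynonymRecord(query=query, source="local")
    cloud = [accepted] + [s for s, _ in table.entries[accepted]]
    synonyms = [n for n in cloud if normalize(n) != key]
    return SynonymRecord(
        query=query,
        matched=True,
        canonical=accepted,
        current=accepted,
        synonyms=synonyms,
        source="local",
    )


@dataclass
class LocalBackboneSource:
    """SynonymSource over a loaded BackboneTable."""

    table: BackboneTable
    name: str = "local"

    @classmethod
    def from_path(cls, path: str | Path, strict: bool = False) -> "LocalBackboneSource":
        return cls(load_backbone(path, strict=strict))

    def resolve(self, query: str) -> SynonymRecord:
        return resolve_local(self.table, query)


# ---------------------------------------------------------------------------
# Fallback through orthographic variants
# ---------------------------------------------------------------------------


def resolve_with_fallback(
    source: SynonymSource,
    query: str,
    rules: Sequence[SubstitutionRule] = DEFAULT_RULES,
) -> SynonymRecord:
    """Resolve verbatim; on failure retry each suffix variant in rule order.

    The first matching variant wins and is recorded in ``via_variant``;
    the returned record keeps the original query.  With an empty rule set
    this is exactly a plain resolve.  Ambiguity flags from the backend
    propagate unchanged.
    """
    record = source.resolve(query)
    if record.matched or record.ambiguous or not rules:
        return record
    try:
        parsed = parse_name(query)
    except MalformedNameError:
        return record
    sep = "_" if "_" in query else " "
    for variant in generate_variants(parsed, rules):
        vname = format_name(variant, sep)
        vrec = source.resolve(vname)
        if vrec.matched or vrec.ambiguous:
            vrec.query = query
            vrec.via_variant = vname
            # the variant that matched belongs in the cloud reported back
            if vrec.matched and normalize(vname) not in {
                normalize(n) for n in [vrec.canonical or "", vrec.current or "", *vrec.synonyms]
            }:
                vrec.synonyms.append(vname)
            vrec.synonyms = [s for s in vrec.synonyms if normalize(s) != normalize(query)]
            return vrec
    return record


# ---------------------------------------------------------------------------
# Remote-flow helpers (shared by the NCBI-style adapter)
# ---------------------------------------------------------------------------


def dedupe_identifiers(ids: Iterable) -> list:
    """Remove duplicate identifiers, keeping first occurrence and order."""
    seen: set = set()
    out = []
    for i in ids:
        if i not in seen:
            seen.add(i)
            out.append(i)
    return out


_DEFAULT_NAME_FIELDS = ("ScientificName", "Name", "OtherNames")


def harvest_names(entry, name_fields: Sequence[str] = _DEFAULT_NAME_FIELDS) -> list[str]:
    """Exhaustively collect name strings from a backend record.

    Walks the nested field structure; every string found at or below a
    designated name field is collected, recursively, deduplicated under
    the normalization key with original spellings preserved.  Missing
    fields contribute nothing.
    """

    def strings_below(node) -> Iterable[str]:
        if isinstance(node, str):
            yield node
        elif isinstance(node, dict):
            # classed name items ({ClassCDE, DispName, ...}) carry the
            # name itself in DispName; the class label is not a name
            if "DispName" in node:
                yield from strings_below(node["DispName"])
            else:
                for v in node.values():
                    yield from strings_below(v)
        elif isinstance(node, (list, tuple)):
            for v in node:
                yield from strings_below(v)

    def walk(node) -> Iterable[str]:
        if isinstance(node, dict):
            for k, v in node.items():
                if k in name_fields:
                    yield from strings_below(v)
                else:
                    yield from walk(v)
        elif isinstance(node, (list, tuple)):
            for v in node:
                yield from walk(v)

    out, seen = [], set()
    for s in walk(entry):
        s = s.strip()
        if not s:
            continue
        k = normalize(s)
        if k not in seen:
            seen.add(k)
            out.append(s)
    return out


# ---------------------------------------------------------------------------
# Remote adapters (transport-injected; tested via recorded-response replay)
# ---------------------------------------------------------------------------

#: A transport maps (operation, parameters) to a decoded JSON-like payload.
Transport = Callable[[str, dict], object]


def replay_transport(fixtures_dir: str | Path) -> Transport:
    """Transport replaying recorded responses from a fixtures directory.

    One JSON file per query, named by the query's normalization key with
    spaces replaced by underscores; each file maps operation names to the
    payload that operation returned.  A missing file behaves like an
    empty (no-hit) response.
    """
    fixtures_dir = Path(fixtures_dir)

    def transport(operation: str, params: dict):
        query = params.get("name") or params.get("term") or params.get("key", "")
        fname = normalize(str(query)).replace(" ", "_") + ".json"
        fpath = fixtures_dir / fname
        if not fpath.exists():
            return None
        payload = json.loads(fpath.read_text(encoding="utf-8"))
        return payload.get(operation)

    return transport


@dataclass
class GbifSource:
    """GBIF-style flow: backbone identity first, then synonym expansion.

    ``name_backbone`` resolves the query to its backbone usage (canonical
    name, usage key, current/accepted name); ``synonyms`` expands the
    usage key into the known synonym list.  Works against any transport;
    use :func:`replay_transport` for offline operation or
    :func:`live_gbif_transport` for the network.
    """

    transport: Transport
    name: str = "gbif"

    def resolve(self, query: str) -> SynonymRecord:
        hit = self.transport("name_backbone", {"name": query})
        if not hit or not isinstance(hit, dict) or hit.get("matchType") in (None, "NONE"):
            return SynonymRecord(query=query, source=self.name)
        canonical = hit.get("canonicalName")
        current = hit.get("species") or hit.get("acceptedName") or canonical
        key = hit.get("usageKey")
        syn_payload = self.transport("synonyms", {"name": query, "key": key}) or []
        names = []
        for item in syn_payload:
            if isinstance(item, dict):
                n = item.get("canonicalName") or item.get("scientificName")
            else:
                n = item
            if n:
                names.append(str(n))
        qkey = normalize(query)
        ordered = [n for n in [canonical, current, *names] if n and normalize(n) != qkey]
        if canonical is None:
            return SynonymRecord(query=query, source=self.name)
        return SynonymRecord(
            query=query,
            matched=True,
            canonical=canonical,
            current=current,
            synonyms=[n for n in ordered if normalize(n) not in (normalize(canonical), normalize(current or canonical))] ,
            source=self.name,
        )


@dataclass
class NcbiSource:
    """NCBI-Taxonomy-style flow: search, dedupe ids, batch fetch, harvest.

    A query matching several distinct identifiers (a true homonym) has
    its harvested names unioned and the record flagged ambiguous.
    """

    transport: Transport
    name: str = "ncbi"

    def resolve(self, query: str) -> SynonymRecord:
        ids = self.transport("esearch", {"term": query}) or []
        ids = dedupe_identifiers(ids)
        if not ids:
            return SynonymRecord(query=query, source=self.name)
        entries = self.transport("efetch", {"term": query, "ids": ids}) or []
        names: list[str] = []
        canonical = None
        for entry in entries:
            if canonical is None and isinstance(entry, dict):
                canonical = entry.get("ScientificName")
            names.extend(harvest_names(entry))
        qkey = normalize(query)
        synonyms, seen = [], {qkey}
        if canonical:
            seen.add(normalize(canonical))
        for n in names:
            k = normalize(n)
            if k not in seen:
                seen.add(k)
                synonyms.append(n)
        if canonical is None and not synonyms:
            return SynonymRecord(query=query, source=self.name)
        ambiguous = len(ids) > 1
        return SynonymRecord(
            query=query,
            matched=True,
            canonical=canonical,
            current=canonical,
            synonyms=synonyms,
            source=self.name,
            ambiguous=ambiguous,
            ambiguous_candidates=tuple(str(i) for i in ids) if ambiguous else (),
        )


def live_gbif_transport(base_url: str = "https://api.gbif.org/v1") -> Transport:
    """Live HTTP transport for GbifSource (stdlib urllib; optional layer)."""
    import urllib.parse
    import urllib.request

    def transport(operation: str, params: dict):
        if operation == "name_backbone":
            q = urllib.parse.urlencode({"name": params["name"]})
            url = f"{base_url}/species/match?{q}"
        elif operation == "synonyms":
            url = f"{base_url}/species/{params['key']}/synonyms"
        else:  # pragma: no cover - defensive
            return None
        with urllib.request.urlopen(url, timeout=30) as resp:
            payload = json.load(resp)
        if operation == "synonyms":
            return payload.get("results", [])
        return payload

    return transport


def live_ncbi_transport(email: str, api_key: str | None = None) -> Transport:
    """Live Entrez transport for NcbiSource (optional layer)."""
    from Bio import Entrez

    Entrez.email = email
    if api_key:
        Entrez.api_key = api_key

    def transport(operation: str, params: dict):
        if operation == "esearch":
            with Entrez.esearch(db="taxonomy", term=params["term"]) as h:
                return Entrez.read(h).get("IdList", [])
        if operation == "efetch":
            with Entrez.efetch(db="taxonomy", id=",".join(map(str, params["ids"]))) as h:
                return Entrez.read(h)
        return None  # pragma: no cover - defensive

    return transport
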