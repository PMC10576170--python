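"""Synthetic taxonomies with planted nomenclature drift.

Real benchmarks of name reconciliation need a large occurrence dataset,
a reference phylogeny, and live database state — none of which is
self-contained or stable.  This module generates the whole study system
with known ground truth instead: a backbone of pseudo-Latin accepted
names with planted synonym clouds (orthographic variants, genus
transfers, replacement names), a random phylogeny over the accepted
names, and a trait table whose species labels are a controlled mixture
of accepted names, planted synonyms, and orphans absent from the
backbone.  Because every planted name's fate is recorded at generation
time, the expected reconciliation report is known exactly and
independently of the matching code it is used to test.

All randomness flows from one ``random.Random(seed)`` stream built on
integer draws, so a fixed config reproduces byte-identical backbone,
tree and truth files across platforms.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from .names import DEFAULT_RULES, SubstitutionRule, TaxonName, format_name, normalize
from .reconcile import ReconcileReport
from .synonym_store import BackboneTable, write_backbone

__all__ = ["SynthConfig", "GroundTruth", "generate_taxonomy", "make_tree",
           "make_trait_table", "generate_fixture_set"]

# Classes a generated name can belong to.
ACCEPTED = "accepted"
ORTHOGRAPHIC = "orthographic"   # suffix-swapped epithet, same genus
HETEROTYPIC = "heterotypic"     # genus transfer
HOMOTYPIC = "homotypic"         # replacement epithet, same genus
ORPHAN = "orphan"               # absent from the backbone

_SYLLABLES = (
    "ba", "ca", "da", "fe", "ga", "hi", "ka", "la", "me", "ni", "no", "pa",
    "pe", "ra", "re", "ri", "sa", "se", "si", "ta", "te", "ti", "to", "va",
    "ve", "vi", "xa", "ze", "lo", "mu", "du", "cor", "lan", "mor", "tur",
)

#: Latin endings drawn for epithets; each is covered by the default
#: suffix-rule table so orthographic variants are always constructible.
_ENDINGS = ("us", "a", "um", "is", "ii", "ae")


@dataclass(frozen=True)
class SynthConfig:
    """Study-condition knobs for the generator.

    ``synonym_rate`` is the Poisson mean number of planted synonyms per
    accepted species.  ``p_suffix_swap`` and ``p_genus_transfer`` split
    each synonym among the orthographic / genus-transfer / replacement
    classes.  ``p_trait_synonym`` and ``p_trait_orphan`` control what
    fraction of trait rows is labeled with a planted synonym or with a
    name the backbone has never seen.  ``homonym_pairs`` plants the same
    synonym into two species' clouds to exercise the ambiguity path
    (default off).
    """

    n_species: int = 1000
    synonym_rate: float = 1.5
    p_genus_transfer: float = 0.3
    p_suffix_swap: float = 0.4
    p_trait_synonym: float = 0.2
    p_trait_orphan: float = 0.05
    homonym_pairs: int = 0
    seed: int = 0
    rules: tuple[SubstitutionRule, ...] = DEFAULT_RULES

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        for p in ("p_genus_transfer", "p_suffix_swap", "p_trait_synonym", "p_trait_orphan"):
            v = getattr(self, p)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{p} must be in [0, 1], got {v}")
        if self.p_trait_synonym + self.p_trait_orphan > 1.0:
            raise ValueError("p_trait_synonym + p_trait_orphan must be <= 1")
        if self.synonym_rate < 0:
            raise ValueError("synonym_rate must be >= 0")
        if self.homonym_pairs < 0:
            raise ValueError("homonym_pairs must be >= 0")


@dataclass
class GroundTruth:
    """Everything the generator planted, recorded at planting time.

    ``classes`` maps every generated name to ``(accepted_name, class)``;
    ``synonyms_of`` lists each accepted name's planted synonyms in
    order; ``homonym_keys`` holds the keys planted into two clouds;
    ``tips`` is the tree's tip-label set (underscore form of every
    accepted name).
    """

    classes: dict[str, tuple[str, str]] = field(default_factory=dict)
    synonyms_of: dict[str, list[str]] = field(default_factory=dict)
    homonym_keys: set[str] = field(default_factory=set)
    tips: list[str] = field(default_factory=list)

    def accepted(self) -> list[str]:
        return list(self.synonyms_of)


def _poisson(rng: random.Random, lam: float) -> int:
    """Knuth's integer Poisson sampler on the shared random stream."""
    if lam <= 0:
        return 0
    import math

    limit = math.exp(-lam)
    k, p = 0, 1.0
    while True:
        p *= rng.random()
        if p <= limit:
            return k
        k += 1


def _word(rng: random.Random, n_syllables: int) -> str:
    return "".join(rng.choice(_SYLLABLES) for _ in range(n_syllables))


def _fresh_genus(rng: random.Random, used: set[str]) -> str:
    while True:
        g = _word(rng, rng.randint(2, 3)).capitalize()
        if g.lower() not in used:
            used.add(g.lower())
            return g


def _fresh_epithet(rng: random.Random) -> str:
    return _word(rng, rng.randint(2, 3)) + rng.choice(_ENDINGS)


def generate_taxonomy(config: SynthConfig, rng: random.Random | None = None
                      ) -> tuple[BackboneTable, GroundTruth]:
    """Generate the backbone with planted synonym clouds plus ground truth.

    Accepted names are unique pseudo-Latin binomials whose epithets end
    in rule-covered Latin suffixes.  Per species, Poisson(synonym_rate)
    synonyms are planted; each synonym is, by one draw, an orthographic
    suffix variant (prob ``p_suffix_swap``), a genus transfer (prob
    ``p_genus_transfer``), or otherwise a replacement epithet in the same
    genus.  Status flags in the emitted backbone are truthful.
    ``homonym_pairs`` extra plants copy an existing synonym into a second
    species' cloud.
    """
    rng = rng if rng is not None else random.Random(config.seed)
    truth = GroundTruth()
    table = BackboneTable()
    used_keys: set[str] = set()
    used_genera: set[str] = set()
    genera_pool: list[str] = []

    def register(name: str) -> bool:
        k = normalize(name)
        if k in used_keys:
            return False
        used_keys.add(k)
        return True

    # accepted species
    accepted_names: list[TaxonName] = []
    while len(accepted_names) < config.n_species:
        if genera_pool and rng.random() < 0.6:
            genus = rng.choice(genera_pool)
        else:
            genus = _fresh_genus(rng, used_genera)
            genera_pool.append(genus)
        name = TaxonName(genus, _fresh_epithet(rng))
        display = format_name(name, " ")
        if register(display):
            accepted_names.append(name)
            truth.classes[display] = (display, ACCEPTED)
            truth.synonyms_of[display] = []
            table.entries[display] = []

    # planted synonyms
    all_synonyms: list[tuple[str, str]] = []  # (synonym display, accepted display)
    for name in accepted_names:
        accepted_display = format_name(name, " ")
        k = _poisson(rng, config.synonym_rate)
        for _ in range(k):
            for _attempt in range(50):
                r = rng.random()
                if r < config.p_suffix_swap:
                    applicable = [
                        s for rule in config.rules if (s := rule.apply(name.epithet))
                    ]
                    if not applicable:
                        continue
                    syn = TaxonName(name.genus, rng.choice(applicable))
                    cls = ORTHOGRAPHIC
                elif r < config.p_suffix_swap + config.p_genus_transfer:
                    genus = rng.choice(genera_pool)
                    if genus == name.genus:
                        genus = _fresh_genus(rng, used_genera)
                        genera_pool.append(genus)
                    syn = TaxonName(genus, name.epithet)
                    cls = HETEROTYPIC
                else:
                    syn = TaxonName(name.genus, _fresh_epithet(rng))
                    cls = HOMOTYPIC
                display = format_name(syn, " ")
                if register(display):
                    truth.classes[display] = (accepted_display, cls)
                    truth.synonyms_of[accepted_display].append(display)
                    table.entries[accepted_display].append((display, cls))
                    all_synonyms.append((display, accepted_display))
                    break

    # optional homonym planting: copy a synonym into a second cloud
    planted = 0
    attempts = 0
    while planted < config.homonym_pairs and all_synonyms and attempts < 1000:
        attempts += 1
        syn, owner = rng.choice(all_synonyms)
        other = format_name(rng.choice(accepted_names), " ")
        if other == owner:
            continue
        key = normalize(syn)
        if key in truth.homonym_keys:
            continue
        table.entries[other].append((syn, HETEROTYPIC))
        truth.homonym_keys.add(key)
        planted += 1

    # reverse index (collision-aware, mirroring load_backbone semantics)
    claimed: dict[str, set[str]] = {}
    for accepted, syns in table.entries.items():
        claimed.setdefault(normalize(accepted), set()).add(accepted)
        for syn, _status in syns:
            claimed.setdefault(normalize(syn), set()).add(accepted)
    for key, owners in claimed.items():
        if len(owners) > 1:
            table.collisions[key] = tuple(sorted(owners))
        else:
            table.reverse[key] = next(iter(owners))

    truth.tips = [format_name(n, "_") for n in accepted_names]
    return table, truth


def make_tree(truth: GroundTruth, seed: int) -> str:
    """Random binary tree over the accepted names, as a Newick string.

    Built by sequential random joins; tip labels are the underscore form
    of the accepted names; branch lengths are uniform(0, 1], written with
    six decimals.  With a single species the tree degenerates to a
    single labelled tip.
    """
    rng = random.Random(seed)
    nodes = list(truth.tips)
    if not nodes:
        raise ValueError("no accepted names to build a tree over")
    while len(nodes) > 1:
        i = rng.randrange(len(nodes))
        a = nodes.pop(i)
        j = rng.randrange(len(nodes))
        b = nodes.pop(j)
        bl_a = 1.0 - rng.random()  # uniform (0, 1]
        bl_b = 1.0 - rng.random()
        nodes.append(f"({a}:{bl_a:.6f},{b}:{bl_b:.6f})")
    return nodes[0] + ";"


def make_trait_table(
    truth: GroundTruth,
    config: SynthConfig,
    rng: random.Random | None = None,
) -> tuple[list[str], list[list[str]], ReconcileReport]:
    """One trait row per accepted species, with planted label drift.

    Each row's species label is the accepted name (underscore form) with
    probability ``1 - p_trait_synonym - p_trait_orphan``, a uniformly
    chosen planted synonym with probability ``p_trait_synonym`` (falling
    back to the accepted name when the species has no synonyms), or a
    fresh orphan name with probability ``p_trait_orphan``.  The single
    trait column is standard-normal noise.  Returns (header, rows,
    expected report): the report is bookkept at planting time — a drawn
    synonym is expected ``recovered`` unless its key was planted as a
    homonym (expected ``ambiguous``); orphans are expected ``unmatched``.
    """
    rng = rng if rng is not None else random.Random(config.seed + 1)
    header = ["species", "trait_value"]
    rows: list[list[str]] = []
    report = ReconcileReport()
    used_keys = {normalize(n) for n in truth.classes}

    for accepted in truth.accepted():
        tip = accepted.replace(" ", "_")
        r = rng.random()
        syns = truth.synonyms_of[accepted]
        if r < config.p_trait_synonym:
            if not syns:  # no planted synonym to draw: fall back to accepted
                report.n_direct += 1
                report.ledger.append((tip, tip, "direct"))
                rows.append([tip, f"{rng.gauss(0.0, 1.0):.6f}"])
                continue
            label = rng.choice(syns).replace(" ", "_")
            if normalize(label) in truth.homonym_keys:
                report.n_ambiguous += 1
                report.ledger.append((label, "", "ambiguous"))
            else:
                report.n_recovered += 1
                report.ledger.append((label, tip, "recovered"))
        elif r < config.p_trait_synonym + config.p_trait_orphan:
            while True:
                orphan = TaxonName(_fresh_genus(rng, set()), _fresh_epithet(rng))
                label = format_name(orphan, "_")
                if normalize(label) not in used_keys:
                    used_keys.add(normalize(label))
                    break
            report.n_unmatched += 1
            report.ledger.append((label, "", "unmatched"))
        else:
            label = tip
            report.n_direct += 1
            report.ledger.append((label, tip, "direct"))
        rows.append([label, f"{rng.gauss(0.0, 1.0):.6f}"])

    report.n_input = len(rows)
    report.n_rows = len(rows)
    report.check_partition()
    return header, rows, report


def generate_fixture_set(config: SynthConfig, outdir: str | Path) -> dict[str, Path]:
    """Emit backbone TSV, Newick tree, trait CSV and ground-truth TSV.

    Byte-identical for identical configs.  Returns the written paths
    under keys ``backbone``, ``tree``, ``traits``, ``truth``,
    ``expected_report``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(config.seed)
    table, truth = generate_taxonomy(config, rng)
    paths = {
        "backbone": outdir / "backbone.tsv",
        "tree": outdir / "tree.nwk",
        "traits": outdir / "traits.csv",
        "truth": outdir / "truth.tsv",
        "expected_report": outdir / "expected_report.tsv",
    }
    write_backbone(table, paths["backbone"])
    paths["tree"].write_text(make_tree(truth, config.seed + 7) + "\n", encoding="utf-8")
    header, rows, expected = make_trait_table(truth, config, rng)
    with paths["traits"].open("w", encoding="utf-8", newline="") as fh:
        fh.write(",".join(header) + "\n")
        for row in rows:
            fh.write(",".join(row) + "\n")
    with paths["truth"].open("w", encoding="utf-8", newline="") as fh:
        fh.write("name\taccepted\tclass\n")
        for name, (acc, cls) in truth.classes.items():
            fh.write(f"{name}\t{acc}\t{cls}\n")
    with paths["expected_report"].open("w", encoding="utf-8", newline="") as fh:
        fh.write("metric\tvalue\n")
        for k in ("n_input", "n_rows", "n_direct", "n_recovered", "n_ambiguous", "n_unmatched"):
            fh.write(f"{k}\t{getattr(expected, k)}\n")
    return paths
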