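# tipmatch

Reconcile species names in comparative trait tables with the tip labels
of a phylogenetic tree.

## The problem

Phylogenetic comparative analyses require every row of a trait dataset
to be matched to a tip of the tree, but the two usually come from
different sources with different taxonomies: the dataset may say
`Felis_leo` where the tree says `Panthera_leo`, carry an orthographic
variant (`taeniurum` for `taeniurus`), or use an outdated genus
combination. Rows whose names fail to match are silently dropped,
shrinking the analysis for no biological reason. tipmatch fixes this
programmatically: it compiles candidate synonyms for each tip name from
a synonym source, then rewrites the trait table so every resolvable row
carries its phylogeny-matched name, with a full accounting of what
happened to each name.

## How it works

1. **Query.** For each target name (typically the tree's tip labels) a
   synonym source is asked for the taxon's name cloud: the accepted
   (canonical) name, the currently used name, and all known synonyms.
   Sources implement one operation, `resolve(name) -> SynonymRecord`;
   shipped backends are a deterministic local backbone table (TSV of
   accepted name / synonym / status) and GBIF- and NCBI-style remote
   adapters driven through an injectable transport. When a strict lookup
   fails, a small table of bidirectional Latin suffix swaps (um↔us,
   us↔a, um↔a, is↔e, ii↔i, ae↔a) generates orthographic variants and the
   lookup is retried. Results are collated into a ragged CSV: first
   column the query, each further column one synonym.
2. **Reconcile.** The synonym lists are treated as name clouds. A trait
   name that is itself a tip matches directly; a name that shares a
   cloud with exactly one tip is *recovered* and swapped to that tip's
   exact spelling; a name whose clouds touch two or more tips is flagged
   *ambiguous* (never silently assigned); everything else is
   *unmatched*. The matched name is written to a new `tree_name` column
   (the original column is preserved), and the four outcome counts
   partition the distinct input names:
   `n_direct + n_recovered + n_ambiguous + n_unmatched = n_input`.

All comparison happens on a normalization key (case-folded,
space/underscore-collapsed); all output preserves original spellings
byte for byte, with the tree's spelling as the reference frame.

A synthetic-data generator (`tipmatch.synth`) builds complete study
systems with known ground truth — pseudo-Latin taxonomies with planted
synonym clouds, a random tree over the accepted names, and trait tables
with a controlled mixture of accepted names, synonyms, and orphans — so
the whole pipeline is testable offline, end to end, with exact expected
outcomes.

## Worked example

Generate a 200-species synthetic system, compile synonyms for the tree
tips against its backbone, and reconcile the trait table:

```sh
tipmatch synth --n-species 200 --seed 7 --out demo
tipmatch query --input demo/tree.nwk --backbone demo/backbone.tsv \
    --out demo/synonyms.csv
tipmatch reconcile --traits demo/traits.csv --synonyms demo/synonyms.csv \
    --tree demo/tree.nwk --out demo/traits_reconciled.csv \
    --report demo/report.tsv
```

The query step prints

```
200 names: 200 matched (0 via variant), 0 unmatched
```

and the reconcile step prints

```
200 rows, 200 distinct names: 163 direct, 28 recovered via synonyms, 0 ambiguous, 9 unmatched
```

meaning 163 trait rows already used a tip name, 28 rows carried a
synonym and were swapped to the tree's spelling (rows that a naive merge
would have dropped), and 9 rows carried names unknown to the backbone
(the planted orphans). `demo/synonyms.csv` holds the ragged synonym
lists, e.g.

```
Lomorcor_nobaus,Rivi nobaus,Lomorcor nobaum
```

and `demo/traits_reconciled.csv` is the input table plus the
`tree_name` column. The same steps work on real data: a Newick tree, a
trait CSV whose first column is a `Genus_epithet` name, and either a
backbone TSV export or one of the remote sources.

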