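# Methods

## The matching model

tipmatch treats taxonomic reconciliation as a set-cover problem over
*name clouds*. A cloud is one taxon's set of interchangeable names: the
accepted name plus every synonym a source knows for it. The tree's tip
labels define the reference frame; a trait-table name is placed by the
rule:

1. **direct** — the name's normalization key equals a tip's key. Direct
   identity always wins, even if some cloud also contains the name:
   moving a name that already matches a tip would require taxonomic
   judgment the software should not exercise.
2. **recovered** — the name is not a tip, but the union of all clouds
   containing it touches exactly one tip. The name is swapped to that
   tip's exact spelling.
3. **ambiguous** — the clouds containing the name touch two or more
   distinct tips (a homonym, or conflicting synonymies). The name is
   flagged and left unplaced; resolving it is the user's call.
4. **unmatched** — no cloud links the name to any tip.

The four counts partition the distinct input names; this identity is
asserted at run time on every reconciliation. Rows are never dropped or
reordered, and all non-name fields pass through untouched. Several
input names may resolve to the same tip (taxonomic lumping); these
collisions are reported but all rows are kept — aggregation is a
downstream decision.

The indexed implementation (a reverse map from name key to tip built in
one pass over the synonym table) is checked in the test suite against a
brute-force reimplementation that literally scans every synonym list
for every trait name; the two must agree name for name on randomized
fixtures.

### Normalization

Names are compared on a key that is case-folded and collapses runs of
spaces/underscores to a single space. Output never uses the key: the
tree's tip spelling is emitted byte for byte, and query/synonym
spellings are preserved in reports. Authorship strings
("Panthera leo (Linnaeus, 1758)") are stripped at parse time by taking
the leading Latin-word tokens; trinomials are collapsed to the binomial
before matching by default (`--keep-trinomials` disables this), since
trees are nearly always labeled with binomials.

### Orthographic fallback

When a strict lookup fails, variants are generated by bidirectional
whole-suffix swaps on the epithet and retried in rule order. The default
table is {um↔us, us↔a, um↔a, is↔e, ii↔i, ae↔a}, covering common Latin
gender/declension endings; only um↔us is load-bearing for the classic
failure case, the rest are pragmatic extensions and the whole table can
be replaced or emptied (`--rules`). Two guards keep every rule strictly
bidirectional: a suffix only matches at a clean boundary (the preceding
character must differ from the suffix's first character, so a degenerate
stem like `niii` matches neither `ii` nor `i`), and a swap is accepted
only if applying the rule to the result recovers the input. The genus
token is never altered, and no fuzzy or edit-distance matching is
attempted anywhere.

## Synonym sources

All backends implement `resolve(name) -> SynonymRecord` and express
failure as `matched=False`, never as an exception; homonym collisions
are surfaced on the record (`ambiguous=True` with the candidate
accepted names) rather than silently resolved either way. Synonym
status flags (homotypic / heterotypic / orthographic / unknown) are
carried through but never used to filter: the design goal is to find
*all* candidate synonyms and let the user judge.

* **Local backbone** — a TSV of (accepted_name, synonym, status) rows.
  Loading builds a reverse index over every name key; a key claimed by
  two accepted names is recorded as a collision (or raises under
  `strict=True`).
* **GBIF-style adapter** — resolve the backbone identity of the query,
  then expand its usage key into the synonym list.
* **NCBI-style adapter** — search for identifiers (with the suffix
  fallback on failure), drop duplicate identifiers keeping first
  occurrence, batch-fetch the records, and exhaustively harvest every
  name field (recursively; classed name items contribute their
  `DispName`). A query matching several distinct identifiers has its
  names unioned and the record flagged ambiguous.

The remote adapters take an injectable transport callable and are
exercised exclusively against recorded-response replay files in the
test suite (the bundled replay fixtures are hand-built synthetic
records mirroring the services' response shapes); live transports over
stdlib HTTP and Bio.Entrez exist as a thin optional layer. Batch
queries run on a thread pool (4 workers by default) but results are
keyed by input position, so output bytes are invariant to worker count
and scheduling — byte-stability is asserted in the tests.

## The synthetic study system

`tipmatch.synth` generates the three files the pipeline consumes, plus
ground truth, from a single seeded `random.Random` stream (pure integer
draws, so files are byte-identical across platforms for a fixed
config):

* **Taxonomy** — `n_species` unique pseudo-Latin binomials built from a
  fixed syllable inventory, epithets ending in one of
  -us/-a/-um/-is/-ii/-ae so that every epithet admits suffix variants.
  Per species, Poisson(`synonym_rate`) synonyms are planted; each is an
  orthographic suffix variant (probability `p_suffix_swap`), a genus
  transfer (`p_genus_transfer`), or otherwise a replacement epithet in
  the same genus, with truthful status flags in the emitted backbone.
* **Tree** — sequential random joins over the accepted names, branch
  lengths uniform(0, 1]; the tree is a label carrier, not a model of
  evolution.
* **Trait table** — one row per species; the label is a planted synonym
  with probability `p_trait_synonym` (falling back to the accepted name
  for species with no synonyms), a fresh orphan name with
  `p_trait_orphan`, otherwise the accepted name, plus one
  standard-normal trait column.

The expected reconciliation report is bookkept *at planting time*, not
re-derived from the generated files, so end-to-end tests compare two
independent code paths. Optional homonym planting (`homonym_pairs`)
copies a synonym into a second species' cloud to exercise the ambiguity
path; a trait row drawing such a name is expected ambiguous.

Defaults are `n_species=1000`, `synonym_rate=1.5`,
`p_trait_synonym=0.2`, `p_trait_orphan=0.05` — a regime where roughly a
fifth of the data would be lost to naming drift without reconciliation —
and `p_suffix_swap=0.4`, `p_genus_transfer=0.3`, chosen once as a
realistic mixture in which orthographic variants and recombinations
dominate over wholly new names. The acceptance script runs the
1000-species configuration; it completes in well under a minute on one
CPU.

What the generator does *not* emulate: misspellings beyond suffix
variation, authorship-string noise in the backbone itself, rank
structure above species, database drift over time, and the skewed
synonym-count distributions of real genera. Passing the planted-truth
benchmark therefore demonstrates the mechanics of compilation and
matching are exact, not that any particular real dataset will reach a
given recovery rate.

## Numerical and formatting choices

* Synonym CSV rows are ordered query, canonical, current, remaining
  synonyms (key-deduplicated), making repeated runs diffable; the file
  has no header because rows are ragged.
* Duplicate input names collapse to one query row; duplicate trait
  names are accounted once in the report partition (`n_input` counts
  distinct keys; `n_rows` counts rows).
* The unmatched/ambiguous sentinel in the output column is the empty
  field (configurable), so it can never collide with a real name.
* Branch lengths are written with six decimals; trait values with six
  decimals from the seeded stream.
* Poisson draws use Knuth's product method on the shared stream rather
  than a vectorized sampler, keeping generation byte-reproducible
  without a numerics dependency.

## Known limitations

* No fuzzy matching: a misspelling that is not a whole-suffix variant
  is unmatched by design.
* Cross-code homonyms can only be detected within the information one
  source provides; two sources disagreeing about a name is not detected
  because queries run against a single source at a time.
* The report treats the tree as authoritative: a wrong tip label
  propagates into every row recovered to it.
* Live remote transports are provided but intentionally untested
  against the network; recorded-response replay is the supported path.
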