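# Methods

This note documents the procedures didkit implements, the parameters that
matter, the synthetic study conditions, and the design choices made where the
problem was genuinely open.

## The construction procedure

A drug–indication database row is the join of four normalizations over one
parsed record:

1. **Parsing and filtering.** Each source export is converted to
   (source, raw drug name, entire indication value, target) records.
   Pair-style sources drop relations outside a configurable allowlist and
   blocklisted role objects (defaults: allow `may_treat`, `may_prevent`,
   `may_diagnose`, `therapeutic`, `has_role`; block `metabolite`, `prodrug`,
   `epitope`). Hierarchy-style sources treat every classification level as a
   candidate indication, collapse identical terms repeated at nested levels,
   and drop combination and ill-formed drug names. Free-text sources drop
   combination products and texts of ≥ 540 characters (after newline → space
   conversion; 539 is the longest tractable length), collapse records that
   differ only by trade name / dosage / supplier, and split the surviving
   text into targets. Every adapter's removals plus survivors sum exactly to
   its initial candidate count, and `filtered ≤ initial` always; `parsed`
   exceeds `filtered` exactly when some entire value yields several targets.

2. **Drug-name normalization.** Each raw name is looked up in every
   dictionary under a normalized key (casefold, collapse whitespace;
   punctuation preserved so chemically distinct names are not merged).
   Match quality is classified as PT-exact > synonym > quasi-synonym >
   narrower > broader (that order is also the within-authority precedence
   when several entries hit). Narrower/broader classification is driven by a
   salt/formulation token lexicon (default: hydrochloride, fumarate, sodium,
   sulfate, maleate, tartrate, acetate, mesylate, besylate, hydrate,
   dihydrate), quasi-synonymy by a modifier lexicon (anhydrous, monohydrate,
   racemic); directionality is raw-to-standard. The CAS number comes from the
   highest-ranked authority providing one, the CUI from the designated
   UMLS-like authority, and the preferred PT from rank resolution across
   authorities (equal ranks break on the lexicographically smaller concept
   id, for reproducibility). No fuzzy/edit-distance matching is performed:
   the procedure is exact-key matching over generated variants.

3. **Indication normalization.** Targets are mapped by exact key against the
   indication dictionary, preferring candidates with a *phenotypic* semantic
   type, then P status, then the smallest concept id. Non-phenotypic results
   (therapeutic-class concepts) are remapped through a curated table to the
   disease concept they imply; the initial mapping is preserved alongside and
   the final match is demoted to quasi-synonym quality. Classes without a
   curated target remain stuck, so the final non-phenotypic share can only be
   less than or equal to the initial one; the remap operation is idempotent.
   The remap table is data, not code — class→disease pairs cannot be derived
   algorithmically, so the package ships only fixtures and accepts
   user-supplied tables. Targets no single concept covers are partitioned
   into maximal dictionary-matchable spans (leftmost-longest, the same policy
   as free-text splitting) and indexed as compound components; uncovered
   residue is dropped and logged, since compound rows are rare and no
   principled residue rule exists.

4. **Subtype tagging.** Case-insensitive lexical cues over the raw entire
   value: keywords/head nouns, prefixes and suffixes, each mapping to a leaf
   label that rolls up to a lexical root and a polarity (therapeutic roots
   negative, causative roots positive, undecidable ones — including
   "diagnose" — unknown). Prefix cues require ≥ 3 characters after the
   prefix so "anti" does not fire on "ant…" words. Polarity is a function of
   the root alone. The default tables are small seeds; real deployments
   should curate their own.

Rows are unique on (source, raw drug name, target, indication CUI);
duplicates keep the best indication match quality. The file dialect is TSV
with cell-level escaping of tabs/newlines/backslashes, byte-deterministic
output, and a legacy read mode that tolerates exported-spreadsheet subsets
missing the optional initial-mapping block.

## Metrics

Terminological reduction TR = (N + X)/U as defined in the README. For drugs
the normalized identifier basis is selectable: CAS number, CUI, or either
(default), because the three variants answer different questions about
authority coverage. Overlap is the per-source mean, over that source's
unique entities, of the number of sources containing each entity (self
counts, so scores lie in [1, S]); the pooled "All" score averages over the
*union* of unique entities rather than concatenated per-source lists — this
is what lets the pooled score sit below every per-source score. At the
normalized stage, unmapped names participate as themselves (namespaced raw
keys), so unnormalizable content still counts as private content. The same
identity space is used on both sides of a sharing count within a stage.
Reported tables round to 2 decimals (half-even) at presentation only;
internal values keep full precision.

## Synthetic study conditions

`WorldSpec` defaults define the conditions under which the package is
validated: 3 sources (one per export style), 30 drug and 24 indication
concepts, 2 aliases per concept (preferred term + 1 synonym), a 0.25 chance
of an additional salt-variant alias, 5% unmappable names, 30% of indication
units carrying a therapeutic-class term (mirroring the ~29% initial
non-phenotypic share real class-heavy sources produce), 10% of classes left
without a remap entry (the observed stuck residue is a small fraction of the
class terms), 30% of concepts shared by all sources (real source overlap is
strikingly low), a mean of 3 indications per drug (the middle of the
observed per-source richness range), and 10% of free-text records exceeding
the tractability cutoff. Names come from a pronounceable syllable grammar
with global uniqueness, so alias → concept resolution is decidable by
construction and salt variants are classified narrower by construction;
indication terms are exactly two tokens so no term is a token-prefix of
another and greedy extraction is unambiguous.

The generator records, per source, the exact raw-string and normalized-key
entity sets it emitted; `expected_metrics` recomputes every statistic from
those sets by set arithmetic alone. Pipeline-vs-oracle comparison is for
*exact* equality (all means are ratios of exact integer sums, so no
tolerance is needed). What passing does and does not show: the synthetic
worlds exercise alias scatter, class remapping, hierarchy redundancy,
free-text splitting and filter accounting, but they do not model typos,
punctuation variants, genuinely ambiguous terms, manual curation, or the
scale of real corpora — results on real data depend on dictionary quality
and curated remaps in ways no synthetic test can certify. Absolute corpus
counts from licensed sources are out of scope by design.

## Numerical and degenerate-input choices

- Term keys preserve punctuation; only case and whitespace are normalized.
- Free-text sentence splitting is on `.` and `;`; extraction is greedy
  leftmost-longest over whitespace tokens, ties impossible by construction
  (longest wins at each position). A value with no dictionary hit becomes
  its own single target.
- Combination-product detection is by separator tokens
  (" and ", "/", "+", ", combinations", " with ") in the drug field;
  ill-formed hierarchy names are empty, purely numeric, or open with a
  letter-digit code token. Both are heuristics, configurable where they
  matter.
- Empty queries, empty targets, empty cue lists, negative length cutoffs,
  missing normalizations at assembly, and source-set mismatches in change
  scores are hard errors, not silent defaults.
- Determinism throughout: same inputs → byte-identical outputs; the
  generator is a pure function of its spec (including the seed).

## Problem sizes

The validation grid runs 3 world specifications × 10 seeds (roughly 150–200
table rows per world), which completes in seconds; dictionary and table
operations are dict/set-based and scale linearly in rows, so desk-scale
corpora (10⁵–10⁶ rows) remain practical in memory.

## Known limitations

- Exact-key matching only; no statistical concept mapper or fuzzy matching,
  so real free text needs richer synonym dictionaries than the fixtures.
- The shipped semantic-type scheme, lexicons, cue tables and remap fixtures
  are deliberately small seeds, not curated resources.
- The legacy table reader maps only the documented columns of exported
  subsets and ignores others.
- Trade names resolve only through dictionary synonymy; there is no
  heuristic trade-name stripping.
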