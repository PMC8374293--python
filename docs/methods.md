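# Methods

## The problem

Bibliometric studies of eponym usage need the number of citations whose
*text* (title or abstract) actually uses an eponym, per surface form and per
year. Two properties of PubMed make naive counting wrong: unfielded searches
match controlled-vocabulary (MeSH) index terms in addition to text, and
quoted phrases absent from the index are silently rewritten into broader
word queries. The package therefore (a) searches only exact quoted phrases
restricted to `[Title/Abstract]`, and (b) discards any response whose
warning list contains `QuotedPhraseNotFound` or whose reported query
translation differs from the submitted query.

## Standardization rules

Input rows carry a `names` field (surnames) and a `term` field, split by a
human curator — distinguishing a two-person eponym ("Mallory Weiss") from a
multi-word surname ("Van Slyke") is not reliably automatable, so a bare
space is deliberately *not* treated as a name separator. Mechanical rules
applied per row:

* possessive markers removed per token: trailing `'s` dropped, trailing
  `s'` loses the apostrophe; both straight `'` and curly `’` glyphs are
  accepted on input, output uses the straight glyph only;
* conjunctions between surnames (`-`, `,`, the word `and`, and combinations
  like `, and`) are normalized to hyphens;
* whitespace trimmed, internal runs collapsed (Excel exports vary);
* UTF-8 byte order mark consumed on read, never emitted on write;
* an empty `names` field marks a term-only entry (e.g. *Escherichia coli*,
  where the discoverer's name survives only inside a Latinized genus name);
  such entries are exempt from permutation, which would generate nonsense;
* a surname retaining an apostrophe after possessive stripping (e.g.
  O'Brien) is rejected: the possessive grammar below cannot represent
  internal apostrophes, and none occur in the curated list.

`invert_prepositional` is a list-preparation helper for "Term of Name"
eponyms ("Crypts of Lieberkuhn" → names "Lieberkuhn", term "Crypts"); with
more than one "of" it refuses and demands a manual split.

## Permutation grammar and its calibration

Variants are built from four axes: conjunction joiners
`{"-", " ", ", ", " and ", ", and "}` (hyphen renders the standard form),
possessive placement (none / final name / all names), the two accepted
spellings for names ending in *s* (`s'`, `s's`; other names take `'s`
only), and a single prepositional inversion `Term of Name1-…-Namek`.

The axes alone do not determine which combinations are emitted; the variant
*counts* do. The default grammar is calibrated so that every published
per-arity count is realized simultaneously:

* conjunction variants: all four non-hyphen joiners, applied uniformly;
* final-name possessive: in the three contexts `-`, ` `, ` and `;
* all-names possessive (Cartesian product of per-name spellings): in the
  single context ` and `;
* exactly one inversion whenever n ≥ 1.

For two names this gives, excluding the standard form, 4 + 1 + 3·f + 1·p
variants where f ∈ {1, 2} and p ∈ {1, 2, 4} depend on the s-endings: 9 with
no s-ending name, 10 (first only), 13 (final only — *Mallory-Weiss*,
*Peutz-Jeghers*), 15 (both). One name yields 2 (plain) or 3 (s-ending,
e.g. *Chagas*); term-only roots yield 0. Over the bundled 27-root list —
22 one-name roots (only *Chagas* s-ending), 4 two-name roots (two with
final s-endings), 1 term-only — the expansion totals 89 variants + 27
standard forms = 116 search terms. This assignment is the smallest one
consistent with all of those counts at once; equivalent reassignments that
permute which contexts carry which possessive scheme would produce the same
tallies with slightly different phrase sets.

Three-name eponyms (none in the bundled list) are supported behind an
explicit flag with a wider pattern set — 7 conjunction variants (the 4
uniform joiners plus 3 serial-comma/mixed forms), final-name possessives in
4 contexts and all-names possessives in 2 — whose s-configuration extremes
are exactly 14 (no s-endings) and 32 (all three). Without the flag, and for
any arity above three, permutation raises an unsupported-arity error rather
than guessing.

Generated phrases keep the input capitalization (searching is
case-insensitive; lowercasing would discard information), and each root's
phrase list is de-duplicated with the standard form first, so downstream
per-root deduplication deterministically attributes a citation to the
earliest-generated matching variant.

## Search client

* **Pagination.** A search uses `retmax` = page cap (default 100,000, the
  service maximum) and increments `retstart` until `count` ids are
  collected: exactly `max(1, ⌈count / cap⌉)` requests. The count and query
  translation must agree across pages and the concatenated ids must be
  duplicate-free; violations raise an integrity error rather than returning
  a silently corrupt result set.
* **Fetching.** Record details are requested as MEDLINE text in id chunks
  of at most 10,000 (the service maximum): `⌈N / chunk⌉` requests. Records
  are returned in request order; an id missing from the response is logged
  and skipped. Parsing uses Bio.Medline; the fields kept are PMID, journal
  title (JT) and publication date (DP).
* **Validity.** A response is valid iff no `QuotedPhraseNotFound` warning is
  present *and* the query translation equals the submitted query after
  case-folding and whitespace collapsing (the live service reformats
  queries benignly; byte-exact comparison would discard good results).
  Invalid queries are recorded with hit count 0 and an empty id list, and
  no fetch is ever issued for them. When the first page already carries the
  warning, paging stops — the remaining pages would be discarded anyway.
* **Etiquette.** Sliding-window rate limiting (3 requests/s without an API
  key, 10 with one, per NCBI policy; the clock and sleeper are injectable
  for testing). Transport-level failures are retried up to 3 attempts with
  exponential backoff starting at 1 s; a well-formed response with warnings
  is a semantic outcome and is never retried. Live use requires a contact
  email; it is configuration, never hard-coded.
* **Years.** The publication year is the first 4-digit token of DP, which
  covers the observed dialects ("1996", "1996 Jan", "1996 Jan-Feb",
  "1996-1997"); an unparseable DP leaves the year blank and the citation is
  tallied under an "unknown" bucket so counts always conserve.

## Deduplication semantics

`pmid_results.csv` keeps one row per (phrase, PMID) hit, so a citation using
several variants of one root appears several times. Deduplication collapses
repeats *within* a root (first-encountered phrase survives; generation order
makes that the standard form when it matched) and never across roots — the
same paper may legitimately cite two different eponyms. Conservation
invariants: before dedup, row count equals the sum of valid per-term hit
counts; after dedup, the year-summary total equals the row count. Per-root
counting implies a PMID citing k distinct roots contributes k to the sum of
per-root totals; a globally-unique-citation count would be a different
statistic and is not computed.

## The mock responder: what it emulates, what it does not

`generate_corpus` plants each phrase verbatim in an exact number of titles
and abstracts, embedded in filler drawn from a fixed generic vocabulary from
which every word of every planted phrase has been removed — so a planted
phrase can never occur by accident, and planted counts are ground truth by
construction. Plants must be pairwise substring-free after normalization
(enforced), dates are sampled from a per-plant year distribution, and the
whole corpus is a pure function of its seed. `respond_search` implements
exact-phrase matching as word-boundary-anchored containment on
whitespace-normalized, casefolded text, with ascending-PMID paging; an
absent phrase triggers the live service's misleading behaviour: a
`QuotedPhraseNotFound` warning, a translation reduced to the phrase's last
word, and hits for that word. `respond_fetch` renders MEDLINE with 6-space
continuation wrapping at column 80 and round-trips exactly through the
client's parser.

The mock does **not** emulate MeSH expansion, stemming, phrase-index gaps
for *indexed* phrases, PubMed's full query grammar, or the service's
progressive word-dropping (it broadens in a single step). Tests passing
against the mock therefore demonstrate that the client logic — pagination,
chunking, validity handling, dedup, summarization — is correct under the
documented E-utilities contract; they cannot certify live hit counts, which
depend on the database state at search time (which is why the run manifest
records the search date).

## Problem sizes and determinism

The test suite and the acceptance script run entirely at desk scale:
corpora of tens to ~100 records, pagination laws exercised at reduced caps
(1, 2, 7, 50) where the ceiling arithmetic is the same law as at the
service caps, and end-to-end recovery checked across three seeds. All
randomness flows from explicit integer seeds; identical configuration
yields byte-identical outputs apart from the manifest timestamp.

## Known limitations

* Title/Abstract only: usage in full text, captions or references is
  invisible, as is usage in papers without abstracts where the term appears
  only in the body.
* The grammar covers conjunction/possessive/inversion variation; it does
  not generate plural/singular term variants, abbreviations, or diacritic
  variants (the curated list is ASCII; transliteration would silently
  change search phrases).
* Internal-apostrophe surnames are rejected rather than permuted.
* The three-name pattern set is an extrapolation constrained only by the
  documented count range; it is opt-in for that reason.
* Per-root deduplication is the only dedup offered; cross-root overlap is
  reported, not collapsed.
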