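# eponymsearch

Tools for measuring how medical **eponyms** — diseases, signs, structures and
procedures named after people, like *Zenker Diverticulum* or *Mallory-Weiss
Tear* — are used in the biomedical literature.

Counting eponym usage with PubMed is harder than it looks. The same eponym
appears under many surface forms ("Zenker's Diverticulum", "Diverticulum of
Zenker", "Mallory Weiss tear", "Mallory-Weiss' tear", …), an unfielded PubMed
search silently matches MeSH index terms rather than actual textual usage,
and when a quoted phrase does not exist in the index the service *broadens*
the query (dropping words) and returns thousands of unrelated hits, flagged
only by a `QuotedPhraseNotFound` warning. This package automates the whole
workflow while avoiding those pitfalls:

1. **Standardize** a curated eponym list (CSV with `names`/`term` columns):
   strip possessives ("Zenker's" → "Zenker"), hyphenate conjunctions
   ("Zollinger and Ellison" → "Zollinger-Ellison"), tolerate Excel's UTF-8
   byte order mark.
2. **Permute** each root into the exhaustive list of variant phrases, built
   combinatorially from four axes: conjunctions between names
   (`-`, ` `, `, `, ` and `, `, and `), possessive placement (none / final
   name / all names), the two possessive spellings for names ending in *s*
   (`s'`, `s's`), and prepositional inversion (*Term of Name*). For a root
   with *n* names this yields, beyond the standard form, 0 variants (*n* = 0),
   2–3 (*n* = 1), 9–15 (*n* = 2), or 14–32 (*n* = 3, opt-in pattern set) —
   the bundled 27-root gastrointestinal list expands to **116** search terms.
3. **Search** each phrase as an exact quoted phrase restricted to the
   Title/Abstract fields (`"Zenker Diverticulum"[Title/Abstract]`) against an
   Entrez E-utilities endpoint, with correct `retstart`/`retmax` pagination
   (≤ 100,000 ids per search request), chunked MEDLINE-format record fetches
   (≤ 10,000 ids per fetch), NCBI-polite rate limiting and retries — and
   **rejection of broadened queries**: any response carrying
   `QuotedPhraseNotFound` or a rewritten query translation contributes zero
   hits and is never fetched.
4. **Deduplicate and summarize**: citations matched by several variants of
   the same root are counted once per root (never merged across roots), and
   the deduplicated table is tallied by publication year and by journal.

Because live PubMed counts drift with the database's indexing date, the
package ships a deterministic **mock E-utilities responder**: a synthetic
corpus generator that plants exact phrase occurrences at configured
frequencies and answers search/fetch requests with the same semantics as the
live service, including the misleading broadening behaviour. Every pipeline
stage is tested end-to-end against it; the live transport (`Bio.Entrez`)
speaks the identical contract.

## Worked example

Generate a reproducible fixture (the curated 27-eponym gastrointestinal
list plus a 94-record synthetic corpus with planted phrase frequencies) and
run the full pipeline against it:

```bash
eponymsearch make-fixture --out-dir demo --seed 1
eponymsearch run --in demo/raw_eponyms.csv --out-dir demo/out \
    --endpoint mock --mock-corpus demo/corpus.medline
```

`demo/out/term_results.csv` holds one row per search phrase (here the first
rows; `valid` is `False` where the responder had to broaden the query, so
those phrases count zero):

```
root,term,variant_class,valid,hit_count
Escherichia coli,Escherichia coli,standard,False,0
Crohn Disease,Crohn Disease,standard,True,12
Crohn Disease,Crohn's Disease,possessive_final,False,0
Crohn Disease,Disease of Crohn,inversion,False,0
```

`demo/out/manifest.json` records the run parameters and totals:

```
"n_terms": 116, "n_valid_terms": 7, "n_hits": 44, "n_deduplicated_hits": 44
```

116 phrases were searched, the 7 planted phrases were found, and their 44
hits survive per-root deduplication (the demo plants are disjoint). The year
summary starts at 1876 — the corpus plants a single 1876 *Meckel
Diverticulum* citation in the *Journal of Anatomy and Physiology* — and
`summary_by_journal.csv` ranks journals by citation count:

```
year,citations          journal_title,citations
1876,1                  Annals of Surgery,10
1970,1                  Journal of Clinical Pathology,10
1980,1                  World Journal of Gastroenterology,9
```

For a live run, replace the endpoint options with
`--endpoint live --email you@example.org [--api-key KEY]`; results then
depend on the PubMed database state on the search date, which the manifest
records. The same stages are available individually (`standardize`,
`permute`, `search`, `dedup`, `summarize`) and as library functions
(`eponymsearch.permute_all`, `eponymsearch.search_term`,
`eponymsearch.run_pipeline`, …).

## Layout

| Module | Role |
| --- | --- |
| `eponymsearch.eponym_io` | CSV reading/writing, standardization rules |
| `eponymsearch.permuter` | variant grammar and permutation engine |
| `eponymsearch.entrez_client` | query building, pagination, validity, MEDLINE parsing, transports |
| `eponymsearch.results` | result tables, per-root dedup, year/journal summaries |
| `eponymsearch.mock_eutils` | synthetic corpus generator and mock responder |
| `eponymsearch.pipeline`, `eponymsearch.cli` | stage chaining, manifest, command line |

See `docs/methods.md` for the permutation grammar calibration, the mock
responder's model of PubMed semantics, and known limitations.
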