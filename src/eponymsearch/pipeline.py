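"""End-to-end pipeline: standardize -> permute -> search -> dedup -> summarize.

One call produces every artifact of an eponym usage study in an output
directory, together with a run manifest.  Phrase counts depend on the
state of the literature database on the day of the search, so the
manifest records the search date, endpoint and every parameter needed to
interpret (if live) or exactly reproduce (if mock) a run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

from . import __version__
from .entrez_client import (
    CitationRecord,
    EntrezTransport,
    PaginationPolicy,
    RateLimitedTransport,
    RateLimiter,
    Transport,
    fetch_records,
    search_term,
)
from .eponym_io import read_eponym_csv, standardize_all, write_standardized_csv
from .errors import ValidationError
from .mock_eutils import MockTransport, corpus_from_medline
from .permuter import DEFAULT_GRAMMAR, PermutationGrammar, permute_all, write_permuted_csv
from .results import (
    build_hit_rows,
    dedup_pmids,
    summarize_by_journal,
    summarize_by_year,
    write_pmid_results,
    write_term_results,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "STAGES"]

STAGES = ("standardize", "permute", "search", "dedup", "summarize")


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    ``endpoint`` is either "live" (requires ``email``) or "mock" (requires
    ``mock_corpus``, a MEDLINE flat file the responder indexes).
    """

    out_dir: Path
    endpoint: str = "mock"
    email: Optional[str] = None
    api_key: Optional[str] = None
    mock_corpus: Optional[Path] = None
    policy: PaginationPolicy = field(default_factory=PaginationPolicy)
    grammar: PermutationGrammar = field(default_factory=lambda: DEFAULT_GRAMMAR)
    db: str = "pubmed"
    stop_after: Optional[str] = None

    def __post_init__(self):
        if self.endpoint not in ("live", "mock"):
            raise ValidationError(f"unknown endpoint {self.endpoint!r}; use 'live' or 'mock'")
        if self.endpoint == "live" and not self.email:
            raise ValidationError("a contact email is required for the live endpoint")
        if self.endpoint == "mock" and self.mock_corpus is None:
            raise ValidationError("the mock endpoint requires a corpus MEDLINE file")
        if self.stop_after is not None and self.stop_after not in STAGES:
            raise ValidationError(f"unknown stage {self.stop_after!r}; one of {STAGES}")


def _make_transport(config: RunConfig) -> Transport:
    if config.endpoint == "mock":
        return MockTransport(corpus_from_medline(config.mock_corpus))
    live = EntrezTransport(email=config.email, api_key=config.api_key)
    rate = 10.0 if config.api_key else config.policy.requests_per_second
    return RateLimitedTransport(live, RateLimiter(rate))


def run_pipeline(
    config: RunConfig, raw_csv: str | Path, transport: Optional[Transport] = None
) -> Path:
    """Run the pipeline and return the output directory.

    Writes, in order: standardized.csv, permuted.csv, term_results.csv,
    pmid_results.csv, pmid_results.dedup.csv, summary_by_year.csv,
    summary_by_journal.csv and manifest.json.  ``config.stop_after``
    truncates the run after the named stage.  A ``transport`` argument
    overrides endpoint construction (used for in-memory corpora).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    started = datetime.now(timezone.utc)

    roots = standardize_all(read_eponym_csv(raw_csv))
    write_standardized_csv(roots, out / "standardized.csv")
    logger.info("standardized %d roots", len(roots))
    manifest = {
        "search_date": started.date().isoformat(),
        "started_utc": started.isoformat(),
        "package_version": __version__,
        "input": str(raw_csv),
        "endpoint": config.endpoint,
        "db": config.db,
        "esearch_page_cap": config.policy.esearch_page_cap,
        "efetch_chunk_cap": config.policy.efetch_chunk_cap,
        "requests_per_second": config.policy.requests_per_second,
        "n_roots": len(roots),
    }
    if config.stop_after == "standardize":
        return _finish(out, manifest)

    terms = permute_all(roots, config.grammar)
    write_permuted_csv(terms, out / "permuted.csv")
    manifest["n_terms"] = len(terms)
    logger.info("permuted into %d search terms", len(terms))
    if config.stop_after == "permute":
        return _finish(out, manifest)

    if transport is None:
        transport = _make_transport(config)
    results = []
    records: dict[str, CitationRecord] = {}
    for term in terms:
        res = search_term(term, config.policy, transport, db=config.db)
        logger.debug(
            "term %r: valid=%s hits=%d warnings=%s",
            term.text, res.valid, res.hit_count, list(res.warnings),
        )
        results.append(res)
        if res.valid and res.pmids:
            for rec in fetch_records(res.pmids, config.policy, transport, db=config.db):
                records[rec.pmid] = rec
    write_term_results(results, out / "term_results.csv")
    hit_rows = build_hit_rows(results, records)
    write_pmid_results(hit_rows, out / "pmid_results.csv")
    manifest["n_valid_terms"] = sum(1 for r in results if r.valid)
    manifest["n_hits"] = len(hit_rows)
    if config.stop_after == "search":
        return _finish(out, manifest)

    deduped = dedup_pmids(hit_rows)
    write_pmid_results(deduped, out / "pmid_results.dedup.csv")
    manifest["n_deduplicated_hits"] = len(deduped)
    if config.stop_after == "dedup":
        return _finish(out, manifest)

    summarize_by_year(deduped).to_csv(out / "summary_by_year.csv", index=False)
    summarize_by_journal(deduped).to_csv(out / "summary_by_journal.csv", index=False)
    return _finish(out, manifest)


def _finish(out: Path, manifest: dict) -> Path:
    with (out / "manifest.json").open("w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
    return out
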