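"""Exact-phrase Title/Abstract searching against an E-utilities endpoint.

The search contract mirrors NCBI's ESearch/EFetch parameter vocabulary
(``db``, ``term``, ``field``, ``retmax``, ``retstart``; id lists and
MEDLINE-format fetches) so the same client code runs against the live
service, recorded responses, or the in-process mock responder — the
transport is injected.

Two service behaviours drive the design:

* **Pagination/chunking.**  ESearch returns at most 100,000 PMIDs per
  request, EFetch details for at most 10,000 PMIDs; larger result sets are
  collected by incrementing ``retstart`` and by splitting the id list into
  chunks.
* **Silent query broadening.**  When a quoted phrase does not occur in the
  index, the service rewrites the query (dropping words) and returns hits
  for the rewritten query, flagged only by a ``QuotedPhraseNotFound``
  warning and a mismatching query translation.  Such results are spurious
  for phrase counting — a query like ``"Mallory-Weiss' Tear"[Title/Abstract]``
  silently becomes ``Tear[Title/Abstract]`` — and are discarded wholesale:
  an invalid query contributes zero hits and triggers no record fetch.
"""

from __future__ import annotations

import logging
import re
import time
from collections import deque
from dataclasses import dataclass
from io import StringIO
from typing import Callable, Optional, Protocol, Sequence

from Bio import Medline

from .errors import (
    IntegrityError,
    MedlineParseError,
    TransientFailureError,
    TransportFailure,
    ValidationError,
)
from .permuter import SearchTerm

logger = logging.getLogger(__name__)

__all__ = [
    "QUOTED_PHRASE_NOT_FOUND",
    "TITLE_ABSTRACT_FIELD",
    "PaginationPolicy",
    "SearchResponse",
    "Transport",
    "QueryResult",
    "CitationRecord",
    "RateLimiter",
    "RateLimitedTransport",
    "EntrezTransport",
    "build_query",
    "paged_search",
    "assess_validity",
    "parse_medline",
    "extract_year",
    "fetch_records",
    "search_term",
]

QUOTED_PHRASE_NOT_FOUND = "QuotedPhraseNotFound"
TITLE_ABSTRACT_FIELD = "[Title/Abstract]"


@dataclass(frozen=True)
class PaginationPolicy:
    """Service limits and client etiquette for one search run.

    ``esearch_page_cap`` is the ``retmax`` used per search request (service
    maximum 100,000); ``efetch_chunk_cap`` the id-list chunk size per fetch
    (service maximum 10,000).  ``requests_per_second`` follows NCBI usage
    policy: 3 without an API key, 10 with one.  Transport-level failures
    are retried ``max_retries`` times with exponential backoff starting at
    ``backoff_base`` seconds; a well-formed response carrying warnings is a
    semantic outcome, never retried.
    """

    esearch_page_cap: int = 100_000
    efetch_chunk_cap: int = 10_000
    requests_per_second: float = 3.0
    max_retries: int = 3
    backoff_base: float = 1.0

    def __post_init__(self):
        if not 1 <= self.esearch_page_cap <= 100_000:
            raise ValidationError("esearch_page_cap must be in [1, 100000]")
        if not 1 <= self.efetch_chunk_cap <= 10_000:
            raise ValidationError("efetch_chunk_cap must be in [1, 10000]")
        if self.max_retries < 1:
            raise ValidationError("max_retries must be >= 1")


@dataclass(frozen=True)
class SearchResponse:
    """Structured ESearch reply: total count, one id page, translation, warnings."""

    count: int
    ids: tuple[str, ...]
    query_translation: str
    warnings: tuple[str, ...] = ()


class Transport(Protocol):
    """Injectable endpoint contract mirroring ESearch/EFetch."""

    def esearch(
        self, *, db: str, term: str, retmax: int, retstart: int, field: Optional[str] = None
    ) -> SearchResponse: ...

    def efetch(self, *, db: str, ids: Sequence[str], rettype: str, retmode: str) -> str: ...


@dataclass(frozen=True)
class QueryResult:
    """Outcome of searching one permuted phrase."""

    term: SearchTerm
    requested_query: str
    hit_count: int
    pmids: tuple[str, ...]
    query_translation: str
    warnings: tuple[str, ...]
    valid: bool


@dataclass(frozen=True)
class CitationRecord:
    """The fields kept from one MEDLINE citation: PMID, journal (JT), date (DP)."""

    pmid: str
    journal_title: str
    pub_date_raw: str
    year: Optional[int] = None


class RateLimiter:
    """Sliding-window limiter: at most ``rate`` acquisitions per second.

    Clock and sleeper are injectable so the limiting law can be tested with
    a virtual clock.
    """

    def __init__(
        self,
        rate: float,
        clock: Callable[[], float] = time.monotonic,
        sleep: Callable[[float], None] = time.sleep,
    ):
        if rate <= 0:
            raise ValidationError("rate must be positive")
        self.rate = rate
        self._clock = clock
        self._sleep = sleep
        self._stamps: deque[float] = deque()

    def acquire(self) -> None:
        window = 1.0
        while True:
            now = self._clock()
            while self._stamps and now - self._stamps[0] >= window:
                self._stamps.popleft()
            if len(self._stamps) < self.rate:
                self._stamps.append(now)
                return
            self._sleep(self._stamps[0] + window - now)


class RateLimitedTransport:
    """Wrap any transport so every call first passes the rate limiter."""

    def __init__(self, inner: Transport, limiter: RateLimiter):
        self._inner = inner
        self._limiter = limiter

    def esearch(self, **kwargs) -> SearchResponse:
        self._limiter.acquire()
        return self._inner.esearch(**kwargs)

    def efetch(self, **kwargs) -> str:
        self._limiter.acquire()
        return self._inner.efetch(**kwargs)


class EntrezTransport:
    """Live NCBI transport via Bio.Entrez.

    Requires a contact email per E-utilities etiquette; an API key raises
    the permitted request rate.  Never used by the test suite, which runs
    against the in-process mock responder.
    """

    def __init__(self, email: str, api_key: Optional[str] = None):
        if not email:
            raise ValidationError("a contact email is required for live Entrez use")
        from Bio import Entrez

        self._entrez = Entrez
        Entrez.email = email
        if api_key:
            Entrez.api_key = api_key

    def esearch(self, *, db, term, retmax, retstart, field=None) -> SearchResponse:
        try:
            kwargs = dict(db=db, term=term, retmax=retmax, retstart=retstart)
            if field:
                kwargs["field"] = field
            with self._entrez.esearch(**kwargs) as handle:
                data = self._entrez.read(handle)
        except OSError as exc:
            raise TransportFailure(f"esearch failed: {exc}") from exc
        warnings = []
        warning_list = data.get("WarningList", {})
        for code, messages in warning_list.items():
            if messages:
                warnings.append(code)
        return SearchResponse(
            count=int(data["Count"]),
            ids=tuple(data.get("IdList", [])),
            query_translation=str(data.get("QueryTranslation", "")),
            warnings=tuple(warnings),
        )

    def efetch(self, *, db, ids, rettype, retmode) -> str:
        try:
            with self._entrez.efetch(
                db=db, id=",".join(ids), rettype=rettype, retmode=retmode
            ) as handle:
                return handle.read()
        except OSError as exc:
            raise TransportFailure(f"efetch failed: {exc}") from exc


def build_query(term_text: str) -> str:
    """Wrap a phrase in quotes with the Title/Abstract field qualifier."""
    if not term_text:
        raise ValidationError("cannot build a query from an empty phrase")
    if '"' in term_text:
        raise ValidationError(f"phrase {term_text!r} contains an embedded double quote")
    return f'"{term_text}"{TITLE_ABSTRACT_FIELD}'


def _with_retries(call, policy: PaginationPolicy, sleep, at_offset, **kwargs):
    last_exc: Optional[TransportFailure] = None
    for attempt in range(policy.max_retries):
        try:
            return call(**kwargs)
        except TransportFailure as exc:
            last_exc = exc
            if attempt < policy.max_retries - 1:
                delay = policy.backoff_base * (2**attempt)
                logger.debug("transport failure (%s); retrying in %.1fs", exc, delay)
                sleep(delay)
    raise TransientFailureError(
        f"transport failed after {policy.max_retries} attempts: {last_exc}", retstart=at_offset
    )


def paged_search(
    query: str,
    policy: PaginationPolicy,
    transport: Transport,
    *,
    db: str = "pubmed",
    sleep: Callable[[float], None] = time.sleep,
) -> tuple[int, tuple[str, ...], str, tuple[str, ...]]:
    """Collect the complete PMID list for one query, page by page.

    Issues ``max(1, ceil(total / esearch_page_cap))`` search calls with
    ``retstart`` = 0, cap, 2·cap, ...  The count and query translation must
    be consistent across pages and the concatenated ids duplicate-free,
    else an :class:`IntegrityError` is raised.  Paging stops after the
    first page when the service reports ``QuotedPhraseNotFound`` — the
    broadened results would be discarded anyway.
    """
    cap = policy.esearch_page_cap
    first = _with_retries(
        transport.esearch, policy, sleep, 0,
        db=db, term=query, retmax=cap, retstart=0,
    )
    total = first.count
    translation = first.query_translation
    warnings = list(first.warnings)
    pmids: list[str] = list(first.ids)

    if QUOTED_PHRASE_NOT_FOUND not in warnings:
        retstart = cap
        while retstart < total:
            page = _with_retries(
                transport.esearch, policy, sleep, retstart,
                db=db, term=query, retmax=cap, retstart=retstart,
            )
            if page.count != total:
                raise IntegrityError(
                    f"result count changed mid-query ({total} -> {page.count}) at "
                    f"retstart={retstart} for {query!r}"
                )
            if page.query_translation != translation:
                raise IntegrityError(
                    f"query translation changed across pages for {query!r}"
                )
            for w in page.warnings:
                if w not in warnings:
                    warnings.append(w)
            pmids.extend(page.ids)
            retstart += cap
        if len(set(pmids)) != len(pmids):
            raise IntegrityError(f"duplicate PMIDs across pages for {query!r}")

    return total, tuple(pmids), translation, tuple(warnings)


def _normalize_query(text: str) -> str:
    return " ".join(text.split()).casefold()


def assess_validity(
    requested_query: str, query_translation: str, warnings: Sequence[str]
) -> bool:
    """Decide whether a response answers the query that was actually asked.

    False when the service warned ``QuotedPhraseNotFound`` or when the
    translation differs from the request beyond letter case and whitespace
    — either signals silent broadening.
    """
    if QUOTED_PHRASE_NOT_FOUND in warnings:
        return False
    return _normalize_query(query_translation) == _normalize_query(requested_query)


_YEAR_RE = re.compile(r"\b(\d{4})\b")


def extract_year(pub_date_raw: str) -> Optional[int]:
    """Publication year = first 4-digit token of the MEDLINE DP value.

    DP dialects include "1996", "1996 Jan", "1996 Jan-Feb" and
    "1996-1997"; the first year is the publication year.
    """
    m = _YEAR_RE.search(pub_date_raw or "")
    return int(m.group(1)) if m else None


def parse_medline(text: str) -> list[CitationRecord]:
    """Parse MEDLINE flat-file text into citation records.

    Keeps PMID, journal title (JT) and publication date (DP); continuation
    lines are joined with single spaces; unknown tags are ignored.  A
    record without a PMID is malformed.
    """
    if not text.strip():
        return []
    records = []
    for rec in Medline.parse(StringIO(text)):
        pmid = rec.get("PMID")
        if not pmid:
            first_line = next(iter(rec.values()), "")
            if isinstance(first_line, list):
                first_line = first_line[0] if first_line else ""
            raise MedlineParseError(f"MEDLINE record without PMID (starts: {first_line!r})")
        dp = rec.get("DP", "")
        records.append(
            CitationRecord(
                pmid=str(pmid),
                journal_title=rec.get("JT", ""),
                pub_date_raw=dp,
                year=extract_year(dp),
            )
        )
    return records


def fetch_records(
    pmids: Sequence[str],
    policy: PaginationPolicy,
    transport: Transport,
    *,
    db: str = "pubmed",
    sleep: Callable[[float], None] = time.sleep,
) -> list[CitationRecord]:
    """Fetch citation details for an id list, in chunks, preserving order.

    Issues ``ceil(len(pmids) / efetch_chunk_cap)`` fetch calls.  A PMID the
    service does not return is logged and skipped.
    """
    if not pmids:
        raise ValidationError("fetch_records requires a non-empty PMID list")
    cap = policy.efetch_chunk_cap
    by_pmid: dict[str, CitationRecord] = {}
    for start in range(0, len(pmids), cap):
        chunk = list(pmids[start : start + cap])
        text = _with_retries(
            transport.efetch, policy, sleep, start,
            db=db, ids=chunk, rettype="medline", retmode="text",
        )
        for rec in parse_medline(text):
            by_pmid[rec.pmid] = rec
    out: list[CitationRecord] = []
    for pmid in pmids:
        rec = by_pmid.get(str(pmid))
        if rec is None:
            logger.warning("PMID %s requested but absent from fetch response; skipped", pmid)
            continue
        out.append(rec)
    return out


def search_term(
    term: SearchTerm,
    policy: PaginationPolicy,
    transport: Transport,
    *,
    db: str = "pubmed",
    sleep: Callable[[float], None] = time.sleep,
) -> QueryResult:
    """Search one permuted phrase and judge the response's validity.

    Composes query building, paged searching and validity assessment.  An
    invalid (broadened) query is recorded with zero hits and an empty id
    list so it can never contribute citations downstream.
    """
    query = build_query(term.text)
    total, pmids, translation, warnings = paged_search(
        query, policy, transport, db=db, sleep=sleep
    )
    valid = assess_validity(query, translation, warnings)
    logger.debug(
        "searched %r: count=%d valid=%s warnings=%s", query, total, valid, list(warnings)
    )
    if not valid:
        return QueryResult(
            term=term, requested_query=query, hit_count=0, pmids=(),
            query_translation=translation, warnings=warnings, valid=False,
        )
    return QueryResult(
        term=term, requested_query=query, hit_count=total, pmids=pmids,
        query_translation=translation, warnings=warnings, valid=True,
    )
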