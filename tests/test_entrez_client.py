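"""Search client: query building, pagination laws, broadening rejection, MEDLINE."""

import math

import pytest

from eponymsearch.entrez_client import (
    PaginationPolicy,
    RateLimitedTransport,
    RateLimiter,
    SearchResponse,
    assess_validity,
    build_query,
    extract_year,
    fetch_records,
    paged_search,
    parse_medline,
    search_term,
)
from eponymsearch.errors import (
    IntegrityError,
    MedlineParseError,
    TransientFailureError,
    TransportFailure,
    ValidationError,
)
from eponymsearch.mock_eutils import MockTransport, PlantSpec, generate_corpus
from eponymsearch.permuter import SearchTerm


def _policy(page_cap=100_000, chunk_cap=10_000, retries=3):
    return PaginationPolicy(
        esearch_page_cap=page_cap, efetch_chunk_cap=chunk_cap, max_retries=retries,
        backoff_base=0.01,
    )


@pytest.fixture(scope="module")
def corpus():
    return generate_corpus(
        [
            PlantSpec("Zenker Diverticulum", n_title=5, n_abstract=2),
            PlantSpec("Mallory Weiss Tear", n_title=3, n_abstract=4),
        ],
        n_background=20,
        seed=7,
    )


class TestBuildQuery:
    def test_wraps_and_qualifies(self):
        assert build_query("Zenker Diverticulum") == '"Zenker Diverticulum"[Title/Abstract]'
        assert build_query("Diverticulum of Zenker") == '"Diverticulum of Zenker"[Title/Abstract]'

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            build_query("")

    def test_embedded_quote_rejected(self):
        with pytest.raises(ValidationError):
            build_query('Zenker "Diverticulum"')


class TestAssessValidity:
    def test_broadened_query_is_invalid(self):
        assert not assess_validity(
            '"Mallory-Weiss\' Tear"[Title/Abstract]',
            "Tear[Title/Abstract]",
            ["QuotedPhraseNotFound"],
        )

    def test_echoed_translation_is_valid(self):
        q = '"Zenker Diverticulum"[Title/Abstract]'
        assert assess_validity(q, q, [])

    def test_case_and_spacing_differences_are_benign(self):
        assert assess_validity(
            '"Zenker Diverticulum"[Title/Abstract]',
            '"zenker  diverticulum"[title/abstract]',
            [],
        )

    def test_silent_translation_change_is_invalid(self):
        assert not assess_validity(
            '"Zenker Diverticulum"[Title/Abstract]', "Diverticulum[Title/Abstract]", []
        )


class TestPagedSearch:
    @pytest.mark.parametrize("cap", [1, 2, 7, 50])
    def test_union_of_pages_is_complete_and_duplicate_free(self, corpus, cap):
        transport = MockTransport(corpus)
        total, pmids, _, warnings = paged_search(
            '"Zenker Diverticulum"[Title/Abstract]', _policy(page_cap=cap), transport
        )
        assert total == 7 and len(pmids) == 7
        assert len(set(pmids)) == 7
        assert list(pmids) == sorted(pmids, key=int)
        assert not warnings

    @pytest.mark.parametrize("cap, expected_calls", [(1, 7), (2, 4), (7, 1), (50, 1)])
    def test_search_call_count_law(self, corpus, cap, expected_calls):
        transport = MockTransport(corpus)
        paged_search('"Zenker Diverticulum"[Title/Abstract]', _policy(page_cap=cap), transport)
        assert len(transport.search_calls) == expected_calls == max(1, math.ceil(7 / cap))
        assert [c["retstart"] for c in transport.search_calls] == [
            i * cap for i in range(expected_calls)
        ]

    def test_zero_matches_single_call(self, corpus):
        transport = MockTransport(corpus)
        total, pmids, _, warnings = paged_search(
            '"Rokitansky Aschoff Sinuses"[Title/Abstract]', _policy(page_cap=5), transport
        )
        # absent phrase: broadened response, but only one search call is made
        assert len(transport.search_calls) == 1
        assert "QuotedPhraseNotFound" in warnings

    def test_exactly_cap_matches_single_call(self, corpus):
        transport = MockTransport(corpus)
        paged_search('"Zenker Diverticulum"[Title/Abstract]', _policy(page_cap=7), transport)
        assert len(transport.search_calls) == 1

    def test_inconsistent_total_raises_integrity_error(self, corpus):
        class Drifting(MockTransport):
            def esearch(self, **kw):
                resp = super().esearch(**kw)
                if kw["retstart"] > 0:
                    return SearchResponse(resp.count + 1, resp.ids,
                                          resp.query_translation, resp.warnings)
                return resp

        with pytest.raises(IntegrityError):
            paged_search(
                '"Zenker Diverticulum"[Title/Abstract]', _policy(page_cap=2), Drifting(corpus)
            )


class TestRetries:
    class Flaky:
        """Fails the first k esearch calls, then delegates to the mock."""

        def __init__(self, corpus, failures):
            self._inner = MockTransport(corpus)
            self._failures = failures
            self.attempts = 0

        def esearch(self, **kw):
            self.attempts += 1
            if self.attempts <= self._failures:
                raise TransportFailure("connection reset")
            return self._inner.esearch(**kw)

        def efetch(self, **kw):
            return self._inner.efetch(**kw)

    def test_recovers_after_transient_failures_with_backoff(self, corpus):
        transport = self.Flaky(corpus, failures=2)
        sleeps = []
        total, pmids, _, _ = paged_search(
            '"Zenker Diverticulum"[Title/Abstract]', _policy(), transport,
            sleep=sleeps.append,
        )
        assert total == 7 and len(pmids) == 7
        assert sleeps == [0.01, 0.02]  # exponential backoff

    def test_exhausted_retries_raise_with_offset(self, corpus):
        transport = self.Flaky(corpus, failures=99)
        with pytest.raises(TransientFailureError) as exc_info:
            paged_search(
                '"Zenker Diverticulum"[Title/Abstract]', _policy(), transport,
                sleep=lambda _: None,
            )
        assert exc_info.value.retstart == 0
        assert transport.attempts == 3


class TestFetchRecords:
    @pytest.mark.parametrize("chunk_cap, expected_calls", [(1, 7), (2, 4), (7, 1), (50, 1)])
    def test_chunk_call_count_law(self, corpus, chunk_cap, expected_calls):
        transport = MockTransport(corpus)
        _, pmids, _, _ = paged_search(
            '"Zenker Diverticulum"[Title/Abstract]', _policy(), transport
        )
        records = fetch_records(pmids, _policy(chunk_cap=chunk_cap), transport)
        assert len(transport.fetch_calls) == expected_calls == math.ceil(len(pmids) / chunk_cap)
        assert [r.pmid for r in records] == list(pmids)

    def test_missing_pmid_skipped_not_fatal(self, corpus):
        transport = MockTransport(corpus)
        real = corpus[0].pmid
        records = fetch_records([real, "999999999"], _policy(), transport)
        assert [r.pmid for r in records] == [real]

    def test_empty_list_rejected(self, corpus):
        with pytest.raises(ValidationError):
            fetch_records([], _policy(), MockTransport(corpus))


class TestParseMedline:
    def test_basic_record(self):
        records = parse_medline("PMID- 123\nJT  - Gut\nDP  - 1996 Jan\n")
        assert len(records) == 1
        rec = records[0]
        assert (rec.pmid, rec.journal_title, rec.pub_date_raw, rec.year) == (
            "123", "Gut", "1996 Jan", 1996,
        )

    def test_continuation_lines_joined(self):
        text = (
            "PMID- 77\n"
            "JT  - Journal of Anatomy and\n"
            "      Physiology\n"
            "DP  - 1876\n"
        )
        (rec,) = parse_medline(text)
        assert rec.journal_title == "Journal of Anatomy and Physiology"
        assert rec.year == 1876

    def test_empty_input(self):
        assert parse_medline("") == []

    def test_record_without_pmid_is_malformed(self):
        with pytest.raises(MedlineParseError):
            parse_medline("JT  - Gut\nDP  - 1996\n")

    @pytest.mark.parametrize(
        "dp, year",
        [("1996", 1996), ("1996 Jan", 1996), ("1996 Jan-Feb", 1996),
         ("1996-1997", 1996), ("Spring 2001", 2001), ("n.d.", None), ("", None)],
    )
    def test_year_extraction_dialects(self, dp, year):
        assert extract_year(dp) == year


class TestSearchTerm:
    def test_planted_count_recovered(self, corpus):
        transport = MockTransport(corpus)
        term = SearchTerm("Zenker Diverticulum", "Zenker Diverticulum", "standard")
        result = search_term(term, _policy(), transport)
        assert result.valid
        assert result.hit_count == 7 == len(result.pmids)

    def test_absent_phrase_invalid_and_empty(self, corpus):
        transport = MockTransport(corpus)
        term = SearchTerm("Mallory-Weiss Tear", "Mallory-Weiss' Tear", "possessive_final")
        result = search_term(term, _policy(), transport)
        assert not result.valid
        assert result.hit_count == 0 and result.pmids == ()
        assert "QuotedPhraseNotFound" in result.warnings
        # the broadened translation betrays the rewrite
        assert result.query_translation == "Tear[Title/Abstract]"

    def test_invalid_query_triggers_no_fetch(self, corpus):
        transport = MockTransport(corpus)
        term = SearchTerm("Mallory-Weiss Tear", "Mallory-Weiss' Tear", "possessive_final")
        result = search_term(term, _policy(), transport)
        if result.valid and result.pmids:  # pragma: no cover - guarded composition
            fetch_records(result.pmids, _policy(), transport)
        assert transport.fetch_calls == []


class TestRateLimiter:
    def test_sliding_window_law(self):
        """With rate 3/s, no sliding second ever sees more than 3 acquisitions."""
        clock = {"t": 0.0}
        sleeps = []

        def fake_sleep(dt):
            sleeps.append(dt)
            clock["t"] += dt

        limiter = RateLimiter(3, clock=lambda: clock["t"], sleep=fake_sleep)
        stamps = []
        for _ in range(10):
            limiter.acquire()
            stamps.append(clock["t"])
        for i, t in enumerate(stamps):
            in_window = [s for s in stamps if t - 1.0 < s <= t]
            assert len(in_window) <= 3
        assert sleeps  # the limiter actually had to wait

    def test_wrapped_transport_is_limited(self, corpus):
        clock = {"t": 0.0}

        def fake_sleep(dt):
            clock["t"] += dt

        limiter = RateLimiter(2, clock=lambda: clock["t"], sleep=fake_sleep)
        transport = RateLimitedTransport(MockTransport(corpus), limiter)
        for _ in range(5):
            transport.esearch(
                db="pubmed", term='"Zenker Diverticulum"[Title/Abstract]',
                retmax=10, retstart=0,
            )
        # 5 calls at 2/s need at least 2 virtual seconds
        assert clock["t"] >= 2.0 - 1e-9
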