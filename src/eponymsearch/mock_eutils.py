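"""Deterministic synthetic corpus and in-process E-utilities responder.

Live phrase counts drift with the database's indexing date, so the test
suite and worked examples run against a synthetic corpus with *planted*
phrase occurrences: each :class:`PlantSpec` asks for an exact number of
records carrying one phrase verbatim in the title or abstract, embedded in
filler text that provably cannot contain any planted phrase (the filler
vocabulary excludes every word of every planted phrase).  The responder
then implements the ESearch/EFetch semantics the client depends on:

* exact-phrase, case-insensitive Title/Abstract matching with
  ``retmax``/``retstart`` pagination, ids ascending;
* the live service's misleading broadening behaviour — an absent quoted
  phrase yields a ``QuotedPhraseNotFound`` warning, a translation reduced
  to the phrase's last word, and hits for that word instead;
* MEDLINE flat-file rendering with 6-space continuation wrapping.

Because every planted count is known by construction, end-to-end pipeline
runs can be checked for exact count recovery.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .entrez_client import SearchResponse, TITLE_ABSTRACT_FIELD
from .errors import AmbiguityError, ValidationError

__all__ = [
    "CorpusRecord",
    "PlantSpec",
    "generate_corpus",
    "render_medline",
    "corpus_from_medline",
    "MockResponder",
    "MockTransport",
    "default_demo_plants",
]


@dataclass(frozen=True)
class CorpusRecord:
    """One synthetic document the responder indexes."""

    pmid: str
    title: str
    abstract: str
    journal_title: str
    pub_date_raw: str


@dataclass(frozen=True)
class PlantSpec:
    """A phrase to plant: how many titles/abstracts carry it, dated how.

    ``year_distribution`` maps publication year to sampling weight; when
    omitted, years are drawn uniformly from 1990–2020.  An optional
    per-plant ``seed`` decouples this plant's text from the global stream.
    """

    phrase: str
    n_title: int = 0
    n_abstract: int = 0
    year_distribution: Optional[Mapping[int, float]] = None
    journal: Optional[str] = None
    seed: Optional[int] = None

    def __post_init__(self):
        if not self.phrase.strip():
            raise ValidationError("planted phrase must be non-empty")
        if self.n_title < 0 or self.n_abstract < 0:
            raise ValidationError("plant counts must be non-negative")
        if self.year_distribution is not None:
            weights = list(self.year_distribution.values())
            if any(w < 0 for w in weights):
                raise ValidationError("year weights must be non-negative")
            if (self.n_title + self.n_abstract) > 0 and not any(weights):
                raise ValidationError("year weights must not all be zero")


# Generic methods-section vocabulary; surnames never appear here, and any
# word that occurs in a planted phrase is removed before filler is drawn.
_FILLER_VOCABULARY = (
    "retrospective cohort analysis evaluated outcome measures among enrolled "
    "participants baseline characteristics were recorded including demographic "
    "clinical laboratory variables statistical comparison used regression models "
    "adjusted confounders primary endpoint assessed during followup secondary "
    "endpoints included readmission complication mortality rates findings suggest "
    "further prospective evaluation warranted limitations include sample selection "
    "referral bias single center design results generalizable larger populations "
    "imaging endoscopic histologic assessment performed blinded reviewers"
).split()

_JOURNALS = (
    "Gut",
    "Gastroenterology",
    "World Journal of Gastroenterology",
    "Digestive Diseases and Sciences",
    "Journal of Clinical Pathology",
    "Annals of Surgery",
)

_MONTH_FMT = ("{y}", "{y} Jan", "{y} Mar", "{y} Jul-Aug", "{y} Dec")


def _norm(text: str) -> str:
    return " ".join(text.split()).casefold()


def _phrase_pattern(phrase: str) -> re.Pattern:
    # word-boundary-anchored so a phrase never matches inside a longer word
    return re.compile(r"(?<!\w)" + re.escape(_norm(phrase)) + r"(?!\w)")


def phrase_occurs(phrase: str, text: str) -> bool:
    """Exact-phrase containment on whitespace-normalized, casefolded text."""
    return bool(_phrase_pattern(phrase).search(_norm(text)))


def _filler(rng: random.Random, vocab: Sequence[str], n_words: int) -> str:
    return " ".join(rng.choice(vocab) for _ in range(n_words))


def _sample_year(rng: random.Random, dist: Optional[Mapping[int, float]]) -> int:
    if dist:
        years = sorted(dist)
        return rng.choices(years, weights=[dist[y] for y in years], k=1)[0]
    return rng.randint(1990, 2020)


def _date_for(rng: random.Random, year: int) -> str:
    return rng.choice(_MONTH_FMT).format(y=year)


def generate_corpus(
    plants: Sequence[PlantSpec],
    n_background: int,
    seed: int,
    *,
    start_pmid: int = 10_000_001,
) -> list[CorpusRecord]:
    """Build a reproducible corpus with exact planted phrase frequencies.

    For each plant, exactly ``n_title`` records carry the phrase in the
    title and ``n_abstract`` in the abstract; ``n_background`` additional
    records match no planted phrase.  Identical arguments always produce an
    identical corpus.  Planted phrases must be pairwise substring-free
    (after whitespace/case normalization) so counts stay unambiguous.
    """
    normed = [_norm(p.phrase) for p in plants]
    for i, a in enumerate(normed):
        for j, b in enumerate(normed):
            if i != j and a in b:
                raise AmbiguityError(
                    f"planted phrase {plants[i].phrase!r} is a substring of "
                    f"{plants[j].phrase!r}; plants must be disjoint"
                )

    banned = {w for p in plants for w in _norm(p.phrase).split()}
    vocab = [w for w in _FILLER_VOCABULARY if w not in banned]
    if len(vocab) < 10:
        raise ValidationError("planted phrases exhaust the filler vocabulary")

    master = random.Random(seed)
    records: list[CorpusRecord] = []
    pmid = start_pmid

    for idx, plant in enumerate(plants):
        rng = random.Random(plant.seed if plant.seed is not None else master.randrange(2**31))
        for kind in ("title", "abstract"):
            count = plant.n_title if kind == "title" else plant.n_abstract
            for _ in range(count):
                year = _sample_year(rng, plant.year_distribution)
                journal = plant.journal or rng.choice(_JOURNALS)
                lead = _filler(rng, vocab, rng.randint(2, 5))
                tail = _filler(rng, vocab, rng.randint(2, 5))
                plain_title = _filler(rng, vocab, rng.randint(5, 9))
                plain_abstract = _filler(rng, vocab, rng.randint(15, 30))
                if kind == "title":
                    title = f"{lead} {plant.phrase} {tail}"
                    abstract = plain_abstract
                else:
                    title = plain_title
                    abstract = f"{lead} {plant.phrase} {tail}"
                records.append(
                    CorpusRecord(
                        pmid=str(pmid),
                        title=title,
                        abstract=abstract,
                        journal_title=journal,
                        pub_date_raw=_date_for(rng, year),
                    )
                )
                pmid += 1

    bg_rng = random.Random(master.randrange(2**31))
    for _ in range(n_background):
        year = bg_rng.randint(1990, 2020)
        records.append(
            CorpusRecord(
                pmid=str(pmid),
                title=_filler(bg_rng, vocab, bg_rng.randint(5, 9)),
                abstract=_filler(bg_rng, vocab, bg_rng.randint(15, 30)),
                journal_title=bg_rng.choice(_JOURNALS),
                pub_date_raw=_date_for(bg_rng, year),
            )
        )
        pmid += 1

    return records


_WRAP_COLUMN = 80


def _render_field(tag: str, value: str) -> list[str]:
    """Render one MEDLINE field with 6-space continuation wrapping."""
    prefix = f"{tag:<4}- "
    words = value.split()
    if not words:
        return [prefix.rstrip() + " "]
    lines: list[str] = []
    current = prefix
    for word in words:
        candidate = word if current in (prefix, "      ") else " " + word
        if len(current) + len(candidate) > _WRAP_COLUMN and current not in (prefix, "      "):
            lines.append(current)
            current = "      " + word
        else:
            current += candidate
    lines.append(current)
    return lines


def render_medline(records: Sequence[CorpusRecord]) -> str:
    """Render corpus records as MEDLINE flat-file text (NLM tag dialect)."""
    blocks = []
    for rec in records:
        lines: list[str] = []
        lines.extend(_render_field("PMID", rec.pmid))
        lines.extend(_render_field("TI", rec.title))
        if rec.abstract:
            lines.extend(_render_field("AB", rec.abstract))
        lines.extend(_render_field("JT", rec.journal_title))
        lines.extend(_render_field("DP", rec.pub_date_raw))
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + ("\n" if blocks else "")


def corpus_from_medline(path) -> list[CorpusRecord]:
    """Load a corpus back from its MEDLINE flat-file serialization."""
    from pathlib import Path

    from Bio import Medline

    from .errors import InputError

    path = Path(path)
    if not path.is_file():
        raise InputError(f"corpus MEDLINE file not found: {path}")
    with path.open(encoding="utf-8") as fh:
        return [
            CorpusRecord(
                pmid=str(rec["PMID"]),
                title=rec.get("TI", ""),
                abstract=rec.get("AB", ""),
                journal_title=rec.get("JT", ""),
                pub_date_raw=rec.get("DP", ""),
            )
            for rec in Medline.parse(fh)
            if rec.get("PMID")
        ]


_QUERY_RE = re.compile(r'^"(?P<phrase>.+)"\[Title/Abstract\]$', re.IGNORECASE)


class MockResponder:
    """In-process E-utilities responder over a fixed corpus."""

    def __init__(self, corpus: Sequence[CorpusRecord]):
        pmids = [r.pmid for r in corpus]
        if len(set(pmids)) != len(pmids):
            raise ValidationError("corpus PMIDs must be unique")
        self.corpus = list(corpus)
        self._by_pmid = {r.pmid: r for r in self.corpus}

    def _matching_pmids(self, pattern: re.Pattern) -> list[str]:
        hits = [
            r.pmid
            for r in self.corpus
            if pattern.search(_norm(r.title)) or pattern.search(_norm(r.abstract))
        ]
        return sorted(hits, key=int)

    def respond_search(self, query: str, retmax: int, retstart: int) -> SearchResponse:
        """ESearch semantics: exact phrase, or warned broadening to the last word."""
        m = _QUERY_RE.match(query.strip())
        if m is None:
            raise ValidationError(f"malformed query {query!r}; expected a quoted "
                                  f"phrase with {TITLE_ABSTRACT_FIELD}")
        phrase = m.group("phrase")
        exact = self._matching_pmids(_phrase_pattern(phrase))
        if exact:
            return SearchResponse(
                count=len(exact),
                ids=tuple(exact[retstart : retstart + retmax]),
                query_translation=query.strip(),
                warnings=(),
            )
        last_word = phrase.split()[-1].strip("'\",.;:")
        broadened = self._matching_pmids(_phrase_pattern(last_word)) if last_word else []
        return SearchResponse(
            count=len(broadened),
            ids=tuple(broadened[retstart : retstart + retmax]),
            query_translation=f"{last_word}{TITLE_ABSTRACT_FIELD}",
            warnings=("QuotedPhraseNotFound",),
        )

    def respond_fetch(self, pmids: Sequence[str]) -> str:
        """EFetch semantics: MEDLINE text, unknown ids silently omitted."""
        known = [self._by_pmid[p] for p in pmids if p in self._by_pmid]
        return render_medline(known)


class MockTransport:
    """Adapter exposing a :class:`MockResponder` through the transport contract.

    Records every call (for call-count and pagination-law assertions).
    """

    def __init__(self, corpus: Sequence[CorpusRecord]):
        self.responder = MockResponder(corpus)
        self.search_calls: list[dict] = []
        self.fetch_calls: list[dict] = []

    def esearch(self, *, db, term, retmax, retstart, field=None) -> SearchResponse:
        self.search_calls.append(
            {"db": db, "term": term, "retmax": retmax, "retstart": retstart}
        )
        return self.responder.respond_search(term, retmax=retmax, retstart=retstart)

    def efetch(self, *, db, ids, rettype, retmode) -> str:
        self.fetch_calls.append({"db": db, "ids": list(ids), "rettype": rettype})
        return self.responder.respond_fetch(ids)


def default_demo_plants() -> list[PlantSpec]:
    """Plants for the worked example: a paper-shaped gastrointestinal corpus.

    Includes the canonical 1876 Meckel Diverticulum citation in the Journal
    of Anatomy and Physiology, so the demo year summary starts at 1876.
    """
    return [
        PlantSpec("Zenker Diverticulum", n_title=4, n_abstract=3,
                  year_distribution={1995: 1, 2005: 2, 2015: 2}),
        PlantSpec("Zenker's Diverticulum", n_title=6, n_abstract=4,
                  year_distribution={2000: 1, 2010: 2, 2019: 2}),
        PlantSpec("Diverticulum of Zenker", n_title=1, n_abstract=0,
                  year_distribution={1988: 1}),
        PlantSpec("Mallory-Weiss Tear", n_title=3, n_abstract=2,
                  year_distribution={1999: 1, 2012: 1}),
        PlantSpec("Meckel Diverticulum", n_title=1, n_abstract=0,
                  year_distribution={1876: 1},
                  journal="Journal of Anatomy and Physiology"),
        PlantSpec("Chagas Disease", n_title=5, n_abstract=3,
                  year_distribution={1970: 1, 1990: 2, 2018: 3}),
        PlantSpec("Crohn Disease", n_title=8, n_abstract=4,
                  year_distribution={1980: 1, 2000: 2, 2020: 3}),
    ]
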