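"""Result tables: per-term summaries, per-citation hits, dedup and trends.

The search stage produces two artifacts mirroring the standard outputs of
exhaustive phrase searching:

* ``term_results.csv`` — one row per permuted phrase, including phrases
  with zero hits and phrases rejected as broadened (valid = False,
  hit_count = 0);
* ``pmid_results.csv`` — one row per (phrase, PMID) hit.  A citation that
  uses several variants of the same root appears once per variant here.

Because per-root citation counts must count each paper once, duplicates
are removed *within* each root (a PMID matched by both "Zenker
Diverticulum" and "Zenker's Diverticulum" survives once) but never across
roots (the same PMID may legitimately cite two different eponyms).  The
deduplicated table feeds the per-year and per-journal usage summaries.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .entrez_client import CitationRecord, QueryResult, extract_year
from .errors import InputError, ValidationError

__all__ = [
    "TermRow",
    "HitRow",
    "write_term_results",
    "build_hit_rows",
    "write_pmid_results",
    "read_pmid_results",
    "dedup_pmids",
    "summarize_by_year",
    "summarize_by_journal",
    "UNKNOWN_YEAR",
]

#: Bucket label for citations whose DP value yields no parseable year.
UNKNOWN_YEAR = "unknown"


@dataclass(frozen=True)
class TermRow:
    root_label: str
    term_text: str
    variant_class: str
    valid: bool
    hit_count: int


@dataclass(frozen=True)
class HitRow:
    root_label: str
    term_text: str
    pmid: str
    journal_title: str = ""
    pub_date_raw: str = ""
    year: Optional[int] = None


def _open_out(path: str | Path):
    try:
        return Path(path).open("w", newline="", encoding="utf-8")
    except OSError as exc:
        raise InputError(f"cannot write {path}: {exc}") from exc


def write_term_results(results: Sequence[QueryResult], path: str | Path) -> list[TermRow]:
    """Write one summary row per permuted phrase.

    Every phrase appears exactly once; broadened (invalid) phrases are kept
    with valid = False and a zero hit count so the audit trail is complete.
    """
    seen: set[tuple[str, str]] = set()
    rows: list[TermRow] = []
    for res in results:
        key = (res.term.root_label, res.term.text)
        if key in seen:
            raise ValidationError(f"duplicate term row for {key}")
        seen.add(key)
        rows.append(
            TermRow(
                root_label=res.term.root_label,
                term_text=res.term.text,
                variant_class=res.term.variant_class,
                valid=res.valid,
                hit_count=res.hit_count,
            )
        )
    with _open_out(path) as fh:
        writer = csv.writer(fh)
        writer.writerow(["root", "term", "variant_class", "valid", "hit_count"])
        for row in rows:
            writer.writerow(
                [row.root_label, row.term_text, row.variant_class, row.valid, row.hit_count]
            )
    return rows


def build_hit_rows(
    results: Sequence[QueryResult], records: Mapping[str, CitationRecord]
) -> list[HitRow]:
    """One row per (phrase, PMID) hit, duplicates across variants preserved.

    A PMID without a fetched record yields a row with empty journal/date —
    dropped rows would break the hit-count conservation identity.
    """
    rows: list[HitRow] = []
    for res in results:
        if not res.valid:
            continue
        for pmid in res.pmids:
            rec = records.get(str(pmid))
            if rec is None:
                rows.append(HitRow(res.term.root_label, res.term.text, str(pmid)))
            else:
                rows.append(
                    HitRow(
                        root_label=res.term.root_label,
                        term_text=res.term.text,
                        pmid=rec.pmid,
                        journal_title=rec.journal_title,
                        pub_date_raw=rec.pub_date_raw,
                        year=rec.year,
                    )
                )
    return rows


def write_pmid_results(rows: Sequence[HitRow], path: str | Path) -> None:
    """Write hit rows as CSV (header always present, even with no hits)."""
    with _open_out(path) as fh:
        writer = csv.writer(fh)
        writer.writerow(["root", "term", "pmid", "journal_title", "pub_date", "year"])
        for row in rows:
            writer.writerow(
                [
                    row.root_label,
                    row.term_text,
                    row.pmid,
                    row.journal_title,
                    row.pub_date_raw,
                    "" if row.year is None else row.year,
                ]
            )


def read_pmid_results(path: str | Path) -> list[HitRow]:
    path = Path(path)
    if not path.is_file():
        raise InputError(f"pmid results CSV not found: {path}")
    rows: list[HitRow] = []
    with path.open(newline="", encoding="utf-8-sig") as fh:
        reader = csv.DictReader(fh)
        required = {"root", "term", "pmid"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValidationError(f"{path}: expected columns {sorted(required)}")
        for row in reader:
            year_text = (row.get("year") or "").strip()
            rows.append(
                HitRow(
                    root_label=row["root"],
                    term_text=row["term"],
                    pmid=row["pmid"],
                    journal_title=row.get("journal_title", ""),
                    pub_date_raw=row.get("pub_date", ""),
                    year=int(year_text) if year_text else None,
                )
            )
    return rows


def dedup_pmids(hit_rows: Sequence[HitRow]) -> list[HitRow]:
    """Keep each PMID once per root, first occurrence wins, order stable.

    First occurrence follows generation order (the standard form is
    searched first), making the surviving term deterministic.  Rows for
    the same PMID under *different* roots are all retained.
    """
    seen: set[tuple[str, str]] = set()
    out: list[HitRow] = []
    for row in hit_rows:
        key = (row.root_label, row.pmid)
        if key in seen:
            continue
        seen.add(key)
        out.append(row)
    return out


def summarize_by_year(deduped: Sequence[HitRow]) -> pd.DataFrame:
    """Citation counts per publication year over all roots.

    Rows lacking a parseable year are tallied under the "unknown" bucket;
    the column total always equals the number of deduplicated rows.
    """
    if not deduped:
        return pd.DataFrame(columns=["year", "citations"])
    keys = []
    for row in deduped:
        year = row.year
        if year is None:
            year = extract_year(row.pub_date_raw)
        keys.append(UNKNOWN_YEAR if year is None else year)
    series = pd.Series(keys).value_counts()
    known = sorted(k for k in series.index if k != UNKNOWN_YEAR)
    order = known + ([UNKNOWN_YEAR] if UNKNOWN_YEAR in series.index else [])
    return pd.DataFrame({"year": order, "citations": [int(series[k]) for k in order]})


def summarize_by_journal(deduped: Sequence[HitRow]) -> pd.DataFrame:
    """Citation counts per journal, ordered by count desc then title asc."""
    if not deduped:
        return pd.DataFrame(columns=["journal_title", "citations"])
    series = pd.Series([row.journal_title for row in deduped]).value_counts()
    df = pd.DataFrame({"journal_title": series.index, "citations": series.to_numpy()})
    return df.sort_values(
        ["citations", "journal_title"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
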