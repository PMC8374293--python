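"""Reading, standardizing and writing curated eponym lists.

A curated list arrives as a two-column UTF-8 CSV (``names``, ``term``): the
surname part and the medical term, already split by a human curator.  The
split itself is deliberately manual — telling a two-person eponym
("Mallory Weiss") from a multi-word surname ("Van Slyke"), or deciding where
a multi-word term begins, requires domain judgement that is error-prone to
automate.  Everything mechanical after the split happens here:

* byte-order-mark-tolerant CSV reading and whitespace normalization,
* conversion of possessive surname forms ("Zenker's", "Chagas'") to their
  plain equivalents,
* replacement of conjunctions between surnames ("and", ",") by hyphens,
* optional inversion of prepositional forms ("Crypts of Lieberkuhn" ->
  names "Lieberkuhn", term "Crypts") as a helper for list preparation.

The standardized list (one :class:`RootEponym` per row) is the input to the
variant permutation stage.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

from .errors import AmbiguityError, InputError, SchemaError, ValidationError

__all__ = [
    "RawEponymEntry",
    "RootEponym",
    "read_eponym_csv",
    "strip_possessive",
    "normalize_conjunctions",
    "invert_prepositional",
    "standardize",
    "standardize_all",
    "write_standardized_csv",
    "read_standardized_csv",
    "bundled_gi_eponyms_path",
]

#: Apostrophe glyphs accepted on input; output always uses the straight glyph.
_APOSTROPHES = "'’"
_APOS_CLASS = f"[{_APOSTROPHES}]"


@dataclass(frozen=True)
class RawEponymEntry:
    """One row of a curated eponym CSV, before standardization."""

    names_field: str
    term_field: str
    row_index: int  # 1-based position in the source file


@dataclass(frozen=True)
class RootEponym:
    """A standardized eponym: ordered surnames plus the medical term.

    ``names`` may be empty for term-only entries (e.g. "Escherichia coli",
    where the person's name survives only inside a Latinized genus name and
    possessive/conjunction variants would be nonsense).
    """

    names: tuple[str, ...]
    term: str
    source_row: int = 0

    @property
    def n_names(self) -> int:
        return len(self.names)

    @property
    def root_label(self) -> str:
        """Canonical display form: hyphen-joined names, a space, the term."""
        if not self.names:
            return self.term
        return "-".join(self.names) + " " + self.term


def _collapse_ws(text: str) -> str:
    return " ".join(text.split())


def read_eponym_csv(path: str | Path) -> list[RawEponymEntry]:
    """Read a curated eponym CSV into :class:`RawEponymEntry` rows.

    The file must be UTF-8 with or without a leading byte order mark (Excel
    exports one; it is consumed and never reaches a field value).  Columns
    ``names`` and ``term`` are matched case-insensitively.  Surrounding
    whitespace is trimmed; internal whitespace runs collapse to one space.
    """
    path = Path(path)
    if not path.is_file():
        raise InputError(f"eponym CSV not found: {path}")
    # utf-8-sig strips a UTF-8 BOM if present and is a no-op otherwise
    with path.open(newline="", encoding="utf-8-sig") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, expected columns 'names' and 'term'")
        colmap = {name.strip().lower(): name for name in reader.fieldnames}
        for required in ("names", "term"):
            if required not in colmap:
                raise SchemaError(f"{path}: missing required column '{required}'")
        entries: list[RawEponymEntry] = []
        for i, row in enumerate(reader, start=1):
            names = _collapse_ws(row[colmap["names"]] or "")
            term = _collapse_ws(row[colmap["term"]] or "")
            if not term:
                raise ValidationError(f"{path}: empty term field at data row {i}")
            entries.append(RawEponymEntry(names_field=names, term_field=term, row_index=i))
    return entries


def strip_possessive(name: str) -> str:
    """Convert a possessive surname form to its plain equivalent.

    Trailing "'s" (straight or curly apostrophe) is removed; a trailing
    "s'" loses the apostrophe.  Unmarked names pass through unchanged, so
    the operation is idempotent.
    """
    name = re.sub(f"{_APOS_CLASS}[sS]$", "", name)
    name = re.sub(f"([sS]){_APOS_CLASS}$", r"\1", name)
    return name


def normalize_conjunctions(names_field: str) -> list[str]:
    """Split a surname field into its ordered surname tokens.

    Separators are hyphens, commas and the standalone word "and" (in any
    combination, e.g. ", and").  A space alone is *not* a separator: a
    space-separated compound such as "Van Slyke" is a single multi-word
    surname and is kept verbatim; distinct names separated only by a space
    must be hyphenated by the curator upstream.
    """
    if not names_field.strip():
        raise ValidationError("empty names field has no surname tokens")
    text = re.sub(r",\s*(?:and\s+)?", "-", names_field, flags=re.IGNORECASE)
    text = re.sub(r"\s+and\s+", "-", text, flags=re.IGNORECASE)
    tokens = [tok.strip() for tok in text.split("-")]
    tokens = [tok for tok in tokens if tok]
    if not tokens:
        raise ValidationError(f"names field {names_field!r} reduces to zero surname tokens")
    return tokens


def invert_prepositional(eponym_text: str) -> Optional[tuple[str, str]]:
    """Invert a "Term of Name" eponym into a (names, term) split.

    Returns ``(names_field, term_field)`` when exactly one standalone "of"
    separates the term part from the name part, ``None`` when no "of" is
    present (the caller keeps its original split), and raises
    :class:`AmbiguityError` for multiple "of" tokens, which need a manual
    split.
    """
    parts = re.split(r"\s+of\s+", _collapse_ws(eponym_text), flags=re.IGNORECASE)
    if len(parts) == 1:
        return None
    if len(parts) > 2:
        raise AmbiguityError(
            f"{eponym_text!r} contains more than one 'of'; split it manually"
        )
    term_part, name_part = parts
    if not term_part or not name_part:
        raise ValidationError(f"{eponym_text!r} has an empty side around 'of'")
    return name_part, term_part


def standardize(entry: RawEponymEntry) -> RootEponym:
    """Apply the standardization rules to one raw entry.

    Conjunctions between surnames become hyphens, each surname loses any
    possessive marker, and the term is preserved verbatim.  An empty names
    field yields a term-only root.
    """
    if entry.names_field.strip():
        tokens = [strip_possessive(tok) for tok in normalize_conjunctions(entry.names_field)]
        for tok in tokens:
            if any(ch in tok for ch in _APOSTROPHES):
                raise ValidationError(
                    f"surname token {tok!r} (row {entry.row_index}) retains an apostrophe "
                    "after possessive stripping; internal apostrophes are unsupported"
                )
    else:
        tokens = []
    return RootEponym(names=tuple(tokens), term=entry.term_field, source_row=entry.row_index)


def standardize_all(entries: Iterable[RawEponymEntry]) -> list[RootEponym]:
    return [standardize(e) for e in entries]


def write_standardized_csv(roots: list[RootEponym], path: str | Path) -> None:
    """Write a standardized list as UTF-8 CSV (no BOM), columns names/term.

    Reading the output back with :func:`read_standardized_csv` reproduces
    the input list exactly.
    """
    if not roots:
        raise ValidationError("refusing to write an empty standardized list")
    path = Path(path)
    try:
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["names", "term"])
            for root in roots:
                writer.writerow(["-".join(root.names), root.term])
    except OSError as exc:
        raise InputError(f"cannot write standardized CSV to {path}: {exc}") from exc


def read_standardized_csv(path: str | Path) -> list[RootEponym]:
    """Read a standardized CSV back into :class:`RootEponym` objects."""
    return standardize_all(read_eponym_csv(path))


def bundled_gi_eponyms_path() -> Path:
    """Path of the bundled 27-term gastrointestinal eponym fixture.

    The raw list reproduces the curated gastrointestinal set: 25 roots with
    nonzero literature hits plus the two zero-hit roots (Carman Meniscus
    Sign, Heister Spiral Valves).  Raw forms deliberately carry possessives,
    conjunctions and both apostrophe glyphs so standardization is exercised.
    """
    return Path(__file__).parent / "data" / "gi_eponyms_raw.csv"
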