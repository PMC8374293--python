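"""Exhaustive variant generation for standardized eponyms.

A standardized eponym such as "Mallory-Weiss Tear" appears in titles and
abstracts in many surface forms: different conjunctions between the
surnames ("Mallory Weiss Tear", "Mallory and Weiss Tear"), possessive forms
("Mallory-Weiss' Tear", with two accepted spellings when a name ends in
"s"), and the prepositional inversion ("Tear of Mallory-Weiss").  Searching
only the canonical form undercounts usage, so this module permutes each
root into the exhaustive variant list before the search stage.

The generated count (excluding the standard form) depends on the number of
surnames n and which of them end in "s":

=====  ==========================  ======
n      s-ending configuration      count
=====  ==========================  ======
0      —                           0
1      plain / s-ending            2 / 3
2      none ... both               9 – 15
3      (opt-in grammar) none...all 14 – 32
=====  ==========================  ======

The exact slot assignment — which conjunction contexts carry which
possessive scheme — is encoded in :class:`PermutationGrammar`; the default
grammar is the unique small assignment that realizes every count above
simultaneously (see docs/methods.md).
"""

from __future__ import annotations

import csv
import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .eponym_io import RootEponym
from .errors import InputError, UnsupportedArityError, ValidationError

__all__ = [
    "VARIANT_CLASSES",
    "SearchTerm",
    "PermutationGrammar",
    "DEFAULT_GRAMMAR",
    "possessive_forms",
    "permute",
    "permute_all",
    "write_permuted_csv",
    "read_permuted_csv",
]

#: Variant classes a generated phrase may carry.
VARIANT_CLASSES = ("standard", "conjunction", "possessive_final", "possessive_all", "inversion")


@dataclass(frozen=True)
class SearchTerm:
    """One search phrase generated for a root eponym."""

    root_label: str
    text: str
    variant_class: str

    def __post_init__(self):
        if self.variant_class not in VARIANT_CLASSES:
            raise ValidationError(f"unknown variant class {self.variant_class!r}")
        if not self.text:
            raise ValidationError("search term text must be non-empty")


@dataclass(frozen=True)
class PermutationGrammar:
    """Which joiners and possessive schemes combine into variants.

    ``conjunctions`` are the joiner strings placed between surnames; "-"
    must be present (it renders the standard form).  Possessive schemes are
    applied only in the listed conjunction contexts:
    ``final_possessive_contexts`` marks only the final surname possessive,
    ``all_possessive_contexts`` marks every surname (Cartesian product of
    per-name spellings, since an s-ending name has two accepted spellings).
    The opt-in three-name pattern set adds mixed-joiner conjunction forms
    (serial-comma style) and wider possessive contexts.
    """

    conjunctions: tuple[str, ...] = ("-", " ", ", ", " and ", ", and ")
    final_possessive_contexts: tuple[str, ...] = ("-", " ", " and ")
    all_possessive_contexts: tuple[str, ...] = (" and ",)
    inversion_enabled: bool = True
    enable_n3: bool = False

    # three-name pattern set (active only with enable_n3)
    n3_mixed_joiners: tuple[tuple[str, str], ...] = (
        (", ", " and "),
        (", ", ", and "),
        ("-", " and "),
    )
    n3_final_possessive_contexts: tuple[str, ...] = ("-", " ", " and ", ", and ")
    n3_all_possessive_contexts: tuple[str, ...] = (" and ", ", and ")

    def __post_init__(self):
        if "-" not in self.conjunctions:
            raise ValidationError("grammar must include the hyphen joiner (standard form)")
        for ctx in (*self.final_possessive_contexts, *self.all_possessive_contexts):
            if ctx not in self.conjunctions:
                raise ValidationError(f"possessive context {ctx!r} not among conjunctions")


DEFAULT_GRAMMAR = PermutationGrammar()


def possessive_forms(name: str) -> list[str]:
    """Accepted possessive spellings of one surname.

    Names ending in "s" have two ("Weiss'", "Weiss's"); all others one
    ("Zenker's").
    """
    if not name:
        raise ValidationError("cannot build possessive forms of an empty name")
    if name.lower().endswith("s"):
        return [name + "'", name + "'s"]
    return [name + "'s"]


def _names_with_final_possessive(names: Sequence[str]) -> Iterable[tuple[str, ...]]:
    for form in possessive_forms(names[-1]):
        yield (*names[:-1], form)


def _names_with_all_possessive(names: Sequence[str]) -> Iterable[tuple[str, ...]]:
    for combo in itertools.product(*(possessive_forms(n) for n in names)):
        yield combo


def _emit(root: RootEponym, seen: set[str], out: list[SearchTerm], text: str, vclass: str) -> None:
    if text not in seen:
        seen.add(text)
        out.append(SearchTerm(root_label=root.root_label, text=text, variant_class=vclass))


def permute(root: RootEponym, grammar: PermutationGrammar = DEFAULT_GRAMMAR) -> list[SearchTerm]:
    """Generate the standard phrase plus every grammar variant for one root.

    The returned list is de-duplicated by phrase text, with the standard
    form first and generation order otherwise preserved.  Term-only roots
    (n = 0) yield only the standard phrase.  Three-name roots require
    ``grammar.enable_n3``; more names are unsupported.
    """
    n = root.n_names
    if n > 3 or (n == 3 and not grammar.enable_n3):
        raise UnsupportedArityError(
            f"{root.root_label!r} has {n} surnames; no permutation pattern set is "
            "enabled for this arity" + (" (pass enable_n3)" if n == 3 else "")
        )

    out: list[SearchTerm] = []
    seen: set[str] = set()
    _emit(root, seen, out, root.root_label, "standard")
    if n == 0:
        return out

    term = root.term

    if n == 1:
        for form in possessive_forms(root.names[0]):
            _emit(root, seen, out, f"{form} {term}", "possessive_final")
    else:
        if n == 2:
            joiners = [c for c in grammar.conjunctions if c != "-"]
            final_ctx = grammar.final_possessive_contexts
            all_ctx = grammar.all_possessive_contexts
            mixed: tuple[tuple[str, str], ...] = ()
        else:  # n == 3, opt-in
            joiners = [c for c in grammar.conjunctions if c != "-"]
            final_ctx = grammar.n3_final_possessive_contexts
            all_ctx = grammar.n3_all_possessive_contexts
            mixed = grammar.n3_mixed_joiners

        for joiner in joiners:
            _emit(root, seen, out, joiner.join(root.names) + " " + term, "conjunction")
        for pair in mixed:
            text = root.names[0] + pair[0] + pair[1].join(root.names[1:])
            _emit(root, seen, out, text + " " + term, "conjunction")
        for ctx in final_ctx:
            for names in _names_with_final_possessive(root.names):
                _emit(root, seen, out, ctx.join(names) + " " + term, "possessive_final")
        for ctx in all_ctx:
            for names in _names_with_all_possessive(root.names):
                _emit(root, seen, out, ctx.join(names) + " " + term, "possessive_all")

    if grammar.inversion_enabled:
        _emit(root, seen, out, f"{term} of " + "-".join(root.names), "inversion")

    return out


def permute_all(
    roots: Sequence[RootEponym], grammar: PermutationGrammar = DEFAULT_GRAMMAR
) -> list[SearchTerm]:
    """Permute every root, order-stable by source row then generation order."""
    ordered = sorted(roots, key=lambda r: r.source_row)
    terms: list[SearchTerm] = []
    for root in ordered:
        terms.extend(permute(root, grammar))
    return terms


def write_permuted_csv(terms: Sequence[SearchTerm], path: str | Path) -> None:
    """Write generated search terms as UTF-8 CSV (columns root, variant_class, term)."""
    if not terms:
        raise ValidationError("refusing to write an empty term list")
    seen: set[tuple[str, str]] = set()
    for t in terms:
        key = (t.root_label, t.text)
        if key in seen:
            raise ValidationError(f"duplicate phrase {t.text!r} within root {t.root_label!r}")
        seen.add(key)
    path = Path(path)
    try:
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["root", "variant_class", "term"])
            for t in terms:
                writer.writerow([t.root_label, t.variant_class, t.text])
    except OSError as exc:
        raise InputError(f"cannot write permuted CSV to {path}: {exc}") from exc


def read_permuted_csv(path: str | Path) -> list[SearchTerm]:
    path = Path(path)
    if not path.is_file():
        raise InputError(f"permuted CSV not found: {path}")
    with path.open(newline="", encoding="utf-8-sig") as fh:
        reader = csv.DictReader(fh)
        required = {"root", "variant_class", "term"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValidationError(f"{path}: expected columns {sorted(required)}")
        return [
            SearchTerm(root_label=row["root"], text=row["term"], variant_class=row["variant_class"])
            for row in reader
        ]
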