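"""MeSH vocabulary handling.

Medical Subject Headings (MeSH) is the controlled vocabulary used to index
MEDLINE articles.  Each descriptor carries one or more *tree numbers* placing
it in the hierarchy; the first character of a tree number is the top-level
category letter (C = Diseases, D = Chemicals and Drugs, E = Analytical,
Diagnostic and Therapeutic Techniques and Equipment, ...).  The analysis
pipeline restricts term sets to a category whitelist, by default {C, D, E},
with subcategories included implicitly because matching is by first letter.

Two on-disk dialects are supported: the NLM descriptor XML distribution
(``desc20XX.xml``: DescriptorRecord / DescriptorUI / DescriptorName /
TreeNumberList) and a three-column TSV ``ui<TAB>name<TAB>tree;tree;...``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from lxml import etree

log = logging.getLogger(__name__)

#: The 16 top-level MeSH category letters.
TOP_LEVEL_CATEGORIES = frozenset("ABCDEFGHIJKLMNVZ")

#: Default category whitelist: Diseases, Chemicals and Drugs,
#: Analytical/Diagnostic/Therapeutic Techniques and Equipment.
DEFAULT_CATEGORIES = frozenset("CDE")

_TREE_RE = re.compile(r"^[A-Z]\d+(\.\d+)*$")


def normalize_term(name: str) -> str:
    """Normalisation key for descriptor-name matching: trim + casefold."""
    return name.strip().casefold()


@dataclass(frozen=True)
class MeshDescriptor:
    """One controlled-vocabulary term.

    ``categories`` is derived, never stored: it is exactly the set of first
    characters of the tree numbers, so a descriptor without tree numbers has
    no category and is excluded by any category whitelist.
    """

    ui: str
    name: str
    tree_numbers: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for tn in self.tree_numbers:
            if not _TREE_RE.match(tn):
                raise ValueError(
                    f"descriptor {self.ui!r} ({self.name!r}): malformed tree number {tn!r}"
                )

    @property
    def categories(self) -> frozenset[str]:
        return frozenset(tn[0] for tn in self.tree_numbers)


def in_categories(descriptor: MeshDescriptor, allowed: frozenset[str] | set[str]) -> bool:
    """True iff the descriptor belongs to at least one allowed top-level category.

    Matching is by the first letter of each tree number, so subcategories are
    included automatically.
    """
    _validate_categories(allowed)
    return bool(descriptor.categories & set(allowed))


def _validate_categories(allowed: Iterable[str]) -> frozenset[str]:
    allowed = frozenset(allowed)
    if not allowed:
        raise ValueError("category whitelist must be non-empty")
    bad = sorted(c for c in allowed if c not in TOP_LEVEL_CATEGORIES)
    if bad:
        raise ValueError(
            f"unknown MeSH category letter(s): {bad}; valid letters are "
            + "".join(sorted(TOP_LEVEL_CATEGORIES))
        )
    return allowed


class Vocabulary:
    """Descriptor lookup by unique identifier or (case-insensitive) name."""

    def __init__(self, descriptors: Iterable[MeshDescriptor] = ()):
        self._by_ui: dict[str, MeshDescriptor] = {}
        self._by_name: dict[str, MeshDescriptor] = {}
        for d in descriptors:
            self.add(d)

    def add(self, descriptor: MeshDescriptor) -> None:
        if descriptor.ui in self._by_ui:
            raise ValueError(f"duplicate descriptor UI {descriptor.ui!r}")
        key = normalize_term(descriptor.name)
        if key in self._by_name:
            raise ValueError(f"duplicate descriptor name {descriptor.name!r}")
        self._by_ui[descriptor.ui] = descriptor
        self._by_name[key] = descriptor

    def get(self, key: str) -> MeshDescriptor | None:
        """Resolve by UI first, then by normalised name."""
        return self._by_ui.get(key) or self._by_name.get(normalize_term(key))

    def canonical_name(self, name: str) -> str | None:
        d = self.get(name)
        return d.name if d is not None else None

    def __len__(self) -> int:
        return len(self._by_ui)

    def __iter__(self) -> Iterator[MeshDescriptor]:
        return iter(self._by_ui.values())

    def __contains__(self, key: str) -> bool:
        return self.get(key) is not None


def load_vocabulary(path: str | Path, format: str | None = None) -> Vocabulary:
    """Load a MeSH vocabulary from ``mesh-xml`` or ``tsv``.

    ``format=None`` infers from the suffix (``.xml`` -> mesh-xml, else tsv).
    Descriptors without tree numbers are retained with empty categories.
    Malformed files raise ``ValueError`` naming the offending line/element;
    an empty file yields an empty vocabulary with a warning.
    """
    path = Path(path)
    if format is None:
        format = "mesh-xml" if path.suffix.lower() == ".xml" else "tsv"
    if format == "mesh-xml":
        vocab = _load_mesh_xml(path)
    elif format == "tsv":
        vocab = _load_tsv(path)
    else:
        raise ValueError(f"unknown vocabulary format {format!r}")
    if len(vocab) == 0:
        log.warning("vocabulary file %s contains no descriptors", path)
    return vocab


def _load_tsv(path: Path) -> Vocabulary:
    vocab = Vocabulary()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected ui<TAB>name[<TAB>trees]")
            ui, name = parts[0].strip(), parts[1].strip()
            trees = tuple(
                t.strip() for t in (parts[2] if len(parts) > 2 else "").split(";") if t.strip()
            )
            try:
                vocab.add(MeshDescriptor(ui=ui, name=name, tree_numbers=trees))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return vocab


def _load_mesh_xml(path: Path) -> Vocabulary:
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"{path}: malformed XML: {exc}") from exc
    vocab = Vocabulary()
    for rec in tree.iter("DescriptorRecord"):
        ui = rec.findtext("DescriptorUI")
        name = rec.findtext("DescriptorName/String")
        if not ui or not name:
            raise ValueError(
                f"{path}: DescriptorRecord at line {rec.sourceline} lacks "
                "DescriptorUI or DescriptorName/String"
            )
        trees = tuple(
            tn.text.strip()
            for tn in rec.findall("TreeNumberList/TreeNumber")
            if tn.text and tn.text.strip()
        )
        vocab.add(MeshDescriptor(ui=ui.strip(), name=name.strip(), tree_numbers=trees))
    return vocab


def write_vocabulary_tsv(vocab: Vocabulary, path: str | Path) -> None:
    """Write the three-column TSV interchange form."""
    with open(path, "w", encoding="utf-8") as fh:
        for d in vocab:
            fh.write(f"{d.ui}\t{d.name}\t{';'.join(d.tree_numbers)}\n")


def restrict_terms(
    terms: Iterable[str],
    vocabulary: Vocabulary,
    allowed: frozenset[str] | set[str] = DEFAULT_CATEGORIES,
) -> tuple[list[str], list[str], list[str]]:
    """Partition article terms by the category whitelist.

    Returns ``(kept, unmapped, outside)``: terms in an allowed category,
    terms absent from the vocabulary (dropped when filtering is on, per the
    strict category restriction), and mapped terms outside the whitelist.
    """
    allowed = _validate_categories(allowed)
    kept: list[str] = []
    unmapped: list[str] = []
    outside: list[str] = []
    for term in terms:
        d = vocabulary.get(term)
        if d is None:
            unmapped.append(term)
        elif d.categories & allowed:
            kept.append(term)
        else:
            outside.append(term)
    if unmapped:
        log.info("category filter: %d term(s) not in vocabulary were dropped", len(unmapped))
    return kept, unmapped, outside
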