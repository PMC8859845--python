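"""Article records, sample assembly and yearly binning.

A *sample* is a set of MEDLINE articles returned by one query (target or
control).  Before any statistics, PMIDs occurring in both samples are
excluded from both, so every article is uniquely attributed; articles are
then binned into ordered yearly intervals.  Default binning is calendar
years; PubMed-style ``"20XX/10/22"[PDat]:"20XX+1/10/21"[PDat]`` windows are
available via :func:`pubmed_windows`.

Input dialects: MEDLINE/PubMed XML (``PubmedArticleSet`` /
``MedlineCitation`` / ``MeshHeadingList``) and a TSV interchange format
``pmid<TAB>date-or-year<TAB>semicolon-joined MeSH names``.  Only descriptor
names are counted; qualifiers (subheadings) attached to a heading are
stripped.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, replace
from functools import cached_property
from pathlib import Path
from typing import Collection, Iterable, Sequence

from lxml import etree

from .vocab import normalize_term

log = logging.getLogger(__name__)

_MONTHS = {
    m: i + 1
    for i, m in enumerate(
        ["jan", "feb", "mar", "apr", "may", "jun", "jul", "aug", "sep", "oct", "nov", "dec"]
    )
}

#: A labelled closed date interval (label, first day, last day).
Interval = tuple[str, dt.date, dt.date]


@dataclass(frozen=True)
class Article:
    """One publication record: PMID, publication date, MeSH descriptor names.

    ``terms`` is a set, so duplicated descriptors within one record count
    once.  ``year_bin`` is assigned by :func:`bin_by_year`.
    """

    pmid: int
    date: dt.date | None
    terms: frozenset[str]
    year_bin: str | None = None


@dataclass
class SampleCorpus:
    """A labelled article sample with per-bin size bookkeeping.

    ``year_sizes`` (the per-year N_t or N_c denominators) is always computed
    from the article list, so it equals the per-bin tally exactly.
    """

    label: str
    articles: list[Article]

    def __post_init__(self) -> None:
        pmids = [a.pmid for a in self.articles]
        if len(pmids) != len(set(pmids)):
            raise ValueError(f"duplicate PMIDs within sample {self.label!r}")

    @cached_property
    def year_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for a in self.articles:
            if a.year_bin is not None:
                sizes[a.year_bin] = sizes.get(a.year_bin, 0) + 1
        return sizes

    @property
    def pmids(self) -> set[int]:
        return {a.pmid for a in self.articles}

    def __len__(self) -> int:
        return len(self.articles)


def parse_pub_date(text: str) -> dt.date:
    """Parse ``YYYY``, ``YYYY-MM`` or ``YYYY-MM-DD`` (``/`` also accepted).

    Year-only and year-month dates resolve to the first day of the missing
    component, which keeps them inside the calendar-year bin they name.
    """
    text = text.strip().replace("/", "-")
    parts = text.split("-")
    if not 1 <= len(parts) <= 3:
        raise ValueError(f"unparseable date {text!r}")
    try:
        nums = [int(p) for p in parts]
    except ValueError as exc:
        raise ValueError(f"unparseable date {text!r}") from exc
    year = nums[0]
    month = nums[1] if len(nums) > 1 else 1
    day = nums[2] if len(nums) > 2 else 1
    return dt.date(year, month, day)


def read_articles(path: str | Path, format: str | None = None) -> list[Article]:
    """Read article records from ``medline-xml`` or ``tsv``.

    Records that cannot be parsed (bad PMID, missing or unparseable date)
    are skipped with a per-record warning and a final skipped-count report;
    zero parseable records is an error.  Records without MeSH terms are
    retained with an empty term set: they contribute to sample sizes but to
    no term count.
    """
    path = Path(path)
    if format is None:
        format = "medline-xml" if path.suffix.lower() == ".xml" else "tsv"
    if format == "medline-xml":
        articles, skipped = _read_medline_xml(path)
    elif format == "tsv":
        articles, skipped = _read_tsv(path)
    else:
        raise ValueError(f"unknown article format {format!r}")
    if skipped:
        log.warning("%s: skipped %d unparseable record(s)", path, skipped)
    if not articles:
        raise ValueError(f"{path}: no parseable article records")
    return articles


def _clean_terms(names: Iterable[str]) -> frozenset[str]:
    return frozenset(n.strip() for n in names if n and n.strip())


def _read_tsv(path: Path) -> tuple[list[Article], int]:
    articles: list[Article] = []
    skipped = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            try:
                if len(parts) < 2:
                    raise ValueError("expected pmid<TAB>date[<TAB>terms]")
                pmid = int(parts[0])
                if pmid <= 0:
                    raise ValueError("PMID must be positive")
                date = parse_pub_date(parts[1])
                terms = _clean_terms((parts[2] if len(parts) > 2 else "").split(";"))
            except ValueError as exc:
                log.warning("%s:%d: skipping record: %s", path, lineno, exc)
                skipped += 1
                continue
            articles.append(Article(pmid=pmid, date=date, terms=terms))
    return articles, skipped


def _read_medline_xml(path: Path) -> tuple[list[Article], int]:
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"{path}: malformed XML: {exc}") from exc
    articles: list[Article] = []
    skipped = 0
    for cit in tree.iter("MedlineCitation"):
        try:
            articles.append(_parse_citation(cit))
        except ValueError as exc:
            log.warning("%s: skipping record at line %s: %s", path, cit.sourceline, exc)
            skipped += 1
    return articles, skipped


def _parse_citation(cit: etree._Element) -> Article:
    pmid_text = cit.findtext("PMID")
    if not pmid_text or not pmid_text.strip().isdigit():
        raise ValueError(f"missing or non-numeric PMID {pmid_text!r}")
    date = _parse_pubdate_element(cit.find("Article/Journal/JournalIssue/PubDate"))
    if date is None:
        raise ValueError("no parseable publication date")
    terms = _clean_terms(
        el.text or "" for el in cit.findall("MeshHeadingList/MeshHeading/DescriptorName")
    )
    return Article(pmid=int(pmid_text), date=date, terms=terms)


def _parse_pubdate_element(pubdate: etree._Element | None) -> dt.date | None:
    if pubdate is None:
        return None
    year_text = pubdate.findtext("Year")
    if year_text and year_text.strip().isdigit():
        year = int(year_text)
        month = _parse_month(pubdate.findtext("Month"))
        day_text = pubdate.findtext("Day")
        day = int(day_text) if day_text and day_text.strip().isdigit() else 1
        try:
            return dt.date(year, month, day)
        except ValueError:
            return dt.date(year, month, 1)
    # MedlineDate fallback, e.g. "2016 Nov-Dec" or "2015-2016"
    medline = pubdate.findtext("MedlineDate") or ""
    for token in medline.replace("-", " ").split():
        if token.isdigit() and len(token) == 4:
            return dt.date(int(token), 1, 1)
    return None


def _parse_month(text: str | None) -> int:
    if not text:
        return 1
    text = text.strip()
    if text.isdigit():
        return int(text)
    return _MONTHS.get(text[:3].lower(), 1)


def write_articles_tsv(articles: Iterable[Article], path: str | Path) -> None:
    """Write the TSV interchange form (terms sorted for reproducible bytes)."""
    with open(path, "w", encoding="utf-8") as fh:
        for a in articles:
            date = a.date.isoformat() if a.date is not None else ""
            fh.write(f"{a.pmid}\t{date}\t{';'.join(sorted(a.terms))}\n")


def calendar_intervals(start_year: int, end_year: int) -> list[Interval]:
    """Calendar-year bins labelled ``"YYYY"`` (both endpoints inclusive)."""
    if end_year < start_year:
        raise ValueError("end_year before start_year")
    return [
        (str(y), dt.date(y, 1, 1), dt.date(y, 12, 31)) for y in range(start_year, end_year + 1)
    ]


def pubmed_windows(
    start_year: int, end_year: int, boundary: tuple[int, int] = (10, 22)
) -> list[Interval]:
    """PubMed PDat-style windows ``Oct 22 of year Y .. Oct 21 of year Y+1``.

    Labels are ``"Y–Y+1"``.  ``boundary`` is the (month, day) on which each
    window opens; the next window opens one day before the anniversary.
    """
    if end_year < start_year:
        raise ValueError("end_year before start_year")
    month, day = boundary
    out: list[Interval] = []
    for y in range(start_year, end_year + 1):
        start = dt.date(y, month, day)
        end = dt.date(y + 1, month, day) - dt.timedelta(days=1)
        out.append((f"{y}–{y + 1}", start, end))
    return out


def _normalize_intervals(intervals: Sequence) -> list[Interval]:
    norm: list[Interval] = []
    for item in intervals:
        if len(item) == 3:
            label, start, end = item
        elif len(item) == 2:
            start, end = item
            if (start.month, start.day) == (1, 1) and (end.month, end.day) == (12, 31) and (
                start.year == end.year
            ):
                label = str(start.year)
            else:
                label = f"{start.year}–{end.year}"
        else:
            raise ValueError("interval must be (start, end) or (label, start, end)")
        if end < start:
            raise ValueError(f"interval {label!r} ends before it starts")
        norm.append((label, start, end))
    for (la, _, ea), (lb, sb, _) in zip(norm, norm[1:]):
        if sb <= ea:
            raise ValueError(f"intervals {la!r} and {lb!r} overlap or are out of order")
    return norm


def bin_by_year(articles: Iterable[Article], intervals: Sequence) -> list[Article]:
    """Assign each article to the unique closed interval containing its date.

    Articles outside every interval (or without a date) are dropped with a
    logged count.  Intervals must be ordered and non-overlapping.
    """
    norm = _normalize_intervals(intervals)
    binned: list[Article] = []
    dropped = 0
    for a in articles:
        if a.date is None:
            dropped += 1
            continue
        for label, start, end in norm:
            if start <= a.date <= end:
                binned.append(replace(a, year_bin=label))
                break
        else:
            dropped += 1
    if dropped:
        log.info("binning dropped %d article(s) outside all intervals", dropped)
    return binned


def build_samples(
    target_articles: Collection[Article], control_articles: Collection[Article]
) -> tuple[SampleCorpus, SampleCorpus]:
    """Assemble target/control corpora, excluding PMIDs present in both.

    Every shared PMID is removed from *both* samples, so downstream counts
    compare disjoint article sets; per-bin sizes are recomputed after
    removal.  If removal empties either sample the samples are considered
    fully overlapping and an error is raised.
    """
    if not target_articles or not control_articles:
        raise ValueError("both samples must be non-empty")
    shared = {a.pmid for a in target_articles} & {a.pmid for a in control_articles}
    target = [a for a in target_articles if a.pmid not in shared]
    control = [a for a in control_articles if a.pmid not in shared]
    if shared:
        log.info("excluded %d PMID(s) occurring in both samples", len(shared))
    if not target or not control:
        raise ValueError("samples fully overlap: no unique articles remain")
    return SampleCorpus("target", target), SampleCorpus("control", control)


def shared_pmids(
    target_articles: Collection[Article], control_articles: Collection[Article]
) -> set[int]:
    """PMIDs occurring in both samples (the set ``build_samples`` removes)."""
    return {a.pmid for a in target_articles} & {a.pmid for a in control_articles}


def canonical_term_key(term: str) -> str:
    """Matching key used throughout: trimmed, case-insensitive."""
    return normalize_term(term)
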