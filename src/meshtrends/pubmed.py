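"""Optional PubMed E-utilities adapter (untested; requires network).

The analysis pipeline is file-based by design.  This stub documents how a
live sample would be materialised into the TSV interchange format consumed
by :func:`meshtrends.corpus.read_articles`; it is not exercised by the test
suite and needs biopython plus network access.
"""

from __future__ import annotations

from pathlib import Path


def build_year_query(query: str, year: int, boundary: tuple[int, int] = (10, 22)) -> str:
    """Compose a PDat-windowed query string for one yearly interval."""
    m, d = boundary
    start = f"{year}/{m:02d}/{d:02d}"
    end = f"{year + 1}/{m:02d}/{d - 1:02d}"
    return f'({query}) AND ("{start}"[PDat] : "{end}"[PDat])'


def fetch_sample_tsv(query: str, years: range, out_path: str | Path, email: str) -> None:
    """Fetch one sample via Entrez and write the TSV interchange file.

    Untested convenience: walks the yearly windows, fetches MEDLINE XML and
    extracts PMID, publication date and MeSH descriptor names.
    """
    try:
        from Bio import Entrez  # noqa: PLC0415 - optional dependency
    except ImportError as exc:  # pragma: no cover - optional path
        raise ImportError("fetch_sample_tsv requires biopython") from exc
    raise NotImplementedError(
        "live PubMed fetching is intentionally left unimplemented; "
        "materialise samples to the TSV interchange format instead"
    )
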