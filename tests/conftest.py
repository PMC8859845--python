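import datetime as dt

import pytest
from hypothesis import HealthCheck, settings

import meshtrends as mt

settings.register_profile(
    "suite", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("suite")


@pytest.fixture
def tiny_vocab() -> mt.Vocabulary:
    """Six descriptors spanning allowed (C/D/E) and disallowed (A/B) categories."""
    return mt.Vocabulary(
        [
            mt.MeshDescriptor("D000001", "Calcimycin", ("D03.633.100",)),
            mt.MeshDescriptor("D009369", "Neoplasms", ("C04.588", "C04.588.443")),
            mt.MeshDescriptor("D015415", "Biomarkers", ("D23.101",)),
            mt.MeshDescriptor("D013812", "Therapeutics", ("E02.760",)),
            mt.MeshDescriptor("D000818", "Animals", ("B01.050",)),
            mt.MeshDescriptor("D001158", "Arteries", ("A07.015",)),
        ]
    )


def make_article(pmid: int, year: int, terms, bin_label: str | None = None) -> mt.Article:
    return mt.Article(
        pmid=pmid,
        date=dt.date(year, 1, 1),
        terms=frozenset(terms),
        year_bin=bin_label if bin_label is not None else str(year),
    )


@pytest.fixture
def small_panel() -> mt.FrequencyPanel:
    """Two terms over three years, 10 articles per sample per year.

    'alpha' annotates 3 target / 3 control articles every year (null);
    'beta' annotates 8 target / 2 control (target-enriched, 4x).
    """
    target, control = [], []
    pmid = 1
    for year in (2015, 2016, 2017):
        for i in range(10):
            terms = (["alpha"] if i < 3 else []) + (["beta"] if i < 8 else [])
            target.append(make_article(pmid, year, terms))
            pmid += 1
        for i in range(10):
            terms = (["alpha"] if i < 3 else []) + (["beta"] if i < 2 else [])
            control.append(make_article(pmid, year, terms))
            pmid += 1
    t, c = mt.build_samples(target, control)
    return mt.build_panel(t, c)
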