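"""Thin convenience wrappers around standard rank-based tests.

The study compares infectivity metrics across temperatures with
Kruskal-Wallis and across hosts with Mann-Whitney; these are ordinary
library routines, re-exported here with tidy-table-friendly signatures.
"""
from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd
from scipy import stats as _ss


def kruskal_wallis(*groups: Sequence[float]):
    """Kruskal-Wallis H test across two or more groups of values."""
    return _ss.kruskal(*groups)


def kruskal_wallis_by(df: pd.DataFrame, value: str, by: str):
    """Kruskal-Wallis across the levels of column ``by``."""
    groups = [g[value].to_numpy() for _, g in df.groupby(by)]
    return _ss.kruskal(*groups)


def mann_whitney(x: Iterable[float], y: Iterable[float], **kw):
    """Two-sided Mann-Whitney U test."""
    return _ss.mannwhitneyu(x, y, alternative=kw.pop("alternative", "two-sided"), **kw)
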