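"""Excess-usage statistics for word frequencies.

The analysis mirrors excess-mortality reasoning: for each word, its
document frequency in the analysis year Y is compared with a
counterfactual frequency projected linearly from the two pre-effect years
Y-3 and Y-2. All frequencies use add-one smoothing,

    p = (a + 1) / (b + 1),

where ``a`` is the number of abstracts in a year containing the word and
``b`` is that year's abstract total. The counterfactual projection

    q = p_{-2} + 2 * max(p_{-2} - p_{-3}, 0)

never falls below the last pre-effect frequency p_{-2}, making the two
excess measures conservative: the excess ratio r = p/q and the excess gap
delta = p - q. A word is an *excess word* when delta exceeds a gap cutoff
or when its ratio clears a frequency-dependent line in log-log space.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .vocabulary import YearCounts

logger = logging.getLogger(__name__)

CATEGORIES = ("content", "style", "ambiguous", "unannotated")
POS_TAGS = ("noun", "verb", "adjective", "other", "unannotated")


@dataclass
class ThresholdParams:
    """Excess-word calling thresholds.

    A word is excess when ``delta > delta_min`` or
    ``log10(r) > ratio_intercept - ratio_slope * log10(p)`` (strict
    inequalities; at the defaults the ratio criterion reads
    ``r > 2 * p**(-1/4)``, i.e. the line passes through (p=1e-4, r=20)).
    ``eligibility_min_freq`` restricts the analysis to words with smoothed
    frequency above it in both the analysis year and the year before.
    """

    delta_min: float = 0.01
    ratio_intercept: float = math.log10(2.0)
    ratio_slope: float = 0.25
    eligibility_min_freq: float = 1e-4

    def __post_init__(self) -> None:
        for name in ("delta_min", "ratio_intercept", "ratio_slope", "eligibility_min_freq"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def smoothed_frequency(a, b):
    """Add-one-smoothed document frequency (a+1)/(b+1); strictly positive.

    Accepts scalars or arrays; raises when any count is inconsistent
    (a < 0 or a > b).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(a < 0) or np.any(a > b):
        raise ValueError("word counts must satisfy 0 <= a <= b")
    out = (a + 1.0) / (b + 1.0)
    return float(out) if out.ndim == 0 else out


def project_counterfactual(p3, p2):
    """Counterfactual frequency q = p2 + 2*max(p2 - p3, 0), clamped to <= 1.

    ``p3`` and ``p2`` are the frequencies three and two years before the
    analysis year. The projection is floored at p2, which makes downstream
    excess estimates conservative for any declining series.
    """
    p3 = np.asarray(p3, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    q = np.minimum(p2 + 2.0 * np.maximum(p2 - p3, 0.0), 1.0)
    return float(q) if q.ndim == 0 else q


def excess_metrics(p, q):
    """Excess ratio r = p/q and excess gap delta = p - q."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    r = p / q
    delta = p - q
    if r.ndim == 0:
        return float(r), float(delta)
    return r, delta


def flag_excess(p, r, delta, params: Optional[ThresholdParams] = None):
    """Excess-word call: delta > delta_min OR the ratio clears the
    frequency-dependent line (both strict; ties on either boundary are not
    excess)."""
    params = params or ThresholdParams()
    p = np.asarray(p, dtype=float)
    r = np.asarray(r, dtype=float)
    delta = np.asarray(delta, dtype=float)
    ratio_hit = np.log10(r) > params.ratio_intercept - params.ratio_slope * np.log10(p)
    out = (delta > params.delta_min) | ratio_hit
    return bool(out) if out.ndim == 0 else out


def load_annotations(path: str | Path) -> pd.DataFrame:
    """Load a word-annotation TSV with columns word, category, pos.

    Categories outside {content, style, ambiguous, unannotated} or POS tags
    outside {noun, verb, adjective, other, unannotated} are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("unannotated")
    missing = {"word", "category", "pos"} - set(df.columns)
    if missing:
        raise ValueError(f"annotation table lacks columns: {sorted(missing)}")
    bad = set(df["category"]) - set(CATEGORIES)
    if bad:
        raise ValueError(f"unknown annotation categories: {sorted(bad)}")
    bad = set(df["pos"]) - set(POS_TAGS)
    if bad:
        raise ValueError(f"unknown POS tags: {sorted(bad)}")
    return df[["word", "category", "pos"]].drop_duplicates("word")


def detect_excess_words(
    counts: YearCounts,
    year: int,
    params: Optional[ThresholdParams] = None,
    annotations: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Per-word excess metrics for analysis year ``year``.

    Eligibility requires smoothed frequency above ``eligibility_min_freq``
    in both ``year`` and ``year - 1``; ineligible words are absent from the
    output. The year before the analysis year is used *only* for
    eligibility — the projection always extrapolates from Y-3 and Y-2, so
    that a frequency shift already under way in Y-1 cannot contaminate the
    counterfactual. Rows are sorted by delta descending (ties by word).

    Returns a DataFrame with columns word, year, p, q, r, delta, eligible,
    excess, category, pos.
    """
    params = params or ThresholdParams()
    idx = {}
    for offset in (3, 2, 1, 0):
        try:
            idx[offset] = counts.year_index(year - offset)
        except KeyError as exc:
            raise ValueError(
                f"corpus lacks year {year - offset}, required for analysis year {year}"
            ) from exc
    freqs = counts.smoothed()
    p = freqs[idx[0]]
    p1 = freqs[idx[1]]
    p2 = freqs[idx[2]]
    p3 = freqs[idx[3]]
    eligible = (p > params.eligibility_min_freq) & (p1 > params.eligibility_min_freq)
    words = np.array(counts.vocabulary.words, dtype=object)[eligible]
    q = project_counterfactual(p3[eligible], p2[eligible])
    r, delta = excess_metrics(p[eligible], q)
    excess = flag_excess(p[eligible], r, delta, params)
    df = pd.DataFrame(
        {
            "word": words,
            "year": year,
            "p": p[eligible],
            "q": q,
            "r": r,
            "delta": delta,
            "eligible": True,
            "excess": excess,
        }
    )
    if annotations is not None:
        df = df.merge(annotations, on="word", how="left")
        df[["category", "pos"]] = df[["category", "pos"]].fillna("unannotated")
    else:
        df["category"] = "unannotated"
        df["pos"] = "unannotated"
    df = df.sort_values(["delta", "word"], ascending=[False, True], kind="mergesort")
    logger.info(
        "year %d: %d eligible words, %d excess", year, len(df), int(df["excess"].sum())
    )
    return df.reset_index(drop=True)


def load_word_map(path: str | Path) -> dict[str, str]:
    """Load a two-column TSV mapping (e.g. word -> lemma, British -> US)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["src", "dst"], dtype=str)
    return dict(zip(df["src"], df["dst"]))


def lemma_dedup(
    words: Iterable[str],
    lemma_map: Optional[Mapping[str, str]] = None,
    spelling_map: Optional[Mapping[str, str]] = None,
) -> set[str]:
    """Collapse words to their distinct lemmas.

    Each word is first spelling-normalized (e.g. British -> US) and then
    lemma-mapped; absent entries fall back to identity. Used for counting
    unique excess lemmas rather than inflected forms.
    """
    lemma_map = lemma_map or {}
    spelling_map = spelling_map or {}
    out = set()
    for w in words:
        w = spelling_map.get(w, w)
        out.add(lemma_map.get(w, w))
    return out
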