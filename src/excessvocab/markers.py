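"""Marker-word sets and set-level frequency gaps.

A marker set G is a collection of excess style words used jointly: the
observed fraction P_G of abstracts containing at least one word of G is
compared with the counterfactually expected fraction Q_G, and the gap
Delta_G = P_G - Q_G is read as a lower bound on the prevalence of the
process (LLM-assisted writing) driving the excess. Working with the
document-level presence indicator means no independence between the words
of G is assumed.

Two standard constructions are provided: a *rare* set assembled
automatically by sweeping a frequency threshold T over the excess style
words, and a small fixed *common* set of high-gap words. The mean of the
two gaps is the combined lower bound.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .excess import project_counterfactual, smoothed_frequency
from .vocabulary import OccurrenceMatrix

logger = logging.getLogger(__name__)

#: Fixed common set of high-gap style words.
COMMON_SET_WORDS = (
    "across", "additionally", "comprehensive", "crucial", "enhancing",
    "exhibited", "insights", "notably", "particularly", "within",
)

#: Reference set of pandemic content words, evaluated at year 2021 for the
#: historical comparison of effect sizes.
COVID_SET_WORDS = ("covid", "pandemic", "coronavirus", "sars")


@dataclass(frozen=True)
class MarkerSet:
    """A named word set with its construction provenance."""

    name: str
    words: frozenset[str]
    construction: str = "fixed-list"   # fixed-list | rare-sweep | covid-reference
    threshold: Optional[float] = None  # T for rare-sweep sets

    def __len__(self) -> int:
        return len(self.words)


@dataclass
class GapResult:
    """Set-level observed/expected presence frequencies and their gap."""

    set_name: str
    year: int
    P: float
    Q: float
    Delta: float
    n_docs: dict[int, int] = field(default_factory=dict)
    subgroup: Optional[str] = None


@dataclass
class SubgroupSpec:
    """Eligibility rules for per-subgroup gap estimates.

    A subgroup receives a Delta only if it has at least
    ``min_docs_per_year`` documents in *every* year of
    ``eligibility_years``. ``groups`` optionally defines pooled subgroups
    as name -> regex patterns matched against the metadata value (e.g.
    journal-name families).
    """

    key: str
    min_docs_per_year: int = 300
    eligibility_years: tuple[int, int] = (2018, 2023)
    groups: Optional[dict[str, str]] = None


def common_set() -> MarkerSet:
    """The frozen 10-word common marker set."""
    return MarkerSet("common", frozenset(COMMON_SET_WORDS), construction="fixed-list")


def covid_set() -> MarkerSet:
    """The four-word pandemic reference set (historical comparison)."""
    return MarkerSet("covid", frozenset(COVID_SET_WORDS), construction="covid-reference")


def marker_set_from_file(path, name: str = "custom") -> MarkerSet:
    """Read a marker set from a one-word-per-line text file."""
    with open(path, encoding="utf-8") as fh:
        words = frozenset(w.strip().lower() for w in fh if w.strip())
    return MarkerSet(name, words, construction="fixed-list")


def _presence_per_year(matrix: OccurrenceMatrix, G: MarkerSet):
    """Per-year (n_docs, n_present) for documents containing >=1 word of G.

    Words of G absent from the vocabulary contribute nothing.
    """
    cols = [matrix.vocabulary.index[w] for w in G.words if w in matrix.vocabulary]
    if cols:
        present = np.asarray(
            matrix.incidence[:, cols].sum(axis=1)
        ).ravel() > 0
    else:
        present = np.zeros(matrix.n_docs, dtype=bool)
    years = np.unique(matrix.row_years)
    n_docs = {int(y): int(np.sum(matrix.row_years == y)) for y in years}
    n_present = {int(y): int(np.sum(present[matrix.row_years == y])) for y in years}
    return n_docs, n_present


def set_presence_frequency(matrix: OccurrenceMatrix, G: MarkerSet, year: int) -> float:
    """Smoothed fraction P of ``year``'s documents containing >=1 word of G.

    Uses the same (count+1)/(n+1) smoothing as single-word frequencies and
    makes no independence assumption between the words of G.
    """
    n_docs, n_present = _presence_per_year(matrix, G)
    if year not in n_docs:
        raise KeyError(f"year {year} not present in the corpus")
    return smoothed_frequency(n_present[year], n_docs[year])


def set_gap(matrix: OccurrenceMatrix, G: MarkerSet, year: int) -> GapResult:
    """Set-level gap Delta = P(Y) - Q where Q projects the set-level
    presence series from Y-3 and Y-2 with the word-level counterfactual."""
    n_docs, n_present = _presence_per_year(matrix, G)
    for y in (year - 3, year - 2, year):
        if y not in n_docs:
            raise ValueError(f"year {y} missing; set gap at {year} needs Y-3, Y-2 and Y")
    P3 = smoothed_frequency(n_present[year - 3], n_docs[year - 3])
    P2 = smoothed_frequency(n_present[year - 2], n_docs[year - 2])
    P = smoothed_frequency(n_present[year], n_docs[year])
    Q = project_counterfactual(P3, P2)
    return GapResult(
        set_name=G.name,
        year=year,
        P=P,
        Q=Q,
        Delta=P - Q,
        n_docs={y: n_docs[y] for y in (year - 3, year - 2, year)},
    )


def build_rare_set(excess_table: pd.DataFrame, T: float, year: int,
                   warn_empty: bool = True) -> MarkerSet:
    """All excess style words of ``year`` with frequency p strictly below T."""
    rows = excess_table[
        (excess_table["year"] == year)
        & excess_table["excess"]
        & (excess_table["category"] == "style")
        & (excess_table["p"] < T)
    ]
    words = frozenset(rows["word"])
    if not words and warn_empty:
        logger.warning("rare set at T=%g is empty; its gap will be reported as 0", T)
    return MarkerSet(f"rare(T={T:g})", words, construction="rare-sweep", threshold=T)


def default_threshold_grid() -> np.ndarray:
    """Logarithmic sweep grid from 1e-4 to 0.5 (25 points) plus T=0.02."""
    grid = np.geomspace(1e-4, 0.5, 25)
    return np.unique(np.append(grid, 0.02))


def sweep_threshold(
    excess_table: pd.DataFrame,
    matrix: OccurrenceMatrix,
    year: int,
    T_grid: Optional[Sequence[float]] = None,
) -> tuple[float, pd.DataFrame]:
    """Gap of the rare set as a function of the frequency threshold T.

    Returns (best_T, curve); best_T maximizes Delta_rare with ties broken
    toward the smallest T. The curve is not assumed monotone — adding a
    high-baseline word to a set can dilute its gap.
    """
    grid = np.sort(np.asarray(T_grid if T_grid is not None else default_threshold_grid(),
                              dtype=float))
    if grid.size == 0:
        raise ValueError("threshold grid is empty")
    rows = []
    for T in grid:
        G = build_rare_set(excess_table, float(T), year, warn_empty=False)
        if len(G) == 0:
            rows.append({"T": float(T), "n_words": 0, "P": np.nan, "Q": np.nan,
                         "Delta": 0.0})
            continue
        gap = set_gap(matrix, G, year)
        rows.append({"T": float(T), "n_words": len(G), "P": gap.P, "Q": gap.Q,
                     "Delta": gap.Delta})
    curve = pd.DataFrame(rows)
    best_T = float(curve.loc[curve["Delta"].idxmax(), "T"])  # idxmax -> first/smallest T
    return best_T, curve


def combined_bound(delta_rare: float, delta_common: float) -> float:
    """Combined lower bound: the arithmetic mean of the two set gaps."""
    return (delta_rare + delta_common) / 2.0


def subgroup_gaps(
    matrix: OccurrenceMatrix,
    key: str,
    sets: Iterable[MarkerSet],
    spec: SubgroupSpec,
    year: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subgroup set gaps with eligibility screening.

    Subgroups are the distinct values of metadata column ``key`` (or the
    pooled groups of ``spec.groups``, regexes matched against that column).
    Counterfactual years are computed *within* each subgroup. Returns
    (results, excluded) where ``excluded`` lists ineligible subgroups with
    a reason.
    """
    if key not in matrix.row_meta.columns:
        raise KeyError(f"unknown metadata key {key!r}")
    values = matrix.row_meta[key].astype(object)
    if spec.groups:
        members = {
            name: values.str.contains(pattern, regex=True, na=False).to_numpy()
            for name, pattern in spec.groups.items()
        }
    else:
        members = {
            str(v): (values == v).to_numpy()
            for v in sorted(values.dropna().unique(), key=str)
        }
    results, excluded = [], []
    lo, hi = spec.eligibility_years
    sets = list(sets)
    for name, mask in members.items():
        sub_years = matrix.row_years[mask]
        reason = None
        for y in range(lo, hi + 1):
            n = int(np.sum(sub_years == y))
            if n < spec.min_docs_per_year:
                reason = f"{n} docs in {y} < {spec.min_docs_per_year}"
                break
        if reason is not None:
            excluded.append({"subgroup": name, "reason": reason})
            continue
        sub = matrix.subset(mask)
        for G in sets:
            gap = set_gap(sub, G, year)
            gap.subgroup = name
            results.append(
                {
                    "set_name": gap.set_name, "subgroup": name, "year": year,
                    "P": gap.P, "Q": gap.Q, "Delta": gap.Delta,
                    "n_docs_Y": gap.n_docs[year],
                }
            )
    return pd.DataFrame(results), pd.DataFrame(excluded, columns=["subgroup", "reason"])


def greedy_common_set(
    excess_table: pd.DataFrame,
    matrix: OccurrenceMatrix,
    year: int,
    size: int = 10,
    n_candidates: int = 30,
) -> MarkerSet:
    """Exploratory greedy alternative to the frozen common set.

    Starting from the empty set, repeatedly adds the candidate word (drawn
    from the ``n_candidates`` highest-delta excess style words) that most
    increases the set gap. Purely optional: the canonical common set is the
    frozen list, this search is provided for sensitivity analyses only.
    """
    style = excess_table[
        (excess_table["year"] == year)
        & excess_table["excess"]
        & (excess_table["category"] == "style")
    ]
    candidates = list(style.nlargest(n_candidates, "delta")["word"])
    chosen: set[str] = set()
    best_delta = -np.inf
    for _ in range(size):
        best_word = None
        for w in candidates:
            if w in chosen:
                continue
            G = MarkerSet("greedy", frozenset(chosen | {w}))
            delta = set_gap(matrix, G, year).Delta
            if delta > best_delta:
                best_delta, best_word = delta, w
        if best_word is None:
            break
        chosen.add(best_word)
    return MarkerSet("greedy-common", frozenset(chosen), construction="fixed-list")
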