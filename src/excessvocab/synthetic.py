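"""Synthetic corpora with known ground truth.

The generator emulates the statistical regimes seen in real abstract
corpora — flat words, words with linear frequency trends, event-driven
spikes, and LLM marker words — without any linguistic realism. Each
profiled word is included in each document as an independent Bernoulli
draw; a fraction lambda of documents from the adoption year onward is
"LLM-processed", which boosts the inclusion probability of marker words.
Independence gives closed-form presence probabilities

    P0 = 1 - prod_w (1 - f_w)        (documents left untouched)
    P1 = 1 - prod_w (1 - b_w)        (LLM-processed documents)

for any word set, so the expected set-level gap lambda * (P1 - P0) is
available analytically for recovery tests. Real text violates the
independence assumption; see the methods note for what that does and does
not imply.

Filler tokens from a reserved "zz"-prefixed vocabulary pad every document
to the 250-character minimum; they appear in every document, are perfectly
stationary, and never enter marker sets.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .corpus import AbstractRecord, CorpusStore

ROLE_STABLE = "stable"
ROLE_TRENDING = "trending"
ROLE_EVENT = "event"
ROLE_MARKER = "marker"
ROLES = (ROLE_STABLE, ROLE_TRENDING, ROLE_EVENT, ROLE_MARKER)

FILLER_WORDS = (
    "zzaleph", "zzbryo", "zzcrane", "zzdelta",
    "zzember", "zzfjord", "zzgale", "zzhollow",
)
# fixed pad appended to every document so the 250-char length filter passes
_pad_tokens: list[str] = []
while len(" ".join(_pad_tokens)) < 250:
    _pad_tokens.append(FILLER_WORDS[len(_pad_tokens) % len(FILLER_WORDS)])
FILLER_PAD = " ".join(_pad_tokens)


@dataclass
class WordProfile:
    """Generation profile of one word.

    ``base_freq`` is the per-document inclusion probability in the first
    simulated year; ``slope`` adds a linear per-year change. Event words
    gain ``event_boost`` from ``event_year`` onward. Marker words are
    included with probability ``marker_boost`` (instead of the base
    frequency) in LLM-processed documents.
    """

    word: str
    base_freq: float
    slope: float = 0.0
    role: str = ROLE_STABLE
    event_year: Optional[int] = None
    event_boost: float = 0.0
    marker_boost: Optional[float] = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown word role {self.role!r}")
        if not 0.0 <= self.base_freq <= 1.0:
            raise ValueError(f"{self.word}: base_freq outside [0, 1]")
        if self.role == ROLE_MARKER:
            if self.marker_boost is None:
                raise ValueError(f"{self.word}: marker words need a marker_boost")
            if not 0.0 <= self.marker_boost <= 1.0:
                raise ValueError(f"{self.word}: marker_boost outside [0, 1]")
            if self.marker_boost < self.base_freq:
                raise ValueError(f"{self.word}: marker_boost must be >= base_freq")
        if self.role == ROLE_EVENT and self.event_year is None:
            raise ValueError(f"{self.word}: event words need an event_year")

    def probability(self, year: int, start_year: int) -> float:
        """Inclusion probability for a non-LLM document in ``year``."""
        f = self.base_freq + self.slope * (year - start_year)
        if self.role == ROLE_EVENT and year >= self.event_year:
            f += self.event_boost
        return float(min(max(f, 0.0), 1.0))


@dataclass
class SimulationConfig:
    """Full description of one simulated corpus."""

    years: tuple[int, int]
    docs_per_year: int
    profiles: list[WordProfile]
    adoption_year: int
    lam: float
    seed: int
    # optional per-country adoption rates; documents are assigned countries
    # round-robin and each country gets its own lambda
    country_lambdas: Optional[dict[str, float]] = None

    def __post_init__(self) -> None:
        lo, hi = self.years
        if lo > hi:
            raise ValueError("years range is empty")
        if not lo <= self.adoption_year <= hi + 1:
            raise ValueError("adoption_year must lie within the simulated years")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")
        if self.country_lambdas is not None:
            for c, l in self.country_lambdas.items():
                if not 0.0 <= l <= 1.0:
                    raise ValueError(f"lambda for country {c!r} outside [0, 1]")
        names = [p.word for p in self.profiles]
        if len(names) != len(set(names)):
            raise ValueError("duplicate word profiles")

    def marker_words(self) -> list[str]:
        return [p.word for p in self.profiles if p.role == ROLE_MARKER]

    def profile(self, word: str) -> WordProfile:
        for p in self.profiles:
            if p.word == word:
                return p
        raise KeyError(f"word {word!r} is not profiled")


@dataclass
class GroundTruth:
    """Recorded truth of a simulated corpus: per-document LLM flags plus
    the generating configuration (which yields analytic expectations)."""

    config: SimulationConfig
    llm_flags: pd.DataFrame = field(repr=False)  # columns: id, year, country, llm

    def expected_gap(self, words: Sequence[str], year: int,
                     lam: Optional[float] = None) -> float:
        return analytic_expected_gap(self.config, words, year, lam=lam)


def generate_corpus(config: SimulationConfig) -> tuple[CorpusStore, GroundTruth]:
    """Generate a corpus; byte-identical for identical configs and seeds.

    For each year, ``docs_per_year`` documents are drawn; each document is
    independently LLM-flagged with probability lambda once the adoption
    year is reached, and each profiled word is included independently with
    its regime probability. Document text is the space-joined included
    words followed by the deterministic filler pad.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.years
    store = CorpusStore()
    flag_rows = []
    if config.country_lambdas:
        countries = sorted(config.country_lambdas)
        lam_by_country = np.array([config.country_lambdas[c] for c in countries])
    for year in range(lo, hi + 1):
        n = config.docs_per_year
        if config.country_lambdas:
            country_idx = np.arange(n) % len(countries)
            lam_vec = lam_by_country[country_idx]
        else:
            country_idx = None
            lam_vec = np.full(n, config.lam)
        if year < config.adoption_year:
            lam_vec = np.zeros(n)
        llm = rng.random(n) < lam_vec
        tokens: list[list[str]] = [[] for _ in range(n)]
        for prof in config.profiles:
            base = prof.probability(year, lo)
            probs = np.full(n, base)
            if prof.role == ROLE_MARKER:
                probs[llm] = prof.marker_boost
            included = np.nonzero(rng.random(n) < probs)[0]
            for i in included:
                tokens[i].append(prof.word)
        for i in range(n):
            doc_id = f"syn-{year}-{i:06d}"
            content = " ".join(tokens[i])
            text = f"{content} {FILLER_PAD}" if content else FILLER_PAD
            country = countries[country_idx[i]] if country_idx is not None else None
            store.records.append(
                AbstractRecord(id=doc_id, year=year, text=text, country=country)
            )
            flag_rows.append(
                {"id": doc_id, "year": year, "country": country, "llm": bool(llm[i])}
            )
    truth = GroundTruth(config=config, llm_flags=pd.DataFrame(flag_rows))
    return store, truth


def analytic_expected_gap(
    config: SimulationConfig,
    words: Sequence[str],
    year: int,
    lam: Optional[float] = None,
) -> float:
    """Expected set-level gap lambda * (P1 - P0) under the independence
    model, with base frequencies evaluated at ``year``.

    Raises ``KeyError`` for any unprofiled word. ``lam`` overrides the
    configured adoption rate (useful for per-country expectations).
    """
    lo, _hi = config.years
    not_in_plain = 1.0
    not_in_llm = 1.0
    for w in words:
        prof = config.profile(w)
        f = prof.probability(year, lo)
        b = prof.marker_boost if prof.role == ROLE_MARKER else f
        not_in_plain *= 1.0 - f
        not_in_llm *= 1.0 - b
    p0 = 1.0 - not_in_plain
    p1 = 1.0 - not_in_llm
    lam_eff = config.lam if lam is None else lam
    if year < config.adoption_year:
        lam_eff = 0.0
    return lam_eff * (p1 - p0)


def _word_names(prefix: str, n: int) -> list[str]:
    """Deterministic alphabetic word names: prefix + 3 lowercase letters."""
    letters = string.ascii_lowercase
    out = []
    for combo in itertools.product(letters, repeat=3):
        out.append(prefix + "".join(combo))
        if len(out) == n:
            return out
    raise ValueError("too many names requested")


def injection_config(
    lam: float = 0.15,
    docs_per_year: int = 50_000,
    years: tuple[int, int] = (2019, 2024),
    adoption_year: int = 2024,
    n_markers: int = 20,
    marker_base_freq: float = 1e-3,
    target_presence_lift: float = 0.80,
    seed: int = 0,
    country_lambdas: Optional[dict[str, float]] = None,
) -> SimulationConfig:
    """Standard LLM-injection scenario.

    ``n_markers`` marker words share a base frequency; their boost is
    solved in closed form so that the analytic presence lift P1 - P0 of
    the full marker set equals ``target_presence_lift`` — at the defaults
    the expected combined gap is lambda * 0.80 = 0.12. A background of
    stable words across four decades of frequency, one trending word and
    one event word exercise the counterfactual machinery.
    """
    p0 = 1.0 - (1.0 - marker_base_freq) ** n_markers
    p1 = p0 + target_presence_lift
    if not 0.0 < p1 <= 1.0:
        raise ValueError("target presence lift is unattainable at this base frequency")
    boost = 1.0 - (1.0 - p1) ** (1.0 / n_markers)
    profiles = [
        WordProfile(w, base_freq=marker_base_freq, role=ROLE_MARKER, marker_boost=boost)
        for w in _word_names("mark", n_markers)
    ]
    background_freqs = np.geomspace(5e-4, 0.2, 18)
    profiles += [
        WordProfile(w, base_freq=float(f))
        for w, f in zip(_word_names("back", 18), background_freqs)
    ]
    profiles.append(WordProfile("trendward", base_freq=0.02, slope=0.004,
                                role=ROLE_TRENDING))
    profiles.append(WordProfile("eventide", base_freq=1e-3, role=ROLE_EVENT,
                                event_year=years[0] + 1, event_boost=0.05))
    return SimulationConfig(
        years=years,
        docs_per_year=docs_per_year,
        profiles=profiles,
        adoption_year=adoption_year,
        lam=lam,
        seed=seed,
        country_lambdas=country_lambdas,
    )


def stationary_null_config(
    n_words: int = 2000,
    docs_per_year: int = 20_000,
    years: tuple[int, int] = (2021, 2024),
    seed: int = 0,
) -> SimulationConfig:
    """Stationary null scenario: no trends, no events, no injection.

    Word base frequencies are log-spaced from 2e-4 to 0.2, spanning the
    eligibility cutoff, so false-positive excess calls can be measured
    across the realistic frequency range.
    """
    freqs = np.geomspace(2e-4, 0.2, n_words)
    profiles = [
        WordProfile(w, base_freq=float(f))
        for w, f in zip(_word_names("null", n_words), freqs)
    ]
    return SimulationConfig(
        years=years,
        docs_per_year=docs_per_year,
        profiles=profiles,
        adoption_year=years[1] + 1,  # never adopted
        lam=0.0,
        seed=seed,
    )


def synthetic_annotations(config: SimulationConfig) -> pd.DataFrame:
    """Annotation table for a simulated corpus: markers are style words
    (verbs), everything else profiled is a content noun."""
    rows = [
        {
            "word": p.word,
            "category": "style" if p.role == ROLE_MARKER else "content",
            "pos": "verb" if p.role == ROLE_MARKER else "noun",
        }
        for p in config.profiles
    ]
    return pd.DataFrame(rows, columns=["word", "category", "pos"])
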