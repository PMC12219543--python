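"""Tokenization and the binary document-word occurrence matrix.

The vocabulary is restricted to lowercase words of at least four letters
composed only of the 26 ASCII letters; any other character (digits,
hyphens, apostrophes, accented letters) splits token runs. Occurrence is
binary: a word either appears in an abstract or it does not, and
inflections (mask / masks) remain distinct words.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from sklearn.feature_extraction.text import CountVectorizer

from .corpus import CorpusStore

logger = logging.getLogger(__name__)

_LETTER_RUN = re.compile(r"[A-Za-z]+")
MIN_WORD_LEN = 4


def tokenize(text: str) -> set[str]:
    """Return the set of normalized words occurring in ``text``.

    Tokens are maximal runs of ASCII letters, lowercased; runs shorter than
    four letters are discarded. Duplicates collapse because occurrence is
    binary.
    """
    return {run.lower() for run in _LETTER_RUN.findall(text) if len(run) >= MIN_WORD_LEN}


@dataclass
class Vocabulary:
    words: list[str]            # ordered (alphabetical), unique, lowercase
    index: dict[str, int]       # word -> column position

    @classmethod
    def from_words(cls, words) -> "Vocabulary":
        words = list(words)
        return cls(words=words, index={w: i for i, w in enumerate(words)})

    def __len__(self) -> int:
        return len(self.words)

    def __contains__(self, word: str) -> bool:
        return word in self.index


@dataclass
class OccurrenceMatrix:
    """Sparse binary documents x words incidence with per-row metadata.

    ``row_meta`` holds id/journal/country/field columns aligned with rows.
    """

    incidence: sp.csr_matrix
    vocabulary: Vocabulary
    row_years: np.ndarray
    row_meta: pd.DataFrame

    @property
    def n_docs(self) -> int:
        return self.incidence.shape[0]

    def subset(self, mask: np.ndarray) -> "OccurrenceMatrix":
        """Row-subset the matrix (boolean mask or index array)."""
        return OccurrenceMatrix(
            incidence=self.incidence[mask],
            vocabulary=self.vocabulary,
            row_years=self.row_years[mask],
            row_meta=self.row_meta.iloc[np.nonzero(mask)[0] if mask.dtype == bool else mask]
            .reset_index(drop=True),
        )


@dataclass
class YearCounts:
    """Per-year document totals (b) and per-word document counts (a)."""

    years: np.ndarray           # sorted unique years
    n_docs: np.ndarray          # per-year totals, aligned with `years`
    doc_counts: np.ndarray      # (n_years, n_words) word-in-year counts
    vocabulary: Vocabulary

    @classmethod
    def from_matrix(cls, matrix: OccurrenceMatrix) -> "YearCounts":
        years = np.unique(matrix.row_years)
        counts = np.zeros((len(years), len(matrix.vocabulary)), dtype=np.int64)
        n_docs = np.zeros(len(years), dtype=np.int64)
        for i, y in enumerate(years):
            rows = matrix.row_years == y
            n_docs[i] = int(rows.sum())
            counts[i] = np.asarray(matrix.incidence[rows].sum(axis=0)).ravel()
        return cls(years=years, n_docs=n_docs, doc_counts=counts,
                   vocabulary=matrix.vocabulary)

    def year_index(self, year: int) -> int:
        idx = np.searchsorted(self.years, year)
        if idx >= len(self.years) or self.years[idx] != year:
            raise KeyError(f"year {year} not present in the corpus")
        return int(idx)

    def smoothed(self) -> np.ndarray:
        """Smoothed frequencies p = (a+1)/(b+1), shape (n_years, n_words)."""
        return (self.doc_counts + 1.0) / (self.n_docs[:, None] + 1.0)


def build_matrix(
    store: CorpusStore,
    min_doc_frac: float = 1e-6,
) -> tuple[Vocabulary, OccurrenceMatrix, YearCounts]:
    """Build the binary occurrence matrix over a corpus.

    Words occurring in fewer than ``min_doc_frac`` x (number of documents)
    documents are excluded from the vocabulary. The alphabetic >=4-letter
    restriction is applied by the tokenizer before the frequency cutoff;
    both the raw and the retained vocabulary sizes are logged.
    """
    if len(store) == 0:
        raise ValueError("cannot build a matrix from an empty corpus")
    texts = [rec.text for rec in store.records]
    vectorizer = CountVectorizer(
        analyzer=tokenize, binary=True, min_df=float(min_doc_frac), dtype=np.int8
    )
    try:
        incidence = vectorizer.fit_transform(texts)
    except ValueError as exc:
        raise ValueError(
            f"empty vocabulary after tokenization and min_doc_frac={min_doc_frac} cutoff"
        ) from exc
    words = [str(w) for w in vectorizer.get_feature_names_out()]
    vocab = Vocabulary.from_words(words)
    logger.info(
        "matrix: %d docs x %d words (min_doc_frac=%g)",
        incidence.shape[0], incidence.shape[1], min_doc_frac,
    )
    matrix = OccurrenceMatrix(
        incidence=incidence.tocsr(),
        vocabulary=vocab,
        row_years=np.array([rec.year for rec in store.records], dtype=np.int64),
        row_meta=pd.DataFrame(
            {
                "id": [rec.id for rec in store.records],
                "journal": [rec.journal for rec in store.records],
                "country": [rec.country for rec in store.records],
                "field": [rec.field for rec in store.records],
            }
        ),
    )
    counts = YearCounts.from_matrix(matrix)
    return vocab, matrix, counts


def save_matrix(matrix: OccurrenceMatrix, outdir: str | Path) -> None:
    """Persist an occurrence matrix as MatrixMarket + TSV sidecars."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(outdir / "incidence.mtx"), matrix.incidence)
    pd.Series(matrix.vocabulary.words, name="word").to_csv(
        outdir / "vocabulary.tsv", sep="\t", index=False
    )
    meta = matrix.row_meta.copy()
    meta.insert(1, "year", matrix.row_years)
    meta.to_csv(outdir / "rows.tsv", sep="\t", index=False)


def load_matrix(outdir: str | Path) -> OccurrenceMatrix:
    """Load an occurrence matrix written by :func:`save_matrix`."""
    outdir = Path(outdir)
    incidence = sp.csr_matrix(scipy.io.mmread(str(outdir / "incidence.mtx")), dtype=np.int8)
    words = pd.read_csv(outdir / "vocabulary.tsv", sep="\t")["word"].astype(str).tolist()
    meta = pd.read_csv(outdir / "rows.tsv", sep="\t")
    years = meta.pop("year").to_numpy(dtype=np.int64)
    meta["id"] = meta["id"].astype(str)
    return OccurrenceMatrix(
        incidence=incidence,
        vocabulary=Vocabulary.from_words(words),
        row_years=years,
        row_meta=meta,
    )
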