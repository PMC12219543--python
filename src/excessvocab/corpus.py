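"""Corpus data model and I/O.

A corpus is an ordered collection of year-stamped abstract records. Two
dialects are supported: the package's native line-delimited JSON format
(one record per line, UTF-8) and PubMed baseline XML (optionally
gzip-compressed). Cleaning rules remove contaminating boilerplate strings
(publisher notices, citation footers) or drop whole records (errata,
corrigenda, retraction notices identified by their titles).
"""

from __future__ import annotations

import dataclasses
import gzip
import json
import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

from lxml import etree

logger = logging.getLogger(__name__)

NATIVE_DIALECT = "native-jsonl"
PUBMED_DIALECT = "pubmed-xml"

STRIP_MATCH = "strip-match"
DROP_DOCUMENT = "drop-document"


@dataclass
class AbstractRecord:
    """One year-stamped document.

    ``flags`` carries free-form metadata (e.g. the article title under the
    key ``"title"``, used by drop-document cleaning rules).
    """

    id: str
    year: int
    text: str
    journal: Optional[str] = None
    country: Optional[str] = None
    field: Optional[str] = None
    flags: dict[str, str] = dataclasses.field(default_factory=dict)


@dataclass
class CleaningRule:
    """A single cleaning rule: a regex plus an action.

    ``strip-match`` removes every matched span from the abstract text;
    ``drop-document`` removes the whole record when the pattern matches the
    title (or, lacking a title, the head of the text). Rules are applied in
    file order.
    """

    pattern: str
    action: str
    description: str = ""

    def __post_init__(self) -> None:
        if self.action not in (STRIP_MATCH, DROP_DOCUMENT):
            raise ValueError(f"unknown cleaning action {self.action!r}")
        self.regex = re.compile(self.pattern, re.MULTILINE)


@dataclass
class CorpusStore:
    """Ordered collection of :class:`AbstractRecord` with parse-skip count."""

    records: list[AbstractRecord] = field(default_factory=list)
    n_skipped: int = 0

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[AbstractRecord]:
        return iter(self.records)

    @property
    def year_counts(self) -> Counter:
        """Mapping year -> number of stored records with that year."""
        return Counter(r.year for r in self.records)


def read_corpus(path: str | Path, dialect: str = NATIVE_DIALECT) -> CorpusStore:
    """Read a corpus file in the given dialect.

    Records that fail to parse (malformed line, missing abstract or year)
    are counted in ``store.n_skipped`` and logged, never silently dropped.
    An unreadable file raises.
    """
    path = Path(path)
    if dialect == NATIVE_DIALECT:
        return _read_native(path)
    if dialect == PUBMED_DIALECT:
        return _read_pubmed_xml(path)
    raise ValueError(f"unknown corpus dialect {dialect!r}")


def _read_native(path: Path) -> CorpusStore:
    store = CorpusStore()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
                rec = AbstractRecord(
                    id=str(obj["id"]),
                    year=int(obj["year"]),
                    text=str(obj["text"]),
                    journal=obj.get("journal"),
                    country=obj.get("country"),
                    field=obj.get("field"),
                    flags=dict(obj.get("flags") or {}),
                )
                if not rec.text:
                    raise ValueError("empty text")
            except (KeyError, ValueError, TypeError) as exc:
                store.n_skipped += 1
                logger.warning("%s:%d: skipping malformed record (%s)", path, lineno, exc)
                continue
            store.records.append(rec)
    logger.info("read %d records (%d skipped) from %s", len(store), store.n_skipped, path)
    return store


def write_corpus(store: CorpusStore, path: str | Path) -> None:
    """Write a corpus in the native line-delimited dialect (lossless)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for rec in store.records:
            obj = {
                "id": rec.id,
                "year": rec.year,
                "text": rec.text,
                "journal": rec.journal,
                "country": rec.country,
                "field": rec.field,
                "flags": rec.flags,
            }
            fh.write(json.dumps(obj, ensure_ascii=False, sort_keys=True) + "\n")


def _text_of(elem) -> str:
    return "".join(elem.itertext()).strip()


def _pubmed_year(article) -> Optional[int]:
    for xp in (
        ".//ArticleDate/Year",
        ".//Journal/JournalIssue/PubDate/Year",
        ".//PubmedData//PubMedPubDate[@PubStatus='pubmed']/Year",
    ):
        hit = article.find(xp)
        if hit is not None and hit.text and hit.text.strip().isdigit():
            return int(hit.text.strip())
    md = article.find(".//Journal/JournalIssue/PubDate/MedlineDate")
    if md is not None and md.text:
        m = re.search(r"\b(19|20)\d\d\b", md.text)
        if m:
            return int(m.group(0))
    return None


def _pubmed_country(article) -> Optional[str]:
    """Country of the first affiliation of the first author, by string tail."""
    aff = article.find(".//AuthorList/Author/AffiliationInfo/Affiliation")
    if aff is None or not aff.text:
        return None
    tail = aff.text.strip().rstrip(".").rsplit(",", 1)[-1].strip()
    # strip trailing e-mail addresses that PubMed appends to affiliations
    tail = re.sub(r"\S+@\S+", "", tail).strip().rstrip(".").strip()
    return tail or None


def _read_pubmed_xml(path: Path) -> CorpusStore:
    store = CorpusStore()
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rb") as fh:
        for _event, article in etree.iterparse(fh, events=("end",), tag="PubmedArticle"):
            pmid = article.findtext(".//MedlineCitation/PMID")
            lang = article.findtext(".//Article/Language")
            abstract_parts = article.findall(".//Article/Abstract/AbstractText")
            text = " ".join(filter(None, (_text_of(p) for p in abstract_parts)))
            year = _pubmed_year(article)
            if lang is not None and lang != "eng":
                # language filtering relies on the PubMed language tag
                article.clear()
                continue
            if not pmid or not text or year is None:
                store.n_skipped += 1
                logger.warning("%s: skipping PMID=%s (missing abstract or year)", path, pmid)
                article.clear()
                continue
            title = article.findtext(".//Article/ArticleTitle") or ""
            rec = AbstractRecord(
                id=pmid.strip(),
                year=year,
                text=text,
                journal=article.findtext(".//Journal/Title"),
                country=_pubmed_country(article),
                flags={"title": title} if title else {},
            )
            store.records.append(rec)
            article.clear()
    logger.info("read %d records (%d skipped) from %s", len(store), store.n_skipped, path)
    return store


def load_cleaning_rules(path: str | Path) -> list[CleaningRule]:
    """Load cleaning rules from a plain-text file.

    Format: one rule per line, tab-separated ``action<TAB>pattern<TAB>description``;
    lines starting with ``#`` and blank lines are ignored. Rules apply in
    file order.
    """
    rules = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'action<TAB>pattern'")
            action, pattern = parts[0].strip(), parts[1]
            desc = parts[2] if len(parts) > 2 else ""
            rules.append(CleaningRule(pattern=pattern, action=action, description=desc))
    return rules


def clean_text(
    text: str,
    rules: Sequence[CleaningRule],
    title: Optional[str] = None,
) -> Optional[str]:
    """Apply cleaning rules to one document; return the cleaned text or
    ``None`` when a drop-document rule fires.

    Drop rules match against the title when available, otherwise against
    the first 200 characters of the text.
    """
    drop_target = title if title else text[:200]
    for rule in rules:
        if rule.action == DROP_DOCUMENT:
            if rule.regex.search(drop_target):
                return None
        else:
            text = rule.regex.sub("", text)
    return text


def clean_corpus(store: CorpusStore, rules: Sequence[CleaningRule]) -> CorpusStore:
    """Apply cleaning rules to every record; drops and modifications are logged."""
    out = CorpusStore(n_skipped=store.n_skipped)
    n_dropped = n_modified = 0
    for rec in store.records:
        cleaned = clean_text(rec.text, rules, title=rec.flags.get("title"))
        if cleaned is None:
            n_dropped += 1
            continue
        if cleaned != rec.text:
            n_modified += 1
            rec = dataclasses.replace(rec, text=cleaned)
        out.records.append(rec)
    logger.info(
        "cleaning: %d in -> %d out (%d dropped, %d modified)",
        len(store), len(out), n_dropped, n_modified,
    )
    return out


def filter_corpus(
    store: CorpusStore,
    min_len: int = 250,
    max_len: int = 4000,
    years: tuple[int, int] = (2010, 2024),
) -> CorpusStore:
    """Keep records whose text length lies in [min_len, max_len] characters
    and whose year lies in the inclusive ``years`` range.

    Emits a per-stage count log; an empty result is legal but logged as a
    warning. Survivor count + dropped count always equals the input count.
    """
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    lo, hi = years
    out = CorpusStore(n_skipped=store.n_skipped)
    for rec in store.records:
        if min_len <= len(rec.text) <= max_len and lo <= rec.year <= hi:
            out.records.append(rec)
    logger.info(
        "filter: %d in -> %d out (length %d-%d chars, years %d-%d)",
        len(store), len(out), min_len, max_len, lo, hi,
    )
    if not out.records:
        logger.warning("filter produced an empty corpus")
    return out
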