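"""End-to-end analysis pipeline and report assembly.

Sequences corpus reading -> cleaning -> filtering -> occurrence matrix ->
excess-word detection -> rare-set threshold sweep -> common-set gap ->
combined lower bound -> optional subgroup gaps, writing TSV intermediates
plus a machine-readable JSON summary. Every filtering stage logs its
in/out counts; the summary records a configuration hash and library
versions for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import corpus as corpus_mod
from .corpus import filter_corpus, load_cleaning_rules, read_corpus
from .excess import ThresholdParams, detect_excess_words, load_annotations
from .markers import (
    SubgroupSpec,
    build_rare_set,
    combined_bound,
    common_set,
    covid_set,
    marker_set_from_file,
    set_gap,
    subgroup_gaps,
    sweep_threshold,
)
from .vocabulary import build_matrix

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Configuration of one end-to-end run."""

    corpus: Path
    outdir: Path
    analysis_year: int
    dialect: str = corpus_mod.NATIVE_DIALECT
    years: tuple[int, int] = (2010, 2024)
    min_len: int = 250
    max_len: int = 4000
    min_doc_frac: float = 1e-6
    thresholds: ThresholdParams = field(default_factory=ThresholdParams)
    cleaning_rules: Optional[Path] = None
    annotations: Optional[Path] = None
    common_set_file: Optional[Path] = None
    rare_T_grid: Optional[list[float]] = None
    subgroup_keys: list[str] = field(default_factory=list)
    subgroup_min_docs: int = 300
    subgroup_eligibility_years: Optional[tuple[int, int]] = None
    covid_reference_year: Optional[int] = None

    def __post_init__(self) -> None:
        self.corpus = Path(self.corpus)
        self.outdir = Path(self.outdir)
        if self.analysis_year - 3 < self.years[0]:
            raise ValueError("analysis year needs three prior years inside the year range")
        for p in (self.corpus, self.cleaning_rules, self.annotations, self.common_set_file):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


def _config_hash(config: AnalysisConfig) -> str:
    d = dataclasses.asdict(config)
    for k, v in d.items():
        if isinstance(v, Path):
            d[k] = str(v)
    return hashlib.sha256(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()


def _versions() -> dict[str, str]:
    import sklearn
    import scipy

    from . import __version__

    return {
        "excessvocab": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
    }


def run_pipeline(config: AnalysisConfig) -> dict:
    """Run the full analysis and write the report bundle to ``config.outdir``.

    Emits excess_words.tsv (per-word metrics at the analysis year),
    excess_counts_by_year.tsv (yearly excess-word counts split by
    content/style), sweep.tsv (rare-set gap vs threshold), gaps.tsv
    (rare/common/combined and any subgroup rows), and summary.json. The
    summary is byte-identical across reruns with the same inputs.
    """
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    Y = config.analysis_year

    stage = "ingest"
    try:
        store = read_corpus(config.corpus, config.dialect)
        if config.cleaning_rules is not None:
            stage = "clean"
            rules = load_cleaning_rules(config.cleaning_rules)
            store = corpus_mod.clean_corpus(store, rules)
        stage = "filter"
        store = filter_corpus(store, config.min_len, config.max_len, config.years)
        stage = "matrix"
        vocab, matrix, counts = build_matrix(store, config.min_doc_frac)
        ann = load_annotations(config.annotations) if config.annotations else None

        stage = "excess"
        excess = detect_excess_words(counts, Y, config.thresholds, ann)
        excess.to_csv(outdir / "excess_words.tsv", sep="\t", index=False)

        yearly_rows = []
        first_feasible = int(counts.years.min()) + 3
        for year in range(first_feasible, Y + 1):
            tab = (
                excess
                if year == Y
                else detect_excess_words(counts, year, config.thresholds, ann)
            )
            flagged = tab[tab["excess"]]
            yearly_rows.append(
                {
                    "year": year,
                    "n_excess": len(flagged),
                    "n_content": int((flagged["category"] == "content").sum()),
                    "n_style": int((flagged["category"] == "style").sum()),
                }
            )
        yearly = pd.DataFrame(yearly_rows)
        yearly.to_csv(outdir / "excess_counts_by_year.tsv", sep="\t", index=False)

        stage = "sweep"
        best_T, curve = sweep_threshold(excess, matrix, Y, config.rare_T_grid)
        curve.to_csv(outdir / "sweep.tsv", sep="\t", index=False)
        rare = build_rare_set(excess, best_T, Y)
        gap_rare = (
            set_gap(matrix, rare, Y)
            if len(rare)
            else None
        )
        delta_rare = gap_rare.Delta if gap_rare else 0.0

        stage = "gaps"
        if config.common_set_file is not None:
            common = marker_set_from_file(config.common_set_file, name="common")
        else:
            common = common_set()
        gap_common = set_gap(matrix, common, Y)
        delta_common = gap_common.Delta
        delta_combined = combined_bound(delta_rare, delta_common)

        gap_rows = [
            {"set_name": rare.name, "subgroup": "", "year": Y,
             "P": gap_rare.P if gap_rare else np.nan,
             "Q": gap_rare.Q if gap_rare else np.nan,
             "Delta": delta_rare, "n_words": len(rare)},
            {"set_name": common.name, "subgroup": "", "year": Y,
             "P": gap_common.P, "Q": gap_common.Q,
             "Delta": delta_common, "n_words": len(common)},
            {"set_name": "combined", "subgroup": "", "year": Y,
             "P": np.nan, "Q": np.nan, "Delta": delta_combined, "n_words": np.nan},
        ]

        covid_delta = None
        if config.covid_reference_year is not None:
            gap_covid = set_gap(matrix, covid_set(), config.covid_reference_year)
            covid_delta = gap_covid.Delta
            gap_rows.append(
                {"set_name": "covid", "subgroup": "",
                 "year": config.covid_reference_year,
                 "P": gap_covid.P, "Q": gap_covid.Q, "Delta": covid_delta,
                 "n_words": len(covid_set())}
            )

        subgroup_frames = []
        for key in config.subgroup_keys:
            spec = SubgroupSpec(
                key=key,
                min_docs_per_year=config.subgroup_min_docs,
                eligibility_years=(
                    config.subgroup_eligibility_years
                    if config.subgroup_eligibility_years is not None
                    else (Y - 6, Y - 1)
                ),
            )
            res, excl = subgroup_gaps(matrix, key, [rare, common], spec, Y)
            if not res.empty:
                res.insert(0, "key", key)
                subgroup_frames.append(res)
            for _, row in excl.iterrows():
                logger.info("subgroup %s=%s excluded: %s", key, row["subgroup"],
                            row["reason"])

        gaps = pd.DataFrame(gap_rows)
        gaps.to_csv(outdir / "gaps.tsv", sep="\t", index=False)
        if subgroup_frames:
            pd.concat(subgroup_frames, ignore_index=True).to_csv(
                outdir / "subgroup_gaps.tsv", sep="\t", index=False
            )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    summary = {
        "config_hash": _config_hash(config),
        "versions": _versions(),
        "n_docs": len(store),
        "n_words": len(vocab),
        "analysis_year": Y,
        "n_eligible": len(excess),
        "n_excess": int(excess["excess"].sum()),
        "n_excess_style": int(
            (excess["excess"] & (excess["category"] == "style")).sum()
        ),
        "best_T": best_T,
        "rare_set_size": len(rare),
        "delta_rare": delta_rare,
        "delta_common": delta_common,
        "delta_combined": delta_combined,
        "covid_delta": covid_delta,
    }
    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
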