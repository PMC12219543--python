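# Methods

## The excess-usage model

The package treats vocabulary change the way excess-mortality studies
treat death counts: compare what happened in the analysis year *Y* with a
counterfactual projection of what would have happened had pre-existing
trends simply continued. The unit of observation is the *document
frequency* of a word — the fraction of a year's abstracts containing it
at least once — not its token count, so a word used ten times in one
abstract counts once.

**Smoothing.** Every frequency is computed as p = (a+1)/(b+1), where *a*
is the number of abstracts in a year containing the word and *b* is the
year's abstract total. This add-one convention avoids division by zero in
ratios and makes every stored frequency strictly positive; at corpus
scale it is numerically indistinguishable from a/b.

**Counterfactual.** The projection q = p₋₂ + 2·max(p₋₂ − p₋₃, 0)
extrapolates the last two pre-effect years linearly, but clips declining
trends to flat and is clamped at 1. The clipping makes q ≥ p₋₂ always,
so both the ratio r = p/q and the gap δ = p − q are biased *against*
finding excess — a deliberately conservative choice, since the gap is
interpreted as a lower bound. The year Y−1 is excluded from the
projection (it may already carry the effect being measured) and is used
only for the eligibility screen.

**Eligibility and calling.** Only words with p > 10⁻⁴ in both Y and Y−1
are analysed; below that, ratio estimates are dominated by shot noise. A
word is called excess when δ > 0.01 or
log₁₀ r > log₁₀ 2 − ¼·log₁₀ p, both strict. The ratio line in (p, r)
log-log space passes through (10⁻⁴, 20) and (10⁻², ≈6.3): rarer words
must show proportionally larger fold-changes. Intercept and slope are
configuration (`ThresholdParams`), because a gap criterion appropriate
for one corpus size need not be appropriate for another.

**Set-level gaps.** For a word set G, presence P_G is the smoothed
fraction of abstracts containing ≥ 1 word of G, computed directly on the
document–word incidence matrix — no independence between the words of G
is assumed. The expected presence Q_G applies the same word-level
projection formula to the set-level presence series at Y−3 and Y−2. This
was a genuinely open design point (the expected fraction could instead be
assembled from per-word counterfactuals under an independence
assumption); projecting the observed presence series keeps the
conservativeness guarantee (Q_G ≥ P_G(Y−2)) intact at the set level and
needs no extra assumptions. Δ_G = P_G − Q_G is not monotone in G: adding
a high-baseline word saturates presence in all years and can dilute the
gap (the test suite contains an explicit counterexample), which is why
the rare-set threshold sweep must scan rather than grow greedily.

**Rare and common sets, combined bound.** The rare set at threshold T is
all excess *style* words of year Y with p < T (strict); Δ_rare(T) is
swept over a logarithmic grid from 10⁻⁴ to 0.5 (25 points, plus
T = 0.02), ties broken toward the smallest T. The common set is a frozen
10-word list — it was curated by hand, so re-optimizing it would be a
different procedure; a clearly-labelled greedy maximizer is available for
sensitivity analyses but is never used by the pipeline. The combined
bound is the arithmetic mean of the two gaps. A four-word pandemic
reference set (covid, pandemic, coronavirus, sars) evaluated at Y = 2021
is built in for historical comparison of effect sizes.

**Subgroups.** Per-subgroup gaps recompute the full counterfactual
*within* the subgroup (the alternative — rescaling global expectations —
would confound subgroup composition with subgroup adoption). A subgroup
is assigned a Δ only if it has ≥ 300 documents in every year of the
eligibility window (default: the six years before the analysis year);
pooled groups are defined by regex patterns over the metadata value, e.g.
journal-name families.

## Corpus handling

Native corpora are line-delimited JSON records (id, year, text, optional
journal/country/field/flags) — trivially writable by the generator and by
PubMed conversion. The PubMed XML reader keeps English-language records
(by the PubMed language tag; no language detector is bundled) and takes
the affiliation country from the tail of the first author's first
affiliation string. Cleaning rules are a plain-text inventory of regexes
with two actions: `strip-match` removes boilerplate spans (citation
footers, copyright lines), `drop-document` removes whole records whose
*titles* match (errata, corrigenda, retraction notices). The shipped rule
file is an illustrative starting inventory, not a complete one; real
corpora accumulate journal-specific contamination that must be curated
against the data, and excess-word lists from uncleaned corpora will
contain boilerplate artefacts. For native corpora the length filter
(250–4000 characters) is applied to the cleaned text; XML-derived corpora
are assumed filtered upstream at parse time.

Tokenization lowercases and keeps maximal runs of ASCII letters of
length ≥ 4; digits, hyphens, apostrophes and accented letters split runs.
Inflections are *not* collapsed at matrix build — they are distinct
excess signals — and a British→US spelling map plus a lemma map (both
two-column TSVs) are applied only when counting unique excess lemmas.
The incidence matrix is built with scikit-learn's CountVectorizer
(binary, `min_df` = the `min_doc_frac` parameter, default 10⁻⁶, computed
over the full analysed corpus in a single pass); the alphabetic filter
runs before the frequency cutoff.

## The synthetic generator

The generator's purpose is statistical, not linguistic: documents are
bags of independently-included profile words padded to the 250-character
minimum with a reserved `zz`-prefixed filler vocabulary (present in every
document, perfectly stationary, excluded from marker logic by
construction). Word profiles cover the regimes seen in real corpora:
stable words, linear trends, event spikes (boost from an event year
onward), and markers. A fraction λ of documents from the adoption year
onward is flagged LLM-processed; markers are included with probability
`marker_boost` in flagged documents and `base_freq` otherwise.
Independence gives closed forms P₀ = 1 − Π(1−f_w) and P₁ = 1 − Π(1−b_w)
for any set, hence an analytic expected gap λ·(P₁ − P₀) for recovery
tests.

Two standard scenarios define the study conditions:

* **Injection**: 6 years (2019–2024) × 50,000 docs/year, adoption in
  2024, λ = 0.15, 20 markers with base frequency 10⁻³ and a boost solved
  in closed form so the set's presence lift P₁ − P₀ is exactly 0.80
  (expected combined gap 0.120), over a background of 18 stable words
  log-spaced across 5×10⁻⁴–0.2, one trending word (+0.004/yr) and one
  event word. In pipeline recovery runs the sweep-built rare set and the
  known marker list (as the fixed set) play the roles of the rare/common
  pair.
* **Stationary null**: 4 years × 20,000 docs/year, 2,000 stable words
  log-spaced across 2×10⁻⁴–0.2 — a realistic document-frequency range
  straddling the eligibility cutoff — for measuring the false-positive
  excess-call rate (observed well below 1% of eligible words).

What passing these tests shows: the statistics, thresholds and set
machinery are implemented correctly and recover a known adoption rate
from data satisfying the generator's assumptions. What it does not show:
robustness to real-text phenomena the generator omits — word
co-occurrence and topical correlation, author-level style, secular
changes in abstract length, journal-specific boilerplate. On real
corpora the cleaning stage and human annotation of content vs. style
words carry that burden.

## Numerical and edge-case choices

* q is clamped at 1; P = Q gives r = 1, δ = 0, never excess. Ties exactly
  on δ = 0.01 or on the ratio line are not excess (strict inequalities).
* Empty rare sets (no excess style words below T) report Δ = 0 with a
  warning rather than failing; with equal yearly totals the smoothed
  empty-set presence is identical across years, so Δ is exactly 0.
* Excess tables sort by δ descending with the word as a deterministic
  tie-break; sweep ties resolve to the smallest T.
* Words of a marker set absent from the vocabulary contribute nothing to
  presence (they cannot lower it).
* Unannotated words are excluded from style-marker construction — absence
  of annotation is not evidence of style.
* The analysis year must have three prior years inside the corpus range;
  missing years are fatal, not imputed.
* Eligibility is evaluated on whatever corpus is passed in (full corpus
  or subcorpus), and subgroup counterfactuals are subgroup-specific.

## Problem sizes

The shipped tests exercise the full injection scenario (300,000
documents) and null scenario (80,000 documents, 2,000 words) directly;
smaller corpora (2,000–10,000 docs/year) are used where only correctness,
not statistical power, is at stake. The acceptance script regenerates
both large scenarios from scratch on every run.

## Known limitations

* The gap is a lower bound by construction: processed documents
  containing no marker word are invisible, and marker censoring by
  careful authors lowers the bound further. The method quantifies
  corpus-level prevalence and cannot classify individual documents.
* The counterfactual is linear in frequency over a two-year base; words
  with strongly convex organic growth can generate spurious excess, which
  is why threshold defaults were chosen so that pre-effect years produce
  essentially no excess calls.
* The shipped cleaning rules are examples; full-corpus results depend on
  a curated inventory.
* Lemma deduplication is table-driven; words absent from the map pass
  through unchanged.
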