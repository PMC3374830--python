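"""Evaluation of word-form learning: tallies, F-measures, summaries.

A session (or a whole experiment set) is scored by classifying lexicon
entries against the scenario dictionaries — *salient* words (the content
words being taught), *other words* (proper but non-salient, like "this"), and
*non-words* — and balancing them with the equally-weighted F-measure

    F = 2 tp / (2 tp + fp + fn).

Four variants are reported.  The "-1" variants score *real* reinforcement:
tp = salient words learnt, fn = salient words the learner produced but that
were never (correctly) reinforced, including heuristic failures.  The "-2"
variants score *simulated* reinforcement — the upper bound in which every
salient word the learner utters counts as reinforced — so tp = salient words
produced and fn = 0 by definition.  "F1" variants count only non-words as
false positives; "F2" variants add the other (proper but non-salient) words.

Reported values are rounded half-up to two decimals; raw values are retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .teacher import SALIENT

VARIANTS = ("F1-1", "F1-2", "F2-1", "F2-2")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (0.005 -> 0.01), matching report formatting."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def f_measure(tp: int, fp: int, fn: int) -> float:
    """Equal-weight F-measure 2tp/(2tp+fp+fn); defined as 0 on empty input."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    denom = 2 * tp + fp + fn
    if denom == 0:
        warnings.warn("F-measure of all-zero counts reported as 0", stacklevel=2)
        return 0.0
    return 2 * tp / denom


@dataclass(frozen=True)
class FMeasureReport:
    variant: str
    value: float

    @property
    def rounded(self) -> float:
        return round_half_up(self.value, 2)


@dataclass(frozen=True)
class EvalCounts:
    """Reinforcement outcome tallies for one session or one aggregated set."""

    tp: int                 # salient words learnt (real reinforcement)
    fp_nonwords: int        # non-words learnt
    fp_other: int           # proper but non-salient words learnt
    fn_missed: int          # salient words produced but not learnt
    produced_salient: int   # salient words produced (simulated-reinforcement tp)

    def __post_init__(self):
        if min(self.tp, self.fp_nonwords, self.fp_other, self.fn_missed,
               self.produced_salient) < 0:
            raise ValueError("counts must be non-negative")
        if self.tp > self.produced_salient:
            raise ValueError("tp cannot exceed produced_salient")


def four_f_measures(counts: EvalCounts) -> dict[str, FMeasureReport]:
    """All four F-measure variants from one set of tallies."""
    fp1 = counts.fp_nonwords
    fp2 = counts.fp_nonwords + counts.fp_other
    values = {
        "F1-1": f_measure(counts.tp, fp1, counts.fn_missed),
        "F1-2": f_measure(counts.produced_salient, fp1, 0),
        "F2-1": f_measure(counts.tp, fp2, counts.fn_missed),
        "F2-2": f_measure(counts.produced_salient, fp2, 0),
    }
    return {v: FMeasureReport(v, values[v]) for v in VARIANTS}


def classify_lexicon(
    lexicon,
    salient_forms: dict[tuple[str, ...], str],
    word_forms: dict[tuple[str, ...], str],
) -> tuple[int, int, int, dict[tuple[str, ...], str]]:
    """Label every lexicon entry salient / other_word / non_word.

    A form is *salient* iff it is the canonical rendering of a salient word;
    it is an *other word* iff it matches any other known proper-word rendering
    (canonical or variant); everything else is a non-word.  Returns
    (tp, fp_other, fp_nonwords, labels).
    """
    tp = fp_other = fp_non = 0
    labels: dict[tuple[str, ...], str] = {}
    for phonemes, _entry in lexicon.items():
        if phonemes in salient_forms:
            labels[phonemes] = SALIENT
            tp += 1
        elif phonemes in word_forms:
            labels[phonemes] = "other_word"
            fp_other += 1
        else:
            labels[phonemes] = "non_word"
            fp_non += 1
    return tp, fp_other, fp_non, labels


def evaluate_session(
    learner_utterances,
    lexicon,
    salient_forms: dict[tuple[str, ...], str],
    word_forms: dict[tuple[str, ...], str],
) -> tuple[EvalCounts, dict[str, FMeasureReport]]:
    """Score one session: classify the final lexicon, count the distinct
    salient words the learner produced, and derive all four F-measures.

    ``learner_utterances`` is an iterable of produced utterances (or an object
    exposing ``learner_utterances()``, e.g. a session transcript).
    """
    if hasattr(learner_utterances, "learner_utterances"):
        learner_utterances = learner_utterances.learner_utterances()
    produced: set[tuple[str, ...]] = set()
    for utt in learner_utterances:
        for syl in utt.syllables:
            if syl.phonemes in salient_forms:
                produced.add(syl.phonemes)
    tp, fp_other, fp_non, _labels = classify_lexicon(lexicon, salient_forms, word_forms)
    counts = EvalCounts(
        tp=tp,
        fp_nonwords=fp_non,
        fp_other=fp_other,
        fn_missed=len(produced) - tp,
        produced_salient=len(produced),
    )
    return counts, four_f_measures(counts)


def salient_rank_advantage(table, vocabulary, inventory=None) -> float:
    """Mean rank advantage of salient over function-word CVC forms.

    Computed on the perceived CVC table: the mean rank of the canonical CVC
    renderings of function words minus the mean rank of the canonical CVC
    renderings of salient words (larger = salient forms outrank function
    forms by more).  Forms absent from the table rank one past the bottom.
    This quantifies frequency dilution: variable pronunciation spreads a
    function word's mass over renderings, so its canonical form sinks while
    consistently-pronounced salient words rise.
    """
    from .phonology import PhonemeInventory
    from .teacher import FUNCTION

    inventory = inventory or PhonemeInventory.default()

    def is_cvc(form: tuple[str, ...]) -> bool:
        vowels = [t for t in form if t in inventory.vowels]
        return (len(vowels) == 1 and form[0] not in inventory.vowels
                and form[-1] not in inventory.vowels)

    ranked = [p for p, _ in table.rank_syllables("CVC")]
    pos = {p: i + 1 for i, p in enumerate(ranked)}
    bottom = len(ranked) + 1
    sal = [pos.get(e.canonical, bottom) for e in vocabulary
           if e.role == SALIENT and is_cvc(e.canonical)]
    fun = [pos.get(e.canonical, bottom) for e in vocabulary
           if e.role == FUNCTION and is_cvc(e.canonical)]
    if not sal or not fun:
        raise ValueError("vocabulary must contain salient and function CVC forms")
    return float(np.mean(fun) - np.mean(sal))


# -- bundled study tables ----------------------------------------------------

_DATA = resources.files("babblelex") / "data"


def load_study_speech_stats() -> pd.DataFrame:
    """Per-participant speech/perception statistics of the five-set study."""
    with resources.as_file(_DATA / "study_speech_stats.tsv") as p:
        return pd.read_csv(p, sep="\t", comment="#")


def load_study_set_counts() -> pd.DataFrame:
    """Aggregated per-set reinforcement outcome counts of the five-set study."""
    with resources.as_file(_DATA / "study_set_counts.tsv") as p:
        return pd.read_csv(p, sep="\t", comment="#")


# columns of the speech-statistics table that are not comparable for the
# filtered set (set 2) and are excluded from cross-set summaries
FILTERED_COLUMNS = (
    "different_syllables",
    "different_cvc_syllables",
    "salient_in_top10_perceived",
    "salient_uttered_by_robot",
)


def summarize_speech(
    df: pd.DataFrame,
    value_columns: list[str] | None = None,
    exclude_sets: dict[str, tuple[int, ...]] | None = None,
) -> pd.DataFrame:
    """Descriptive statistics (min/max/mean/SD) per column.

    ``exclude_sets`` maps a column name to set numbers whose rows are dropped
    for that column only (the filtered-set convention).  Missing values are
    ignored.  Both the sample and population SD are emitted, since reporting
    conventions differ; a single-value column gets SD 0 and a flag.
    """
    if value_columns is None:
        value_columns = [c for c in df.columns if c not in ("set", "participant")]
    exclude_sets = exclude_sets or {}
    out: dict[str, dict[str, float]] = {}
    for col in value_columns:
        sub = df
        if col in exclude_sets:
            sub = df[~df["set"].isin(exclude_sets[col])]
        vals = pd.to_numeric(sub[col], errors="coerce").dropna().to_numpy(dtype=float)
        single = len(vals) <= 1
        out[col] = {
            "n": len(vals),
            "min": vals.min(),
            "max": vals.max(),
            "mean": vals.mean(),
            "sd_sample": 0.0 if single else float(np.std(vals, ddof=1)),
            "sd_population": 0.0 if single else float(np.std(vals, ddof=0)),
            "single_value_flag": float(single),
        }
    return pd.DataFrame(out)


def default_speech_exclusions() -> dict[str, tuple[int, ...]]:
    """Exclude the filtered set (set 2) from syllable-derived columns."""
    return {c: (2,) for c in FILTERED_COLUMNS}


def study_f_measures(counts: pd.DataFrame | None = None) -> pd.DataFrame:
    """Recompute the per-set F-measure table from the bundled study counts.

    Returns one row per set with raw and 2-dp rounded values for each variant.
    """
    counts = counts if counts is not None else load_study_set_counts()
    rows = []
    for _, r in counts.iterrows():
        ec = EvalCounts(
            tp=int(r["learnt"]),
            fp_nonwords=int(r["nonwords"]),
            fp_other=int(r["other_words"]),
            fn_missed=int(r["missed"]),
            produced_salient=int(r["produced"]),
        )
        reports = four_f_measures(ec)
        row = {"set": int(r["set"])}
        for v in VARIANTS:
            row[v] = reports[v].rounded
            row[v + " raw"] = reports[v].value
        rows.append(row)
    return pd.DataFrame(rows).set_index("set")


def write_report_tsv(path: str | Path, counts: EvalCounts,
                     reports: dict[str, FMeasureReport]) -> None:
    """Write a session report mirroring the study's summary-table layout."""
    with open(path, "w") as fh:
        fh.write("metric\tvalue\n")
        fh.write(f"salient_words_produced\t{counts.produced_salient}\n")
        fh.write(f"salient_words_learnt\t{counts.tp}\n")
        fh.write(f"words_missed\t{counts.fn_missed}\n")
        fh.write(f"nonwords_learnt\t{counts.fp_nonwords}\n")
        fh.write(f"other_words_learnt\t{counts.fp_other}\n")
        for v in VARIANTS:
            fh.write(f"{v}\t{reports[v].rounded:.2f}\n")
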