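"""TF-IDF featurization of per-patient clinical note sets.

All of a patient's first-24-hour notes are pooled into a single "note set";
the vocabulary is the k most frequent terms (by total training token count,
default k = 1000) in the training corpus, fitted per site in cross-site mode
or on the pooled corpus in pooled mode. Weights use sublinear term
frequency, which damps the effect of copy-pasted text:

    weight(term, doc) = (1 + ln tf) * idf       for tf > 0, else 0
    idf(term)         = ln((1 + N) / (1 + df)) + 1

with N the number of training note sets and df the term's training document
frequency. The smoothed idf keeps every fitted term strictly positive, so
rarer terms always get larger weights at equal tf. No length normalization
is applied: text and structured predictors are z-standardized jointly at
model-fit time, which puts them on one scale for the ridge penalty.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["Vocabulary", "tokenize", "build_note_sets", "fit_vocabulary",
           "tfidf_vector", "tfidf_matrix"]

logger = logging.getLogger(__name__)

_TOKEN_RE = re.compile(r"[a-z0-9]+")


@dataclass(frozen=True)
class Vocabulary:
    """A fitted term list with document frequencies and idf weights.

    Terms are ordered by descending training token count, ties broken
    lexicographically. ``n_docs`` is the training note-set count N.
    """

    terms: tuple[str, ...]
    df: tuple[int, ...]
    idf: tuple[float, ...]
    n_docs: int
    site: str | None = None

    def __post_init__(self):
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("vocabulary terms must be unique")
        if any(w <= 0 for w in self.idf):
            raise ValueError("idf weights must be strictly positive")

    def __len__(self) -> int:
        return len(self.terms)

    @property
    def index(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.terms)}


def tokenize(text: str) -> list[str]:
    """Lowercased maximal alphanumeric runs, in order of appearance."""
    return _TOKEN_RE.findall(text.lower())


def build_note_sets(notes: pd.DataFrame, patient_ids=None) -> dict[str, Counter]:
    """Pool each patient's windowed notes into one token multiset.

    If ``patient_ids`` is given, every listed patient gets an entry (empty
    Counter when they wrote no notes); otherwise only patients present in
    the note table appear.
    """
    sets: dict[str, Counter] = {}
    if patient_ids is not None:
        sets = {pid: Counter() for pid in patient_ids}
    for pid, text in zip(notes["patient_id"], notes["text"]):
        if patient_ids is not None and pid not in sets:
            continue
        sets.setdefault(pid, Counter()).update(tokenize(text))
    return sets


def fit_vocabulary(note_sets: dict[str, Counter] | list[Counter], k: int = 1000,
                   site: str | None = None) -> Vocabulary:
    """Top-k terms by total training token count; ties lexicographic.

    Must only ever see training note sets. If fewer than k distinct terms
    exist, all of them are kept and a warning is logged.
    """
    docs = list(note_sets.values()) if isinstance(note_sets, dict) else list(note_sets)
    totals: Counter = Counter()
    df_counts: Counter = Counter()
    for doc in docs:
        totals.update(doc)
        df_counts.update(doc.keys())
    if len(totals) < k:
        logger.warning("only %d distinct terms available for k=%d", len(totals), k)
    ranked = sorted(totals, key=lambda t: (-totals[t], t))[:k]
    n_docs = len(docs)
    df = tuple(df_counts[t] for t in ranked)
    idf = tuple(float(np.log((1 + n_docs) / (1 + d)) + 1.0) for d in df)
    return Vocabulary(terms=tuple(ranked), df=df, idf=idf, n_docs=n_docs, site=site)


def tfidf_vector(note_set: Counter, vocabulary: Vocabulary) -> np.ndarray:
    """Sublinear TF-IDF weights for one note set over a fitted vocabulary.

    Out-of-vocabulary tokens contribute nothing; an empty note set is a
    zero vector.
    """
    out = np.zeros(len(vocabulary))
    idx = vocabulary.index
    idf = vocabulary.idf
    for term, tf in note_set.items():
        j = idx.get(term)
        if j is not None and tf > 0:
            out[j] = (1.0 + np.log(tf)) * idf[j]
    return out


def tfidf_matrix(note_sets: dict[str, Counter], patient_ids, vocabulary: Vocabulary) -> np.ndarray:
    """Stack tfidf_vector rows in the given patient order."""
    empty = Counter()
    return np.vstack([tfidf_vector(note_sets.get(pid, empty), vocabulary)
                      for pid in patient_ids])
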