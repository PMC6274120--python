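"""Virtual-screening metrics: ROC/AUC and enrichment factors.

A screening run yields one score per compound (kcal/mol; more negative is
better) and a binary active/decoy label.  AUC is the probability that a
random active outranks a random decoy (ties counted one-half): 1 is ideal,
0.5 is random selection.  The enrichment factor at x%,

    EF(x%) = (hits_x / N_x) / (hits_t / N_t),

compares the active fraction among the top x% of the ranked list (subset size
N_x = floor(x/100 · N_t)) with the active fraction overall.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

__all__ = [
    "ScreeningResult",
    "roc_auc",
    "enrichment_factor",
    "roc_points",
    "write_report",
    "DEFAULT_EF_PERCENTS",
]

#: Subset sizes conventionally reported for early enrichment.
DEFAULT_EF_PERCENTS = (0.1, 0.5, 1.0, 2.0, 5.0, 10.0)


@dataclass(frozen=True)
class ScreeningResult:
    """Rank-ordered screening output: parallel id/score/label sequences.

    Entries are kept sorted by ascending score (best first); ties keep their
    input order (stable sort), which matters only for EF subsets that split a
    tie group.
    """

    ids: tuple
    scores: tuple
    labels: tuple  # "active" / "decoy"

    def __post_init__(self):
        if not (len(self.ids) == len(self.scores) == len(self.labels)):
            raise ValueError("ids, scores and labels must have equal length")
        bad = {l for l in self.labels} - {"active", "decoy"}
        if bad:
            raise ValueError(f"labels must be 'active' or 'decoy', got {sorted(bad)}")
        order = np.argsort(np.asarray(self.scores, dtype=float), kind="stable")
        object.__setattr__(self, "ids", tuple(self.ids[i] for i in order))
        object.__setattr__(self, "scores", tuple(float(self.scores[i]) for i in order))
        object.__setattr__(self, "labels", tuple(self.labels[i] for i in order))

    @classmethod
    def from_entries(cls, entries) -> "ScreeningResult":
        ids, scores, labels = zip(*entries)
        return cls(tuple(ids), tuple(scores), tuple(labels))

    @classmethod
    def from_csv(cls, path) -> "ScreeningResult":
        df = pd.read_csv(path)
        need = {"id", "score", "label"}
        if not need <= set(df.columns):
            raise ValueError(f"{path} must have columns {sorted(need)}")
        return cls(tuple(df["id"]), tuple(df["score"]), tuple(df["label"]))

    def to_csv(self, path) -> None:
        pd.DataFrame({"id": self.ids, "score": self.scores, "label": self.labels}).to_csv(
            path, index=False
        )

    @property
    def n_total(self) -> int:
        return len(self.ids)

    @property
    def n_actives(self) -> int:
        return sum(l == "active" for l in self.labels)

    @property
    def is_active(self) -> np.ndarray:
        return np.array([l == "active" for l in self.labels])

    def auc(self) -> float:
        return roc_auc(self)

    def ef(self, percent: float) -> float:
        return enrichment_factor(self, percent)


def _check_both_classes(r: ScreeningResult) -> None:
    n_act = r.n_actives
    if n_act == 0 or n_act == r.n_total:
        raise ValueError("AUC/EF need at least one active and one decoy")


def roc_auc(r: ScreeningResult) -> float:
    """Mann–Whitney AUC: P(active scored better than decoy), ties count ½."""
    _check_both_classes(r)
    # lower score = better rank, so the decision value is the negated score
    return float(roc_auc_score(r.is_active, -np.asarray(r.scores)))


def enrichment_factor(r: ScreeningResult, percent: float) -> float:
    """EF at the top ``percent``% of the ranked list (floor subset size)."""
    _check_both_classes(r)
    if not (0 < percent <= 100):
        raise ValueError(f"percent must be in (0, 100], got {percent}")
    n_t = r.n_total
    n_x = math.floor(percent / 100.0 * n_t)
    if n_x == 0:
        raise ValueError(
            f"top {percent}% of {n_t} compounds rounds down to zero entries"
        )
    hits_t = r.n_actives
    hits_x = int(r.is_active[:n_x].sum())
    return (hits_x / n_x) / (hits_t / n_t)


def roc_points(r: ScreeningResult) -> np.ndarray:
    """Tie-aware ROC polyline, shape (m, 2) of (FPR, TPR).

    Starts at (0, 0), ends at (1, 1); each distinct score value advances one
    vertex, so a tied group moves diagonally.  The trapezoidal area under
    this polyline equals :func:`roc_auc`.
    """
    _check_both_classes(r)
    scores = np.asarray(r.scores)
    active = r.is_active
    n_act = active.sum()
    n_dec = len(active) - n_act
    pts = [(0.0, 0.0)]
    i = 0
    tp = fp = 0
    while i < len(scores):
        j = i
        while j < len(scores) and scores[j] == scores[i]:
            j += 1
        tp += int(active[i:j].sum())
        fp += (j - i) - int(active[i:j].sum())
        pts.append((fp / n_dec, tp / n_act))
        i = j
    return np.asarray(pts)


def write_report(r: ScreeningResult, path, ef_percents=DEFAULT_EF_PERCENTS, roc_path=None) -> pd.DataFrame:
    """Write a metrics CSV (AUC + EF at the conventional subset sizes).

    EF percentages whose subset rounds to zero compounds are reported as NaN.
    Optionally writes the ROC polyline to ``roc_path``.
    """
    rows = [{"metric": "AUC", "value": roc_auc(r)}]
    for p in ef_percents:
        try:
            v = enrichment_factor(r, p)
        except ValueError:
            v = float("nan")
        rows.append({"metric": f"EF({p:g}%)", "value": v})
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    if roc_path is not None:
        pts = roc_points(r)
        pd.DataFrame(pts, columns=["fpr", "tpr"]).to_csv(roc_path, index=False)
    return df
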