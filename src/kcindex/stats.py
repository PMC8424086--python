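"""Cutoff selection and discrimination statistics for the KC index.

Subjects with an abnormal general-movement pattern (poor repertoire or
cramped synchronized) form the positive class and score *high* on the KC
index. Discrimination from the normal class is summarized by the ROC curve
and its AUC; the operating cutoff is chosen by Youden's index
J = sensitivity + specificity − 1, and its sampling variability quantified
with a percentile bootstrap (1,000 resamples by default, drawn with
replacement at the original sample size, unstratified).

The AUC is computed as the Mann–Whitney U statistic over all
positive×negative pairs with ties counted ½, which equals the trapezoidal
area under the empirical ROC curve.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import DegenerateLabelsError


@dataclass
class LabeledScores:
    """Scores with binary labels (positive = abnormal movement pattern)."""

    scores: np.ndarray
    labels: np.ndarray  # boolean, True = positive (Ab)

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=bool)
        if self.scores.shape != self.labels.shape or self.scores.ndim != 1:
            raise ValueError("scores and labels must be 1-D and of equal length")
        if not np.all(np.isfinite(self.scores)):
            raise DegenerateLabelsError("scores must be finite")
        if self.labels.all() or not self.labels.any():
            raise DegenerateLabelsError("need at least one positive and one negative")

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        positive_labels: tuple[str, ...] = ("PR", "CS"),
        score_col: str = "kc_index",
        label_col: str = "gm_label",
    ) -> "LabeledScores":
        labeled = frame[frame[label_col].notna()]
        return cls(
            scores=labeled[score_col].to_numpy(float),
            labels=labeled[label_col].isin(positive_labels).to_numpy(),
        )


@dataclass
class RocCurve:
    """Operating points of the empirical ROC, in rising-threshold order.

    A subject is called positive when its score is strictly above the
    threshold. Thresholds are the midpoints between consecutive distinct
    scores, with −inf/+inf sentinels closing the curve; sensitivity is
    non-increasing and specificity non-decreasing along the array.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )


def _auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as concordance probability: P(score_pos > score_neg) + ½P(tie)."""
    ranks = rankdata(scores)  # average ranks -> ties counted 1/2
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_curve(data: LabeledScores) -> RocCurve:
    """Empirical ROC over all midpoint thresholds, plus the AUC."""
    distinct = np.unique(data.scores)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate(([-np.inf], mids, [np.inf]))
    pos = np.sort(data.scores[data.labels])
    neg = np.sort(data.scores[~data.labels])
    # count of scores strictly above each threshold, via sorted search
    sens = (len(pos) - np.searchsorted(pos, thresholds, side="right")) / len(pos)
    spec = np.searchsorted(neg, thresholds, side="right") / len(neg)
    return RocCurve(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=_auc_mann_whitney(data.scores, data.labels),
    )


@dataclass
class YoudenCutoff:
    cutoff: float
    sensitivity: float
    specificity: float

    @property
    def j(self) -> float:
        return self.sensitivity + self.specificity - 1.0


def youden_cutoff(roc: RocCurve) -> YoudenCutoff:
    """Threshold maximizing J = sensitivity + specificity − 1.

    Ties are broken in favor of higher specificity, then the lower threshold
    value. Only the finite midpoint thresholds are candidates (the ±inf
    sentinels describe the curve's endpoints, not usable cutoffs).
    """
    finite = np.isfinite(roc.thresholds)
    if not finite.any():
        raise DegenerateLabelsError("no finite candidate thresholds (all scores equal)")
    thr = roc.thresholds[finite]
    sens = roc.sensitivity[finite]
    spec = roc.specificity[finite]
    j = sens + spec - 1.0
    best = j == j.max()
    best_spec = spec[best].max()
    best = best & (spec == best_spec)
    idx = int(np.flatnonzero(best)[0])  # thresholds ascend -> first = lowest
    return YoudenCutoff(
        cutoff=float(thr[idx]), sensitivity=float(sens[idx]), specificity=float(spec[idx])
    )


def _bootstrap_statistic(
    data: LabeledScores,
    statistic,
    n_boot: int,
    rng: np.random.Generator,
    stratified: bool = False,
) -> np.ndarray:
    """Resampling with replacement at the original sample size.

    Unstratified by default: (score, label) pairs are drawn jointly, and a
    resample missing one class — which cannot support the statistic — is
    redrawn (up to 100·n_boot total draws) so n_boot effective resamples
    remain. With ``stratified=True`` each class is resampled separately,
    preserving the class counts.
    """
    n = data.scores.size
    pos_idx = np.flatnonzero(data.labels)
    neg_idx = np.flatnonzero(~data.labels)
    values = np.empty(n_boot)
    draws = 0
    max_draws = 100 * n_boot
    for b in range(n_boot):
        while True:
            draws += 1
            if draws > max_draws:
                raise DegenerateLabelsError(
                    f"could not draw {n_boot} two-class resamples in {max_draws} tries"
                )
            if stratified:
                idx = np.concatenate(
                    [
                        rng.choice(pos_idx, size=pos_idx.size, replace=True),
                        rng.choice(neg_idx, size=neg_idx.size, replace=True),
                    ]
                )
                break
            idx = rng.integers(0, n, size=n)
            if data.labels[idx].any() and not data.labels[idx].all():
                break
        resample = LabeledScores(scores=data.scores[idx], labels=data.labels[idx])
        values[b] = statistic(resample)
    return values


def bootstrap_cutoff_ci(
    data: LabeledScores, n_boot: int = 1000, seed: int = 0, stratified: bool = False
) -> tuple[float, float]:
    """95% percentile bootstrap CI of the Youden-optimal cutoff."""
    rng = np.random.default_rng(seed)
    cuts = _bootstrap_statistic(
        data, lambda d: youden_cutoff(roc_curve(d)).cutoff, n_boot, rng, stratified
    )
    lo, hi = np.percentile(cuts, [2.5, 97.5])
    return float(lo), float(hi)


def auc_ci(
    data: LabeledScores, n_boot: int = 1000, seed: int = 0, stratified: bool = False
) -> tuple[float, float]:
    """95% percentile bootstrap CI of the AUC (same resampling engine)."""
    rng = np.random.default_rng(seed)
    aucs = _bootstrap_statistic(data, lambda d: roc_curve(d).auc, n_boot, rng, stratified)
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return float(lo), float(hi)


@dataclass
class RocResult:
    """Full evaluation: curve, AUC with CI, cutoff with CI, operating point."""

    curve: RocCurve = field(repr=False)
    auc: float
    auc_ci: tuple[float, float]
    cutoff: float
    cutoff_ci: tuple[float, float]
    sens_at_cutoff: float
    spec_at_cutoff: float
    n_boot: int
    seed: int
    n_pos: int
    n_neg: int

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "cutoff": self.cutoff,
            "cutoff_ci": list(self.cutoff_ci),
            "sens_at_cutoff": self.sens_at_cutoff,
            "spec_at_cutoff": self.spec_at_cutoff,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
        }

    def to_json(self, path: str | Path, **extra) -> None:
        payload = {**self.to_dict(), **extra}
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def evaluate(data: LabeledScores, n_boot: int = 1000, seed: int = 0) -> RocResult:
    """ROC + AUC (bootstrap CI) + Youden cutoff (bootstrap CI) in one call.

    The two bootstrap CIs use independent seeded streams derived from
    ``seed``, so either can be reproduced in isolation.
    """
    curve = roc_curve(data)
    best = youden_cutoff(curve)
    seed_cut, seed_auc = np.random.SeedSequence(seed).generate_state(2) >> 1
    cutoff_ci = bootstrap_cutoff_ci(data, n_boot=n_boot, seed=int(seed_cut))
    ci_auc = auc_ci(data, n_boot=n_boot, seed=int(seed_auc))
    return RocResult(
        curve=curve,
        auc=curve.auc,
        auc_ci=ci_auc,
        cutoff=best.cutoff,
        cutoff_ci=cutoff_ci,
        sens_at_cutoff=best.sensitivity,
        spec_at_cutoff=best.specificity,
        n_boot=n_boot,
        seed=seed,
        n_pos=int(data.labels.sum()),
        n_neg=int((~data.labels).sum()),
    )
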