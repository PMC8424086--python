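"""The KC index: cohort-range-normalized composite of the six features.

For subject *i* with per-limb kurtosis values kur(i)_l (l = LW, RW, LA, RA)
and pair jerk cross-correlations xcorr(i)_p (p = upper, lower), and cohort
extremes max_f / min_f taken over all subjects,

    KC_index(i) = ( Σ_l kur(i)_l / (max(kur_l) − min(kur_l))
                  + Σ_p xcorr(i)_p / (max(xcorr_p) − min(xcorr_p)) ) × 100 .

Each term divides the raw feature by the cohort range; in this default
form of the index the cohort minimum is *not* subtracted, so individual
terms are range-scaled but not mapped onto [0, 1]. A full min-max variant
((x − min)/(max − min)) is available via ``normalization="min_max"``; the two
produce identical rankings within a fixed cohort (each term differs by a
per-feature constant), so cutoffs learned under one normalization do not
transfer to the other.

The index is cohort-referenced by construction: adding a subject can change
every score through the range denominators. For prospective use a fitted
:class:`CohortNormalization` can be frozen to disk and new subjects scored
against it unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .errors import DegenerateCohortError, DegenerateSignalError, KCIndexError
from .features import FEATURE_NAMES, FeatureVector, extract_features
from .preprocess import FilterSpec, highpass
from .recording import SubjectRecording, synchronize, trim_settling

NORMALIZATION_MODES = ("range_divide", "min_max")


@dataclass
class CohortNormalization:
    """Per-feature cohort minima and maxima used as range denominators."""

    mins: dict[str, float]
    maxs: dict[str, float]
    n_subjects: int

    def __post_init__(self):
        if self.n_subjects < 2:
            raise DegenerateCohortError("normalization needs at least 2 subjects")
        for name in FEATURE_NAMES:
            if name not in self.mins or name not in self.maxs:
                raise DegenerateCohortError(f"missing feature {name!r}")
            if not self.maxs[name] > self.mins[name]:
                raise DegenerateCohortError(name)

    def range(self, name: str) -> float:
        return self.maxs[name] - self.mins[name]

    def to_json(self, path: str | Path, **extra) -> None:
        payload = {
            "mins": {k: self.mins[k] for k in FEATURE_NAMES},
            "maxs": {k: self.maxs[k] for k in FEATURE_NAMES},
            "n_subjects": self.n_subjects,
            **extra,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortNormalization":
        payload = json.loads(Path(path).read_text())
        return cls(
            mins=payload["mins"], maxs=payload["maxs"], n_subjects=payload["n_subjects"]
        )


@dataclass
class KCResult:
    """One subject's KC index and its six normalized addends.

    ``kc_index`` equals 100 × the sum of ``contributions`` exactly (to
    floating tolerance).
    """

    subject_id: str
    kc_index: float
    contributions: dict[str, float]
    gm_label: str | None = field(default=None, compare=False)


def fit_normalization(features: list[FeatureVector]) -> CohortNormalization:
    """Scan a cohort's feature vectors for per-feature minima and maxima.

    Raises
    ------
    DegenerateCohortError
        If fewer than 2 subjects, or any feature has zero spread (the range
        denominator would vanish), naming the offending feature.
    """
    if len(features) < 2:
        raise DegenerateCohortError("normalization needs at least 2 subjects")
    table = {name: [fv.as_dict()[name] for fv in features] for name in FEATURE_NAMES}
    mins = {name: float(min(vals)) for name, vals in table.items()}
    maxs = {name: float(max(vals)) for name, vals in table.items()}
    for name in FEATURE_NAMES:
        if not maxs[name] > mins[name]:
            raise DegenerateCohortError(name)
    return CohortNormalization(mins=mins, maxs=maxs, n_subjects=len(features))


def compute_kc(
    features: FeatureVector,
    norm: CohortNormalization,
    normalization: str = "range_divide",
) -> KCResult:
    """Combine one subject's six features into the KC index.

    ``normalization="range_divide"`` (default) divides each feature by the
    cohort range without subtracting the minimum. ``"min_max"`` maps each feature onto [0, 1]
    relative to the cohort extremes instead.
    """
    if normalization not in NORMALIZATION_MODES:
        raise KCIndexError(f"unknown normalization mode {normalization!r}")
    raw = features.as_dict()
    contributions = {}
    for name in FEATURE_NAMES:
        value = raw[name]
        if normalization == "min_max":
            value = value - norm.mins[name]
        contributions[name] = value / norm.range(name)
    kc = 100.0 * float(np.sum([contributions[name] for name in FEATURE_NAMES]))
    return KCResult(
        subject_id=features.subject_id,
        kc_index=kc,
        contributions=contributions,
        gm_label=features.gm_label,
    )


@dataclass
class CohortScores:
    """Output of :func:`score_cohort`: per-subject results plus provenance."""

    results: list[KCResult]
    normalization: CohortNormalization
    features: list[FeatureVector]
    excluded: list[tuple[str, str]]  # (subject_id, reason)

    def to_frame(self) -> pd.DataFrame:
        """Scores table: subject_id, kc_index, gm_label + contribution columns."""
        rows = []
        for res in self.results:
            row = {
                "subject_id": res.subject_id,
                "kc_index": res.kc_index,
                "gm_label": res.gm_label,
            }
            row.update({name: res.contributions[name] for name in FEATURE_NAMES})
            rows.append(row)
        return pd.DataFrame(rows)


def preprocess_subject(rec: SubjectRecording, config: PipelineConfig) -> SubjectRecording:
    """Synchronize (if needed), trim, and high-pass one recording.

    A dead sensor (constant raw signal on every axis) is rejected here with
    :class:`DegenerateSignalError`: after high-pass filtering it would look
    like numerically tiny noise rather than a flat line, and its features
    would be meaningless.
    """
    for limb_id, limb in rec.limbs.items():
        if np.ptp(limb.accel, axis=0).max() == 0:
            raise DegenerateSignalError(f"{limb_id}: constant (dead-sensor) signal")
    if not rec.synchronized:
        rec = synchronize(
            rec,
            target_rate=config.target_rate_hz,
            min_duration_s=config.min_duration_s,
            duration_tol=config.duration_tol,
        )
    if config.settle_s > 0:
        rec = trim_settling(rec, config.settle_s)
    spec = FilterSpec(
        cutoff_hz=config.filter.cutoff_hz,
        order=config.filter.order,
        zero_phase=config.filter.zero_phase,
    )
    return highpass(rec, spec)


def score_subject(
    rec: SubjectRecording,
    norm: CohortNormalization,
    config: PipelineConfig | None = None,
) -> KCResult:
    """Score a single (new) subject against a frozen cohort normalization."""
    config = config or PipelineConfig()
    rec = preprocess_subject(rec, config)
    fv = extract_features(rec, max_lag_s=config.max_lag_s)
    return compute_kc(fv, norm, config.normalization)


def score_cohort(
    recs: list[SubjectRecording],
    config: PipelineConfig | None = None,
) -> CohortScores:
    """Run the full pipeline on a cohort and score every usable subject.

    Per subject: synchronize → high-pass → feature extraction. Subjects
    failing any stage (dead sensor, insufficient overlap, ...) are excluded
    and reported; the normalization is fitted on the survivors, then every
    survivor is scored against it.

    Raises
    ------
    DegenerateCohortError
        If fewer than 2 subjects survive, or a feature has no spread.
    """
    config = config or PipelineConfig()
    features: list[FeatureVector] = []
    excluded: list[tuple[str, str]] = []
    for rec in recs:
        try:
            prepped = preprocess_subject(rec, config)
            features.append(extract_features(prepped, max_lag_s=config.max_lag_s))
        except KCIndexError as exc:
            excluded.append((rec.subject_id, f"{type(exc).__name__}: {exc}"))
    if len(features) < 2:
        raise DegenerateCohortError(
            f"only {len(features)} subject(s) survived feature extraction"
        )
    norm = fit_normalization(features)
    results = [compute_kc(fv, norm, config.normalization) for fv in features]
    return CohortScores(
        results=results, normalization=norm, features=features, excluded=excluded
    )
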