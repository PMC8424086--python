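"""Per-subject movement features: PC1 kurtosis per limb, jerk synchrony per pair.

Six features summarize a recording, mirroring how clinical General Movement
Assessment weighs both single-limb movement quality and inter-limb
coordination:

* per limb, the Pearson kurtosis of the first principal component of the
  (gravity-removed) tri-axial acceleration — sparse, stereotyped movement
  yields a heavy-tailed score distribution and high kurtosis, while rich,
  ongoing movement is closer to Gaussian;
* per limb pair (left/right wrists = "upper", left/right ankles = "lower"),
  the peak of the normalized cross-correlation of the jerk magnitude within
  a ±2 s lag window — near 1 when the two limbs move in lock-step, as in
  cramped synchronized movements.

Kurtosis follows the Pearson (non-excess) convention with the biased moment
estimator, m4/m2²: 3 for a Gaussian, with 1 the lower bound attained by a
symmetric two-point distribution. Jerk is the first difference of
acceleration over the sampling interval, taken as the Euclidean norm across
axes so the result does not depend on how a sensor band was strapped on
(left and right sensors have mirrored, unknown orientations). All six
features are invariant to the overall acceleration scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import DegenerateSignalError, NotSynchronizedError
from .recording import LimbRecording, SubjectRecording, LIMB_IDS

#: limb pairs whose jerk synchrony is measured
PAIRS: dict[str, tuple[str, str]] = {"upper": ("LW", "RW"), "lower": ("LA", "RA")}

#: canonical feature order used by normalization and the feature table
FEATURE_NAMES = ("kur_LW", "kur_RW", "kur_LA", "kur_RA", "xcorr_upper", "xcorr_lower")


@dataclass
class FeatureVector:
    """The six raw features of one subject.

    kur : limb_id -> Pearson kurtosis of the limb's PC1 scores (≥ 1).
    xcorr : pair_id ("upper"/"lower") -> peak normalized jerk
        cross-correlation, in [-1, 1].
    """

    subject_id: str
    kur: dict[str, float]
    xcorr: dict[str, float]
    gm_label: str | None = field(default=None, compare=False)

    def as_dict(self) -> dict[str, float]:
        """Flatten to the canonical ``FEATURE_NAMES`` keys."""
        out = {f"kur_{limb}": self.kur[limb] for limb in LIMB_IDS}
        out["xcorr_upper"] = self.xcorr["upper"]
        out["xcorr_lower"] = self.xcorr["lower"]
        return out


def first_principal_component(limb: LimbRecording) -> np.ndarray:
    """Scores of the centered 3-axis signal on its first principal axis.

    The principal axis is the eigenvector of the largest eigenvalue of the
    3×3 sample covariance. Sign convention: the first nonzero loading is
    positive (kurtosis is sign-invariant; the convention only fixes
    determinism).
    """
    if limb.n_samples < 4:
        raise DegenerateSignalError(f"{limb.limb_id}: fewer than 4 samples")
    centered = limb.accel - limb.accel.mean(axis=0)
    cov = centered.T @ centered / len(centered)
    eigvals, eigvecs = np.linalg.eigh(cov)
    if eigvals[-1] <= 0:
        raise DegenerateSignalError(f"{limb.limb_id}: zero-variance signal")
    pc1 = eigvecs[:, -1]
    for loading in pc1:
        if loading != 0.0:
            if loading < 0:
                pc1 = -pc1
            break
    return centered @ pc1


def kurtosis(x: np.ndarray) -> float:
    """Pearson (non-excess) kurtosis, biased moment form m4/m2².

    m_k is the k-th central sample moment. Equals 3 for a Gaussian and is
    bounded below by 1 for any distribution.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise DegenerateSignalError("kurtosis needs at least 4 samples")
    centered = x - x.mean()
    m2 = np.mean(centered**2)
    if m2 == 0:
        raise DegenerateSignalError("zero-variance series")
    return float(np.mean(centered**4) / m2**2)


def jerk(limb: LimbRecording) -> np.ndarray:
    """Jerk magnitude: norm across axes of the first-difference derivative.

    Returns a series of length n − 1 in m/s³. Requires a uniform grid.
    """
    if limb.n_samples < 2:
        raise DegenerateSignalError(f"{limb.limb_id}: fewer than 2 samples")
    dt = np.diff(limb.timestamps)
    fs = 1.0 / float(np.median(dt))
    per_axis = np.diff(limb.accel, axis=0) * fs
    return np.linalg.norm(per_axis, axis=1)


def pair_xcorr(
    jerk_a: np.ndarray,
    jerk_b: np.ndarray,
    fs: float,
    max_lag_s: float = 2.0,
) -> float:
    """Peak normalized cross-correlation of two jerk series within a lag window.

    Both series are mean-centered and the correlation normalized by the
    product of their norms, so the value at lag 0 is the Pearson correlation.
    The maximum over integer lags with \\|lag\\| ≤ ``max_lag_s``·``fs`` is
    returned: synchrony between limbs tolerates small latencies, while the
    bounded window avoids spurious far-lag maxima.
    """
    a = np.asarray(jerk_a, dtype=float)
    b = np.asarray(jerk_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("jerk series must be 1-D and of equal length")
    a = a - a.mean()
    b = b - b.mean()
    norm = np.linalg.norm(a) * np.linalg.norm(b)
    if norm == 0:
        raise DegenerateSignalError("zero-variance jerk series")
    corr = signal.correlate(a, b, mode="full") / norm
    lags = signal.correlation_lags(len(a), len(b), mode="full")
    window = np.abs(lags) <= int(round(max_lag_s * fs))
    return float(corr[window].max())


def extract_features(rec: SubjectRecording, max_lag_s: float = 2.0) -> FeatureVector:
    """Compute the six features of a synchronized, gravity-removed recording.

    Raises
    ------
    DegenerateSignalError
        Naming the offending limb or pair (e.g. a dead sensor).
    """
    if not rec.synchronized or rec.rate is None:
        raise NotSynchronizedError("extract_features requires a synchronized recording")
    kur: dict[str, float] = {}
    jerks: dict[str, np.ndarray] = {}
    for limb_id in LIMB_IDS:
        limb = rec.limbs[limb_id]
        try:
            kur[limb_id] = kurtosis(first_principal_component(limb))
            jerks[limb_id] = jerk(limb)
        except DegenerateSignalError as exc:
            raise DegenerateSignalError(f"{limb_id}: {exc.what}") from exc
    xcorr: dict[str, float] = {}
    for pair_id, (left, right) in PAIRS.items():
        try:
            xcorr[pair_id] = pair_xcorr(jerks[left], jerks[right], rec.rate, max_lag_s)
        except DegenerateSignalError as exc:
            raise DegenerateSignalError(f"{pair_id} pair: {exc.what}") from exc
    return FeatureVector(
        subject_id=rec.subject_id, kur=kur, xcorr=xcorr, gm_label=rec.gm_label
    )
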