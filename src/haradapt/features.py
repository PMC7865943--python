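"""Per-window feature extraction.

Each 40-sample window is summarized channel by channel with a fixed bank of
time- and frequency-domain statistics.  The pressure channel contributes 13
features (mean, median, max, min, range, variance, standard deviation, RMS,
interquartile range, mean-crossing count, kurtosis, skewness, FFT DC
component); each of the nine inertial channels contributes those plus the
zero-crossing count, spectral entropy, mean power, and three single-level
Haar-wavelet statistics, 19 in total.  With the default configuration the
feature vector has d = 13 + 9 * 19 = 184 entries, concatenated
channel-major in the fixed channel order.

Conventions for quantities the feature names alone do not pin down:

* FFT DC component: |X(0)| / N, the magnitude of the zeroth DFT coefficient
  over the window length (the spectral reading of the window mean).
* Entropy: Shannon entropy (nats) of the normalized one-sided power
  spectrum excluding DC, with 0*log(0) = 0; zero for a flat/empty spectrum.
* Energy: mean signal power (1/N) * sum(x^2).
* Wavelet features: Haar decomposition (default one level); "sum of
  wavelet coefficients" and "sum of squares" are over the detail
  coefficients, and the wavelet energy is the detail fraction
  sum(d^2) / (sum(d^2) + sum(a^2)).
* Crossing counts: strict sign changes between consecutive samples of x
  (zero crossings) or x - mean (mean crossings).
* Skewness and (excess) kurtosis use population moment estimators and are
  defined as 0 for a constant window.
* IQR: Q3 - Q1 with linear-interpolation quantiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .signal_model import CHANNELS, Segment, SegmentSet

PRESSURE_FEATURES = (
    "mean", "median", "max", "min", "range", "variance", "std", "rms",
    "iqr", "mean_crossings", "kurtosis", "skewness", "fft_dc",
)
IMU_FEATURES = (
    "mean", "median", "max", "min", "range", "variance", "std", "rms",
    "iqr", "zero_crossings", "mean_crossings", "fft_dc", "entropy",
    "energy", "kurtosis", "skewness",
    "wavelet_sum", "wavelet_sq_sum", "wavelet_energy",
)


@dataclass(frozen=True)
class FeatureConfig:
    """Feature-bank configuration.

    ``include_pressure`` toggles the 13 pressure features (the with/without
    muscle-pressure comparison is a pure config switch).  ``wavelet_level``
    sets the depth of the Haar cascade whose final-level coefficients feed
    the wavelet features.
    """

    include_pressure: bool = True
    wavelet: str = "haar"
    wavelet_level: int = 1

    def feature_names(self) -> list[str]:
        names = []
        for ch in CHANNELS:
            if ch == "pressure":
                if self.include_pressure:
                    names += [f"{ch}.{f}" for f in PRESSURE_FEATURES]
            else:
                names += [f"{ch}.{f}" for f in IMU_FEATURES]
        return names

    @property
    def d(self) -> int:
        return len(self.feature_names())


@dataclass
class FeatureVector:
    values: np.ndarray
    names: list
    label: str
    subject_id: str


@dataclass
class FeatureMatrix:
    """d x n stack of feature vectors with per-column metadata.

    Columns are segments; ``y`` may be None for an unlabeled (target)
    domain.  ``domain`` tags each column "source"/"target" when relevant.
    """

    X: np.ndarray
    names: list
    y: np.ndarray | None = None
    subjects: np.ndarray | None = None
    domain: np.ndarray | None = None

    @property
    def d(self) -> int:
        return self.X.shape[0]

    @property
    def n(self) -> int:
        return self.X.shape[1]

    def write(self, path, meta_path=None) -> None:
        """CSV with feature names in the first column, segments as columns."""
        df = pd.DataFrame(self.X, index=pd.Index(self.names, name="feature"))
        df.columns = [f"seg{i}" for i in range(self.n)]
        df.to_csv(path)
        if meta_path is not None:
            import json

            meta = {
                "labels": None if self.y is None else [str(v) for v in self.y],
                "subjects": None
                if self.subjects is None
                else [str(v) for v in self.subjects],
                "domain": None
                if self.domain is None
                else [str(v) for v in self.domain],
            }
            with open(meta_path, "w") as fh:
                json.dump(meta, fh)

    @classmethod
    def read(cls, path, meta_path=None) -> "FeatureMatrix":
        df = pd.read_csv(path, index_col=0)
        y = subjects = domain = None
        if meta_path is not None:
            import json

            with open(meta_path) as fh:
                meta = json.load(fh)
            if meta.get("labels") is not None:
                y = np.array(meta["labels"], dtype=object)
            if meta.get("subjects") is not None:
                subjects = np.array(meta["subjects"], dtype=object)
            if meta.get("domain") is not None:
                domain = np.array(meta["domain"], dtype=object)
        return cls(
            X=df.to_numpy(dtype=float),
            names=list(df.index),
            y=y,
            subjects=subjects,
            domain=domain,
        )


def _haar_detail_approx(x: np.ndarray, level: int):
    """Final-level (approx, detail) of an orthonormal Haar cascade.

    Operates along the last axis; odd-length inputs drop the final sample
    at each stage (the 40-sample default divides evenly for level 1).
    """
    a = x
    for _ in range(level):
        n = a.shape[-1] - a.shape[-1] % 2
        even, odd = a[..., 0:n:2], a[..., 1:n:2]
        detail = (even - odd) / np.sqrt(2.0)
        a = (even + odd) / np.sqrt(2.0)
    return a, detail


def _strict_sign_changes(s: np.ndarray) -> np.ndarray:
    return np.sum(s[..., :-1] * s[..., 1:] < 0, axis=-1).astype(float)


def _channel_features(x: np.ndarray, imu: bool, config: FeatureConfig) -> np.ndarray:
    """Feature block for one channel; ``x`` is [n_segments, window]."""
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    mean = x.mean(axis=-1)
    var = x.var(axis=-1)  # population (ddof=0)
    std = np.sqrt(var)
    feats = {
        "mean": mean,
        "median": np.median(x, axis=-1),
        "max": x.max(axis=-1),
        "min": x.min(axis=-1),
        "range": x.max(axis=-1) - x.min(axis=-1),
        "variance": var,
        "std": std,
        "rms": np.sqrt(np.mean(x**2, axis=-1)),
        "iqr": np.percentile(x, 75, axis=-1) - np.percentile(x, 25, axis=-1),
        "mean_crossings": _strict_sign_changes(x - mean[..., None]),
    }
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # constant windows trigger scipy's cancellation warning; that case is
        # defined as 0 below
        warnings.simplefilter("ignore", RuntimeWarning)
        kurt = stats.kurtosis(x, axis=-1, fisher=True, bias=True)
        skew = stats.skew(x, axis=-1, bias=True)
    feats["kurtosis"] = np.where(std > 0, np.nan_to_num(kurt), 0.0)
    feats["skewness"] = np.where(std > 0, np.nan_to_num(skew), 0.0)

    spec = np.fft.rfft(x, axis=-1)
    feats["fft_dc"] = np.abs(spec[..., 0]) / n

    if imu:
        feats["zero_crossings"] = _strict_sign_changes(x)
        power = np.abs(spec[..., 1:]) ** 2  # one-sided, DC excluded
        total = power.sum(axis=-1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(total > 0, power / np.where(total > 0, total, 1.0), 0.0)
            plogp = np.where(p > 0, p * np.log(p), 0.0)
        feats["entropy"] = -plogp.sum(axis=-1)
        feats["energy"] = np.mean(x**2, axis=-1)
        approx, detail = _haar_detail_approx(x, config.wavelet_level)
        d2 = (detail**2).sum(axis=-1)
        a2 = (approx**2).sum(axis=-1)
        denom = d2 + a2
        feats["wavelet_sum"] = detail.sum(axis=-1)
        feats["wavelet_sq_sum"] = d2
        feats["wavelet_energy"] = np.where(denom > 0, d2 / np.where(denom > 0, denom, 1.0), 0.0)
        order = IMU_FEATURES
    else:
        order = PRESSURE_FEATURES
    return np.stack([feats[f] for f in order], axis=-1)


def _extract_block(values: np.ndarray, config: FeatureConfig) -> np.ndarray:
    """Features for a stack of segments; ``values`` is [n_seg, window, 10]."""
    blocks = []
    for j, ch in enumerate(CHANNELS):
        if ch == "pressure" and not config.include_pressure:
            continue
        blocks.append(_channel_features(values[..., j], imu=(ch != "pressure"), config=config))
    return np.concatenate(blocks, axis=-1)


def extract_features(seg: Segment, config: FeatureConfig | None = None) -> FeatureVector:
    """Turn one window into its fixed-layout feature vector."""
    config = config or FeatureConfig()
    vals = np.asarray(seg.values, dtype=float)
    if vals.ndim != 2 or vals.shape[1] != len(CHANNELS):
        raise ValueError(f"segment values must be [window, {len(CHANNELS)}]")
    if not np.all(np.isfinite(vals)):
        raise ValueError("segment contains non-finite values")
    v = _extract_block(vals[None, :, :], config)[0]
    return FeatureVector(
        values=v, names=config.feature_names(), label=seg.label, subject_id=seg.subject_id
    )


def featurize_set(segments: SegmentSet, config: FeatureConfig | None = None) -> FeatureMatrix:
    """Featurize every segment; column i is segment i's feature vector."""
    config = config or FeatureConfig()
    if len(segments) == 0:
        raise ValueError("cannot featurize an empty segment set")
    shapes = {s.values.shape for s in segments}
    if len(shapes) != 1:
        raise ValueError(f"heterogeneous segment shapes: {sorted(shapes)}")
    stack = np.stack([s.values for s in segments], axis=0)
    X = _extract_block(stack, config).T  # d x n
    return FeatureMatrix(
        X=X,
        names=config.feature_names(),
        y=segments.labels,
        subjects=segments.subjects,
    )
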