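"""Channel derivations feeding the DTW pipelines.

Twelve processing variants are compared downstream: {raw, 4-s high-pass,
first derivative} x {X, Y, Z, XYZ}.  The high-pass filter subtracts a
centred rolling mean; at the tag's 2-s cadence a conventional IIR design at
the 4-s band edge would sit exactly at Nyquist, so mean subtraction is the
well-posed way to isolate the high-frequency content.  The first derivative
of a jerk axis is snap (g s^-2 in tag units).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.stats import norm, rankdata

from .errors import DegenerateColumnError, ParameterError, ShapeError, SizeError
from .io import JerkTrace

Variant = Literal["raw", "highpass", "derivative"]
Channels = Literal["X", "Y", "Z", "XYZ"]

VARIANTS: tuple[str, ...] = ("raw", "highpass", "derivative")
CHANNELS: tuple[str, ...] = ("X", "Y", "Z", "XYZ")


@dataclass
class ProcessedSeries:
    """One fish's series under a processing variant.

    ``values`` is 1-D for a single axis or (n, 3) for the multivariate XYZ
    assembly; derivative variants are one sample shorter than their source.
    """

    fish_id: str
    variant: str
    channels: str
    values: np.ndarray
    cadence: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.channels == "XYZ":
            if self.values.ndim != 2 or self.values.shape[1] != 3:
                raise ShapeError("multivariate series must be (n, 3)")
        elif self.values.ndim != 1:
            raise ShapeError("univariate series must be 1-D")

    def __len__(self) -> int:
        return self.values.shape[0]


def compute_actvsum(jerk_x, jerk_y, jerk_z) -> np.ndarray:
    """Vectorial magnitude of jerk across the three axes, clipped to [0, 2].

    The tag computes and logs its own ActVSum channel; this recomputation is
    used for synthetic data, where the [0, 2] g s^-1 tag-scale bound is
    applied explicitly.
    """
    x, y, z = (np.asarray(a, dtype=float) for a in (jerk_x, jerk_y, jerk_z))
    if not (x.shape == y.shape == z.shape):
        raise ShapeError(f"axis length mismatch: {x.shape}, {y.shape}, {z.shape}")
    return np.clip(np.sqrt(x**2 + y**2 + z**2), 0.0, 2.0)


def highpass(series, cadence: float, window: float = 4.0) -> np.ndarray:
    """High-pass a series by subtracting its centred rolling mean.

    The mean at sample i is taken over all samples within +-window/2 seconds
    (inclusive); near the edges the window shrinks.  A constant series maps to
    identically zero, and output length equals input length.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise SizeError("highpass needs a 1-D series of length >= 2")
    if window < cadence:
        raise ParameterError(f"window {window}s shorter than cadence {cadence}s")
    half = int(np.floor(window / 2.0 / cadence + 1e-9))
    csum = np.concatenate([[0.0], np.cumsum(x)])
    n = len(x)
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1)
    means = (csum[hi + 1] - csum[lo]) / (hi - lo + 1)
    return x - means


def first_derivative(series, cadence: float) -> np.ndarray:
    """Forward difference (x[t+1] - x[t]) / cadence; output length n - 1."""
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise SizeError("first_derivative needs a 1-D series of length >= 2")
    return np.diff(x) / cadence


def make_variant(trace: JerkTrace, variant: str, channels: str) -> ProcessedSeries:
    """Build one of the 12 (variant, channels) processing combinations.

    For XYZ the transform is applied per axis and the results assembled into
    3-vectors per time step.
    """
    if variant not in VARIANTS:
        raise ParameterError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    if channels not in CHANNELS:
        raise ParameterError(f"unknown channels {channels!r}; expected one of {CHANNELS}")

    def transform(axis: np.ndarray) -> np.ndarray:
        if variant == "raw":
            return axis.copy()
        if variant == "highpass":
            return highpass(axis, trace.cadence)
        return first_derivative(axis, trace.cadence)

    per_axis = {"X": trace.jerk_x, "Y": trace.jerk_y, "Z": trace.jerk_z}
    if channels == "XYZ":
        values = np.column_stack([transform(per_axis[c]) for c in ("X", "Y", "Z")])
    else:
        values = transform(per_axis[channels])
    return ProcessedSeries(
        fish_id=trace.fish_id,
        variant=variant,
        channels=channels,
        values=values,
        cadence=trace.cadence,
    )


def all_variants() -> list[tuple[str, str]]:
    """The 12 enumerable (variant, channels) pairs."""
    return [(v, c) for v in VARIANTS for c in CHANNELS]


def zscore(values) -> np.ndarray:
    """Standardize to mean 0 and sample SD 1 (denominator n - 1)."""
    x = np.asarray(values, dtype=float)
    if len(np.unique(x)) < 2:
        raise DegenerateColumnError("zscore needs >= 2 distinct values")
    return (x - x.mean()) / x.std(ddof=1)


@dataclass
class NormalizationMap:
    """Invertible record of a rank-based inverse-normal transform.

    Stores the observed (value, quantile) support; the inverse maps normal
    scores back to the data scale by monotone linear interpolation, with
    linear extrapolation (edge slopes) beyond the observed tails.
    """

    values: np.ndarray  # sorted unique observed values
    scores: np.ndarray  # corresponding normal scores, strictly increasing

    def inverse(self, z) -> np.ndarray:
        z = np.atleast_1d(np.asarray(z, dtype=float))
        out = np.interp(z, self.scores, self.values)
        lo_slope = (self.values[1] - self.values[0]) / (self.scores[1] - self.scores[0])
        hi_slope = (self.values[-1] - self.values[-2]) / (self.scores[-1] - self.scores[-2])
        below = z < self.scores[0]
        above = z > self.scores[-1]
        out[below] = self.values[0] + (z[below] - self.scores[0]) * lo_slope
        out[above] = self.values[-1] + (z[above] - self.scores[-1]) * hi_slope
        return out

    def forward(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        out = np.interp(x, self.values, self.scores)
        lo_slope = (self.scores[1] - self.scores[0]) / (self.values[1] - self.values[0])
        hi_slope = (self.scores[-1] - self.scores[-2]) / (self.values[-1] - self.values[-2])
        below = x < self.values[0]
        above = x > self.values[-1]
        out[below] = self.scores[0] + (x[below] - self.values[0]) * lo_slope
        out[above] = self.scores[-1] + (x[above] - self.values[-1]) * hi_slope
        return out


def normalize_response(values) -> tuple[np.ndarray, NormalizationMap]:
    """Rank-based inverse-normal (ordered-quantile) transform.

    A value with (tie-averaged) rank r among n maps to the standard-normal
    quantile at (r - 0.5) / n, so the transformed column is as Gaussian as a
    rank map can make it while preserving order exactly.  Returns the
    transformed column and an invertible mapping for back-transformation of
    model predictions.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 3:
        raise SizeError(f"normalize_response needs >= 3 observations, got {n}")
    ranks = rankdata(x, method="average")
    z = norm.ppf((ranks - 0.5) / n)
    uniq_vals, first_idx = np.unique(x, return_index=True)
    if len(uniq_vals) < 2:
        raise DegenerateColumnError("normalize_response needs >= 2 distinct values")
    mapping = NormalizationMap(values=uniq_vals, scores=z[first_idx])
    return z, mapping
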