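"""Frame-level binocular matching operators.

Given a ternary stereo pair and a spatial window ``W`` of ``k`` pixels at
window disparity ``d`` (right eye sampled at ``x - d``), four operators are
defined on a single frame:

``cross_correlation``
    (1/k) sum of pixelwise products ``I_L I_R`` — the linear template that
    underlies disparity-energy selectivity; range [-1, 1].
``cross_matching``
    (1/k) sum of half-wave-rectified products ``[I_L I_R]+`` — rectification
    *inside* the window sum, i.e. at single-pixel resolution; equals the
    fraction of window pixels forming contrast-matched dotted combinations.
``generalized_cross_matching``
    ``[cross_correlation]+`` — rectification *after* the spatial average
    over the k-pixel window.
``onoff_cross_matching``
    the ON/OFF-channel rewrite ``(1/k) sum([I_L]+[I_R]+ + [-I_L]+[-I_R]+)``,
    algebraically identical to ``cross_matching`` on ternary inputs.

Expectations over frames are taken separately (:func:`tuning_curve`), so the
same pure operators serve tuning curves, signal-strength simulation and
psychophysics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stimulus import FrameSequence, GeometryError, StereoPair, split_offsets

__all__ = [
    "MatchWindow",
    "TuningCurve",
    "FRAME_OPERATORS",
    "cross_correlation_frame",
    "cross_matching_frame",
    "generalized_cross_matching_frame",
    "onoff_cross_matching_frame",
    "tuning_curve",
    "window_products",
]


@dataclass(frozen=True)
class MatchWindow:
    """A set of left-image pixel coordinates plus a window disparity.

    ``ys``/``xs`` are parallel integer arrays of the k window pixels in
    left-image coordinates; the right eye is sampled at ``x - d``.
    """

    ys: np.ndarray
    xs: np.ndarray
    d: int

    def __post_init__(self) -> None:
        ys = np.atleast_1d(np.asarray(self.ys, dtype=np.intp))
        xs = np.atleast_1d(np.asarray(self.xs, dtype=np.intp))
        object.__setattr__(self, "ys", ys)
        object.__setattr__(self, "xs", xs)
        if ys.shape != xs.shape or ys.ndim != 1 or ys.size < 1:
            raise GeometryError("ys and xs must be equal-length 1-D arrays with k >= 1")

    @property
    def k(self) -> int:
        return self.xs.size

    @classmethod
    def rect(cls, y0: int, x0: int, height: int, width: int, d: int) -> "MatchWindow":
        ys, xs = np.mgrid[y0 : y0 + height, x0 : x0 + width]
        return cls(ys.ravel(), xs.ravel(), d)

    @classmethod
    def centered(cls, image_size: int, window_size: int, d: int) -> "MatchWindow":
        """Square window centred in a square image, disparity split between eyes.

        Mirrors the stimulus geometry: the left-eye window sits at
        x-offset ``(image_size - window_size + d)//2`` and its right-eye
        counterpart at that offset minus ``d``, so both windows fit for any
        |d| <= image_size - window_size.
        """
        x_l, _ = split_offsets(image_size, window_size, d)
        y0 = (image_size - window_size) // 2
        return cls.rect(y0, x_l, window_size, window_size, d)

    def _check_bounds(self, shape: tuple[int, int]) -> None:
        H, W = shape
        xs_r = self.xs - self.d
        if (
            self.ys.min() < 0 or self.ys.max() >= H
            or self.xs.min() < 0 or self.xs.max() >= W
            or xs_r.min() < 0 or xs_r.max() >= W
        ):
            raise GeometryError(
                f"window (d={self.d}) or its shifted counterpart exits image {shape}"
            )


def window_products(left: np.ndarray, right: np.ndarray, w: MatchWindow) -> np.ndarray:
    """Pixelwise binocular products over the window, for stacked frames.

    ``left``/``right`` are ``(H, W)`` or ``(n, H, W)`` ternary arrays;
    returns products of shape ``(k,)`` or ``(n, k)`` (values in {-1, 0, 1}).
    """
    left = np.asarray(left)
    right = np.asarray(right)
    w._check_bounds(left.shape[-2:])
    lv = left[..., w.ys, w.xs]
    rv = right[..., w.ys, w.xs - w.d]
    return (lv * rv).astype(np.int8)


def cross_correlation_batch(left, right, w: MatchWindow) -> np.ndarray:
    p = window_products(left, right, w)
    return p.sum(axis=-1, dtype=np.int64) / w.k


def cross_matching_batch(left, right, w: MatchWindow) -> np.ndarray:
    p = window_products(left, right, w)
    return (p == 1).sum(axis=-1, dtype=np.int64) / w.k


def generalized_cross_matching_batch(left, right, w: MatchWindow) -> np.ndarray:
    return np.maximum(cross_correlation_batch(left, right, w), 0.0)


def onoff_cross_matching_batch(left, right, w: MatchWindow) -> np.ndarray:
    left = np.asarray(left)
    right = np.asarray(right)
    w._check_bounds(left.shape[-2:])
    lv = left[..., w.ys, w.xs].astype(np.int64)
    rv = right[..., w.ys, w.xs - w.d].astype(np.int64)
    on = np.maximum(lv, 0) * np.maximum(rv, 0)
    off = np.maximum(-lv, 0) * np.maximum(-rv, 0)
    return (on + off).sum(axis=-1) / w.k


def cross_correlation_frame(pair: StereoPair, w: MatchWindow) -> float:
    """Windowed cross-correlation of one frame; in [-1, 1]."""
    return float(cross_correlation_batch(pair.left, pair.right, w))


def cross_matching_frame(pair: StereoPair, w: MatchWindow) -> float:
    """Windowed cross-matching (rectify-then-average) of one frame; in [0, 1]."""
    return float(cross_matching_batch(pair.left, pair.right, w))


def generalized_cross_matching_frame(pair: StereoPair, w: MatchWindow) -> float:
    """Generalized cross-matching (average-then-rectify over the window)."""
    return float(generalized_cross_matching_batch(pair.left, pair.right, w))


def onoff_cross_matching_frame(pair: StereoPair, w: MatchWindow) -> float:
    """ON/OFF-channel form; equals :func:`cross_matching_frame` exactly."""
    return float(onoff_cross_matching_batch(pair.left, pair.right, w))


FRAME_OPERATORS = {
    "correlation": cross_correlation_batch,
    "matching": cross_matching_batch,
    "generalized": generalized_cross_matching_batch,
    "onoff": onoff_cross_matching_batch,
}


@dataclass(frozen=True)
class TuningCurve:
    """Mean operator output as a function of window disparity."""

    disparities: np.ndarray
    values: np.ndarray
    se: np.ndarray
    n_frames: int
    operator: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "disparity": self.disparities,
                "mean": self.values,
                "se": self.se,
                "n_frames": self.n_frames,
            }
        )

    def save(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def tuning_curve(
    seq: FrameSequence,
    operator: str,
    disparities,
    window_size: int | None = None,
) -> TuningCurve:
    """Disparity-tuning curve: per-disparity frame mean of a named operator.

    The window is a square of ``window_size`` (default: the spec's centre
    size) centred in the image with the symmetric-split convention.  One
    pass over the frames evaluates all disparities, so curves at different
    d share the identical stimulus sample.
    """
    if operator not in FRAME_OPERATORS:
        raise ValueError(
            f"unknown operator {operator!r}; choose from {sorted(FRAME_OPERATORS)}"
        )
    op = FRAME_OPERATORS[operator]
    size = window_size if window_size is not None else seq.spec.center_size
    disparities = np.asarray(list(disparities), dtype=int)
    windows = [MatchWindow.centered(seq.spec.surround_size, size, int(d)) for d in disparities]
    sums = np.zeros(len(windows))
    sq_sums = np.zeros(len(windows))
    for left, right in seq.batches():
        for i, w in enumerate(windows):
            v = op(left, right, w)
            sums[i] += v.sum()
            sq_sums[i] += (v * v).sum()
    n = seq.n_frames
    means = sums / n
    var = np.maximum(sq_sums / n - means**2, 0.0)
    se = np.sqrt(var / n)
    return TuningCurve(disparities, means, se, n, operator)
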