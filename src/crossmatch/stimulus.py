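"""Random-dot stereogram (RDS) synthesis.

Stereograms are pairs of ternary luminance-contrast images: +1 for bright
dots, -1 for dark dots, 0 for background.  A central square carrying a
horizontal disparity ``d_s`` (negative = crossed/near) is embedded in a
perfectly correlated, zero-disparity surround.  Binocular correlation ``c``
grades the stimulus continuously from correlated (c=+1) through half-matched
(c=0) to anticorrelated (c=-1): each dot is contrast-matched between the
eyes with probability (1+c)/2 and contrast-reversed otherwise.

Two stimulus families are provided:

* single-pixel dots placed by independent Bernoulli draws per pixel
  (:func:`generate_rds`), the regime in which the trinomial theory in
  :mod:`crossmatch.analytics` is exact;
* square multi-pixel dots at uniformly random positions
  (:func:`generate_dot_rds`), used with Gabor receptive fields in
  :mod:`crossmatch.energy`.

Disparity convention: ``d = x_L - x_R``.  A feature at column ``x`` in the
left eye appears at column ``x - d`` in the right eye.  Both the embedded
square and detector windows split the offset symmetrically between the two
eyes so that every |d| up to the surround margin fits inside the image.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator

import numpy as np

__all__ = [
    "RdsSpec",
    "StereoPair",
    "FrameSequence",
    "generate_rds",
    "generate_rds_batch",
    "generate_dot_rds",
    "generate_dot_rds_batch",
    "measure_pair_statistics",
    "split_offsets",
]

_TERNARY = frozenset((-1, 0, 1))


class ParameterError(ValueError):
    """A stimulus or experiment parameter violates its constraints."""


class GeometryError(ValueError):
    """A window or disparity does not fit inside the image geometry."""


def split_offsets(outer: int, inner: int, d: int) -> tuple[int, int]:
    """Left/right x-offsets of an ``inner``-wide region carrying disparity d.

    The offset is split symmetrically between the eyes, keeping the
    convention ``d = x_L - x_R``.  Raises :class:`GeometryError` if the
    shifted region would exit the outer extent.
    """
    if abs(d) > outer - inner:
        raise GeometryError(
            f"disparity {d} does not fit: |d| must be <= {outer - inner} "
            f"for inner size {inner} in outer size {outer}"
        )
    x_left = (outer - inner + d) // 2
    x_right = x_left - d
    if x_right < 0 or x_right + inner > outer:
        raise GeometryError(f"disparity {d} places right-eye region out of bounds")
    return x_left, x_right


@dataclass(frozen=True)
class RdsSpec:
    """Parameters of a dynamic random-dot stereogram.

    Attributes
    ----------
    center_size : int
        Side of the disparity-carrying central square, pixels.
    surround_size : int
        Side of the full image (zero-disparity correlated surround), pixels.
    dot_density : float
        Probability rho in [0, 1] that a pixel (or area fraction, for
        multi-pixel dots) carries a dot.
    binocular_correlation : float
        c in [-1, 1]; matched-dot fraction is (1+c)/2.
    stimulus_disparity : int
        d_s in signed pixels; negative = crossed (near).
    dot_size : int
        Side of a single square dot, pixels (1 = Bernoulli pixel dots).
    seed : int | None
        Seed for :class:`FrameSequence`; single-frame generators take an
        explicit Generator instead.
    """

    center_size: int = 32
    surround_size: int = 34
    dot_density: float = 0.25
    binocular_correlation: float = 1.0
    stimulus_disparity: int = -2
    dot_size: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.center_size <= 0 or self.surround_size <= 0:
            raise ParameterError("image dimensions must be positive integers")
        if self.surround_size < self.center_size:
            raise ParameterError(
                "surround_size must be >= center_size "
                f"({self.surround_size} < {self.center_size})"
            )
        if (
            self.dot_size == 1
            and abs(self.stimulus_disparity) > self.surround_size - self.center_size
        ):
            # the embedded square must fit within the surround; multi-pixel
            # dot stimuli carry whole-field disparity (dots clip at the edge)
            raise ParameterError(
                "stimulus_disparity exceeds the surround margin: "
                f"|{self.stimulus_disparity}| > "
                f"{self.surround_size - self.center_size}"
            )
        if not 0.0 <= self.dot_density <= 1.0:
            raise ParameterError(f"dot_density must lie in [0, 1], got {self.dot_density}")
        if not -1.0 <= self.binocular_correlation <= 1.0:
            raise ParameterError(
                f"binocular_correlation must lie in [-1, 1], got {self.binocular_correlation}"
            )
        if self.dot_size <= 0:
            raise ParameterError("dot_size must be a positive integer")
        if self.dot_size > self.center_size:
            raise ParameterError(
                f"dot_size {self.dot_size} larger than center_size {self.center_size}"
            )

    def with_(self, **changes) -> "RdsSpec":
        return replace(self, **changes)


@dataclass(frozen=True)
class StereoPair:
    """A left/right pair of ternary contrast images (int8, values -1/0/+1)."""

    left: np.ndarray
    right: np.ndarray

    def __post_init__(self) -> None:
        left = np.asarray(self.left, dtype=np.int8)
        right = np.asarray(self.right, dtype=np.int8)
        object.__setattr__(self, "left", left)
        object.__setattr__(self, "right", right)
        if left.shape != right.shape:
            raise GeometryError(
                f"left/right shapes differ: {left.shape} vs {right.shape}"
            )
        if left.ndim != 2:
            raise GeometryError("contrast images must be 2-D")
        for name, img in (("left", left), ("right", right)):
            bad = set(np.unique(img)) - _TERNARY
            if bad:
                raise ParameterError(f"{name} image has non-ternary values {sorted(bad)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.left.shape


def _ternary_field(u: np.ndarray, rho: float) -> np.ndarray:
    """Map uniforms in [0,1) to ternary contrasts: dot w.p. rho, sign fair."""
    out = np.zeros(u.shape, dtype=np.int8)
    out[u < rho / 2.0] = 1
    out[(u >= rho / 2.0) & (u < rho)] = -1
    return out


def generate_rds_batch(
    spec: RdsSpec, n_frames: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Generate ``n_frames`` independent single-pixel-dot RDS frames.

    Returns ``(left, right)`` int8 arrays of shape ``(n_frames, S, S)``.
    Per central-square pixel, independently: a dot appears with probability
    rho (bright/dark equiprobable in the left eye) and is contrast-matched
    in the right eye with probability (1+c)/2.  The surround is identical
    between the eyes (c=+1, zero disparity) at the same density.
    """
    spec.validate()
    if spec.dot_size != 1:
        raise ParameterError("generate_rds_batch requires dot_size=1; use generate_dot_rds_batch")
    if n_frames <= 0:
        raise ParameterError("n_frames must be positive")
    S, C = spec.surround_size, spec.center_size
    rho, c, ds = spec.dot_density, spec.binocular_correlation, spec.stimulus_disparity
    x_l, x_r = split_offsets(S, C, ds)
    y0 = (S - C) // 2

    surround = _ternary_field(rng.random((n_frames, S, S), dtype=np.float32), rho)
    left = surround
    right = surround.copy()

    center_left = _ternary_field(rng.random((n_frames, C, C), dtype=np.float32), rho)
    reversed_mask = rng.random((n_frames, C, C), dtype=np.float32) < (1.0 - c) / 2.0
    center_right = np.where(reversed_mask, -center_left, center_left)

    left[:, y0 : y0 + C, x_l : x_l + C] = center_left
    right[:, y0 : y0 + C, x_r : x_r + C] = center_right
    return left, right


def generate_rds(spec: RdsSpec, rng: np.random.Generator) -> StereoPair:
    """Generate one single-pixel-dot RDS frame (see :func:`generate_rds_batch`)."""
    left, right = generate_rds_batch(spec, 1, rng)
    return StereoPair(left[0], right[0])


def generate_dot_rds_batch(
    spec: RdsSpec, n_frames: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Generate frames made of ``dot_size``-square dots at random positions.

    Density is the expected fraction of pixels covered before overwriting:
    ``n_dots = round(rho * area / dot_area)``.  Dots may overlap (later dots
    win) and the whole field carries the stimulus disparity, applied by
    offsetting dot positions between the eyes (symmetric split).  Positions
    wrap horizontally (toroidal field) so that dot coverage stays uniform
    and the two eyes' monocular statistics are identical despite the
    interocular shift.  Per dot, contrast is reversed in the right eye with
    probability (1-c)/2.
    """
    spec.validate()
    if n_frames <= 0:
        raise ParameterError("n_frames must be positive")
    S = spec.surround_size
    D = spec.dot_size
    if D > S:
        raise ParameterError(f"dot_size {D} larger than image size {S}")
    rho, c, ds = spec.dot_density, spec.binocular_correlation, spec.stimulus_disparity
    n_dots = int(round(rho * S * S / (D * D)))
    left = np.zeros((n_frames, S, S), dtype=np.int8)
    right = np.zeros((n_frames, S, S), dtype=np.int8)
    if n_dots == 0:
        return left, right

    # cyclopean dot positions; per-eye x offsets by +/- d_s/2
    dx_l = ds - (ds // 2)  # symmetric split of the disparity; x_L - x_R == ds
    dx_r = dx_l - ds
    ys = rng.integers(0, S - D + 1, size=(n_frames, n_dots))
    xs = rng.integers(0, S, size=(n_frames, n_dots))  # full circle: wrap keeps stationarity
    sign = np.where(rng.random((n_frames, n_dots)) < 0.5, 1, -1).astype(np.int8)
    flip = rng.random((n_frames, n_dots)) < (1.0 - c) / 2.0
    sign_r = np.where(flip, -sign, sign).astype(np.int8)

    frame_idx = np.arange(n_frames)[:, None, None]
    rel = np.arange(D)
    for j in range(n_dots):  # sequential so later dots overwrite earlier ones
        yy = ys[:, j, None, None] + rel[None, :, None]
        _paint(left, frame_idx, yy, xs[:, j] + dx_l, sign[:, j], D, S)
        _paint(right, frame_idx, yy, xs[:, j] + dx_r, sign_r[:, j], D, S)
    return left, right


def _paint(img, frame_idx, yy, x0, value, D, S):
    """Paint D-wide rows at columns x0..x0+D-1, wrapping horizontally."""
    xx = (x0[:, None, None] + np.arange(D)[None, None, :]) % S
    img[frame_idx, yy, xx] = value[:, None, None]


def generate_dot_rds(spec: RdsSpec, rng: np.random.Generator) -> StereoPair:
    """Generate one multi-pixel-dot RDS frame (see :func:`generate_dot_rds_batch`)."""
    left, right = generate_dot_rds_batch(spec, 1, rng)
    return StereoPair(left[0], right[0])


@dataclass(frozen=True)
class FrameSequence:
    """Lazily generated sequence of independent frames sharing one spec.

    Emulates a dynamic RDS: the embedded disparity structure is fixed while
    the dot pattern refreshes every frame.  Iteration is reproducible from
    ``seed``.
    """

    spec: RdsSpec
    n_frames: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ParameterError("n_frames must be >= 1")

    def _generator(self) -> np.random.Generator:
        seed = self.seed if self.seed is not None else self.spec.seed
        return np.random.default_rng(seed)

    def batches(self, batch_size: int = 512) -> Iterator[tuple[np.ndarray, np.ndarray]]:
        """Yield ``(left, right)`` stacked-frame batches."""
        gen = (
            generate_dot_rds_batch if self.spec.dot_size > 1 else generate_rds_batch
        )
        rng = self._generator()
        remaining = self.n_frames
        while remaining > 0:
            n = min(batch_size, remaining)
            yield gen(self.spec, n, rng)
            remaining -= n

    def __iter__(self) -> Iterator[StereoPair]:
        for left, right in self.batches():
            for i in range(left.shape[0]):
                yield StereoPair(left[i], right[i])


def measure_pair_statistics(
    pair: StereoPair,
    window: tuple[np.ndarray, np.ndarray] | "object",
    d: int | None = None,
) -> tuple[float, float | None]:
    """Empirical (dotted-combination fraction, matched fraction | dotted).

    ``window`` is either a :class:`crossmatch.matching.MatchWindow` or a
    ``(ys, xs)`` coordinate pair in left-image coordinates (then ``d`` must
    be given).  Returns the fraction of window pixels whose left and right
    samples are both dots, and, among those, the fraction whose contrasts
    match; the latter is ``None`` when no dotted combination exists.
    """
    if d is None:
        ys, xs, d = window.ys, window.xs, window.d  # type: ignore[union-attr]
    else:
        ys, xs = window
    H, W = pair.shape
    xs_r = xs - d
    if (
        xs.min() < 0 or xs.max() >= W or xs_r.min() < 0 or xs_r.max() >= W
        or ys.min() < 0 or ys.max() >= H
    ):
        raise GeometryError("window or its disparity-shifted counterpart out of bounds")
    lv = pair.left[ys, xs]
    rv = pair.right[ys, xs_r]
    dotted = (lv != 0) & (rv != 0)
    n = lv.size
    n_dotted = int(dotted.sum())
    if n_dotted == 0:
        return 0.0, None
    matched = (lv[dotted] == rv[dotted]).sum()
    return n_dotted / n, float(matched / n_dotted)
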