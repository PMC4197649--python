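"""Closed-form expectations and exact distributions for the matching operators.

For a k-pixel window each binocular pixel combination is, independently,
contrast-matched, contrast-reversed, or background with probabilities
``p = (p_m, p_r, p_b)``:

* window aligned with the stimulus plane: ``p = ((1+c)rho/2, (1-c)rho/2, 1-rho)``
* window elsewhere:                      ``p = (rho^2/2, rho^2/2, 1-rho^2)``

The combination counts ``n = (n_m, n_r, n_b)`` are trinomial, the
cross-correlation of a frame is ``(n_m-n_r)/k``, and the cross-matching is
``n_m/k``.  Signed signal strength is the operator's expectation at the
aligned disparity minus its baseline elsewhere:

* cross-correlation:          ``S_C = c rho``
* cross-matching:             ``S_M = (c+1) rho/2 - rho^2/2``
* generalized cross-matching: ``S_G(k) = E[[n_m-n_r]+]/k`` (aligned minus
  baseline), with ``S_G(1) = S_M`` and ``S_G(inf) = [c rho]+``.

The Monte-Carlo :func:`sd_surface` measures the trial-to-trial variability
of the opponent (near-minus-far) differential signal on simulated RDSs,
including the covariance induced by the two windows sharing pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import binom

from .matching import FRAME_OPERATORS, MatchWindow
from .stimulus import ParameterError, RdsSpec, generate_rds_batch

__all__ = [
    "ProbabilityTriple",
    "CombinationCounts",
    "DistributionSummary",
    "SignalSurface",
    "combination_probabilities",
    "expected_value",
    "signal_strength_correlation",
    "signal_strength_matching",
    "signal_strength_generalized",
    "trinomial_pmf",
    "operator_distribution",
    "sd_surface",
    "sd_surfaces",
    "expected_surface",
    "default_c_grid",
    "default_rho_grid",
]

#: Combination codes: cross-correlation scores (matched, reversed, background)
#: as (1, -1, 0); cross-matching rectifies them to (1, 0, 0).
CODES = (1, -1, 0)
CODES_RECTIFIED = (1, 0, 0)


class ProbabilityTriple(NamedTuple):
    """(p_matched, p_reversed, p_background); sums to one."""

    p_m: float
    p_r: float
    p_b: float

    def validate(self) -> "ProbabilityTriple":
        if any(not 0.0 <= p <= 1.0 for p in self):
            raise ParameterError(f"probabilities must lie in [0, 1]: {self}")
        if abs(sum(self) - 1.0) > 1e-12:
            raise ParameterError(f"probabilities must sum to 1: {self}")
        return self


class CombinationCounts(NamedTuple):
    """(n_matched, n_reversed, n_background) pixel counts in a window."""

    n_m: int
    n_r: int
    n_b: int

    @property
    def k(self) -> int:
        return self.n_m + self.n_r + self.n_b


def _check_params(c: float, rho: float) -> None:
    if not -1.0 <= c <= 1.0:
        raise ParameterError(f"binocular correlation must lie in [-1, 1], got {c}")
    if not 0.0 <= rho <= 1.0:
        raise ParameterError(f"dot density must lie in [0, 1], got {rho}")


def combination_probabilities(c: float, rho: float, at_match: bool) -> ProbabilityTriple:
    """Probabilities of (matched, reversed, background) combinations.

    ``at_match=True`` gives the vector for a window aligned with the
    stimulus disparity; ``False`` the vector at any other disparity, where
    left and right samples are independent dots.
    """
    _check_params(c, rho)
    if at_match:
        p = ProbabilityTriple((1 + c) * rho / 2, (1 - c) * rho / 2, 1 - rho)
    else:
        p = ProbabilityTriple(rho**2 / 2, rho**2 / 2, 1 - rho**2)
    return p.validate()


def expected_value(model: str, c: float, rho: float, at_match: bool) -> float:
    """Expected frame-operator output (codes dotted with the probability vector)."""
    p = combination_probabilities(c, rho, at_match)
    if model == "correlation":
        codes = CODES
    elif model == "matching":
        codes = CODES_RECTIFIED
    else:
        raise ValueError(f"unknown model {model!r}; choose 'correlation' or 'matching'")
    return float(np.dot(codes, p))


def signal_strength_correlation(c, rho):
    """S_C = c*rho: peak-minus-baseline of cross-correlation (vectorized)."""
    c = np.asarray(c, dtype=float)
    rho = np.asarray(rho, dtype=float)
    return c * rho


def signal_strength_matching(c, rho):
    """S_M = (c+1)rho/2 - rho^2/2: peak-minus-baseline of cross-matching.

    Not separable in c and rho; its zero contour is the line c = rho - 1,
    and at c=0 it is maximal at rho = 1/2.
    """
    c = np.asarray(c, dtype=float)
    rho = np.asarray(rho, dtype=float)
    return (c + 1) * rho / 2 - rho**2 / 2


def _rectified_difference_mean(k: int, p: ProbabilityTriple) -> float:
    """E[[n_m - n_r]+] under the trinomial(k, p), by O(k^2) enumeration.

    Only pairs with n_m > n_r contribute; n_b is marginalized analytically
    (it is fixed by k - n_m - n_r).  Stable in log space.
    """
    n_m, n_r = np.meshgrid(np.arange(k + 1), np.arange(k + 1), indexing="ij")
    mask = (n_m > n_r) & (n_m + n_r <= k)
    n_m = n_m[mask]
    n_r = n_r[mask]
    n_b = k - n_m - n_r
    with np.errstate(divide="ignore", invalid="ignore"):
        log_terms = (
            gammaln(k + 1)
            - gammaln(n_m + 1)
            - gammaln(n_r + 1)
            - gammaln(n_b + 1)
            + np.where(n_m > 0, n_m * np.log(np.maximum(p.p_m, 1e-300)), 0.0)
            + np.where(n_r > 0, n_r * np.log(np.maximum(p.p_r, 1e-300)), 0.0)
            + np.where(n_b > 0, n_b * np.log(np.maximum(p.p_b, 1e-300)), 0.0)
        )
    # zero-probability categories with nonzero counts contribute nothing
    dead = ((p.p_m == 0) & (n_m > 0)) | ((p.p_r == 0) & (n_r > 0)) | ((p.p_b == 0) & (n_b > 0))
    weights = np.where(dead, 0.0, np.exp(log_terms))
    return float(np.sum((n_m - n_r) * weights))


def signal_strength_generalized(c: float, rho: float, k) -> float:
    """S_G(c, rho | k): signal strength of generalized cross-matching.

    ``k`` is the pixel count of the pre-threshold averaging window; pass
    ``math.inf`` (or the string ``"inf"``) for the infinite-window limit,
    which equals the half-wave-rectified cross-correlation ``[c rho]+``.
    """
    _check_params(c, rho)
    if k == "inf" or (isinstance(k, float) and math.isinf(k)):
        return float(max(c * rho, 0.0))
    k = int(k)
    if k < 1:
        raise ParameterError(f"window size k must be >= 1 or inf, got {k}")
    peak = _rectified_difference_mean(k, combination_probabilities(c, rho, True)) / k
    base = _rectified_difference_mean(k, combination_probabilities(c, rho, False)) / k
    return peak - base


def trinomial_pmf(n: CombinationCounts, p: ProbabilityTriple) -> float:
    """Probability of counts ``n`` under trinomial(k, p), stable for large k."""
    n = CombinationCounts(*n)
    p = ProbabilityTriple(*p).validate()
    if any(v < 0 for v in n):
        raise ParameterError(f"counts must be nonnegative: {n}")
    from scipy.stats import multinomial

    return float(multinomial.pmf(list(n), n=n.k, p=list(p)))


@dataclass(frozen=True)
class DistributionSummary:
    """Exact pmf of a frame operator, with a central 95% interval.

    The interval is equal-tail on the discrete pmf: each side excludes at
    most 2.5% mass, so the enclosed mass is >= 95%.
    """

    support: np.ndarray
    probabilities: np.ndarray
    interval: tuple[float, float]

    def mean(self) -> float:
        return float(np.dot(self.support, self.probabilities))

    def sd(self) -> float:
        m = self.mean()
        return float(np.sqrt(np.dot((self.support - m) ** 2, self.probabilities)))


def _equal_tail_interval(support: np.ndarray, probs: np.ndarray, mass: float = 0.95):
    tail = (1.0 - mass) / 2.0
    cdf = np.cumsum(probs)
    below = cdf - probs  # P(X < x)
    above = 1.0 - cdf  # P(X > x)
    lo_candidates = np.where(below <= tail + 1e-12)[0]
    hi_candidates = np.where(above <= tail + 1e-12)[0]
    lo = support[lo_candidates[-1]]
    hi = support[hi_candidates[0]]
    return float(lo), float(hi)


def operator_distribution(
    model: str, c: float, rho: float, k: int, at_match: bool
) -> DistributionSummary:
    """Exact distribution of the frame operator over random dot patterns.

    cross-matching output ``n_m/k`` is binomial; cross-correlation output
    ``(n_m-n_r)/k`` is aggregated from the full trinomial over (n_m, n_r).
    """
    if k < 1:
        raise ParameterError("k must be >= 1")
    p = combination_probabilities(c, rho, at_match)
    if model == "matching":
        n = np.arange(k + 1)
        probs = binom.pmf(n, k, p.p_m)
        support = n / k
        keep = probs > 0
        support, probs = support[keep], probs[keep]
    elif model == "correlation":
        n_m, n_r = np.meshgrid(np.arange(k + 1), np.arange(k + 1), indexing="ij")
        mask = n_m + n_r <= k
        n_m, n_r = n_m[mask], n_r[mask]
        n_b = k - n_m - n_r
        with np.errstate(divide="ignore"):
            log_terms = (
                gammaln(k + 1)
                - gammaln(n_m + 1)
                - gammaln(n_r + 1)
                - gammaln(n_b + 1)
                + np.where(n_m > 0, n_m * np.log(np.maximum(p.p_m, 1e-300)), 0.0)
                + np.where(n_r > 0, n_r * np.log(np.maximum(p.p_r, 1e-300)), 0.0)
                + np.where(n_b > 0, n_b * np.log(np.maximum(p.p_b, 1e-300)), 0.0)
            )
        dead = (
            ((p.p_m == 0) & (n_m > 0))
            | ((p.p_r == 0) & (n_r > 0))
            | ((p.p_b == 0) & (n_b > 0))
        )
        weights = np.where(dead, 0.0, np.exp(log_terms))
        diff = n_m - n_r + k  # shift to [0, 2k] for bincount
        agg = np.bincount(diff, weights=weights, minlength=2 * k + 1)
        support = (np.arange(2 * k + 1) - k) / k
        keep = agg > 0
        support, probs = support[keep], agg[keep]
    else:
        raise ValueError(f"unknown model {model!r}; choose 'correlation' or 'matching'")
    probs = probs / probs.sum()  # renormalize away rounding at large k
    interval = _equal_tail_interval(support, probs)
    return DistributionSummary(support, probs, interval)


@dataclass(frozen=True)
class SignalSurface:
    """A quantity tabulated over a (binocular correlation, dot density) grid."""

    model: str
    c_values: np.ndarray
    rho_values: np.ndarray
    values: np.ndarray  # shape (len(rho_values), len(c_values))

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.rho_values), len(self.c_values)):
            raise ParameterError("surface values inconsistent with grid dimensions")

    def max(self) -> float:
        return float(np.max(self.values))

    def to_frame(self) -> pd.DataFrame:
        cc, rr = np.meshgrid(self.c_values, self.rho_values)
        return pd.DataFrame(
            {
                "correlation": cc.ravel(),
                "density": rr.ravel(),
                "value": self.values.ravel(),
                "model": self.model,
            }
        )

    def save(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def default_c_grid() -> np.ndarray:
    return np.round(np.arange(-1.0, 1.0 + 1e-9, 0.1), 10)


def default_rho_grid() -> np.ndarray:
    return np.round(np.arange(0.05, 1.0 + 1e-9, 0.05), 10)


def expected_surface(model: str, c_grid=None, rho_grid=None, k=None) -> SignalSurface:
    """Closed-form expected signal strength on a (c, rho) grid."""
    c = default_c_grid() if c_grid is None else np.asarray(c_grid, dtype=float)
    rho = default_rho_grid() if rho_grid is None else np.asarray(rho_grid, dtype=float)
    cc, rr = np.meshgrid(c, rho)
    if model == "correlation":
        vals = signal_strength_correlation(cc, rr)
        tag = "correlation"
    elif model == "matching":
        vals = signal_strength_matching(cc, rr)
        tag = "matching"
    elif model == "generalized":
        if k is None:
            raise ParameterError("generalized surface requires a window size k")
        vals = np.array(
            [[signal_strength_generalized(ci, ri, k) for ci in c] for ri in rho]
        )
        tag = f"generalized(k={k})"
    else:
        raise ValueError(f"unknown model {model!r}")
    return SignalSurface(tag, c, rho, np.asarray(vals, dtype=float))


def sd_surfaces(
    models: Sequence[str],
    c_grid=None,
    rho_grid=None,
    k: int = 1024,
    n_patterns: int = 1000,
    n_runs: int = 200,
    seed: int | None = None,
    stimulus_disparity: int = -2,
    surround_size: int | None = None,
) -> dict[str, SignalSurface]:
    """Monte-Carlo SD of the opponent differential signal over a (c, rho) grid.

    For each grid cell, ``n_patterns`` RDS frames (center sqrt(k) x sqrt(k),
    surround two pixels larger unless overridden, stimulus disparity
    ``stimulus_disparity``) are simulated; the near (d = d_s) and far
    (d = -d_s) window outputs are differenced per frame, the SD across
    frames is taken, and SDs are averaged over ``n_runs`` repetitions.
    Several operators can be measured on the identical stimulus sample in
    one pass.
    """
    side = math.isqrt(k)
    if side * side != k:
        raise ParameterError(f"k={k} must be a perfect square (window side)")
    S = surround_size if surround_size is not None else side + 2
    c = default_c_grid() if c_grid is None else np.asarray(c_grid, dtype=float)
    rho = default_rho_grid() if rho_grid is None else np.asarray(rho_grid, dtype=float)
    for m in models:
        if m not in FRAME_OPERATORS:
            raise ValueError(f"unknown operator {m!r}")
    near = MatchWindow.centered(S, side, stimulus_disparity)
    far = MatchWindow.centered(S, side, -stimulus_disparity)
    rng = np.random.default_rng(seed)
    out = {m: np.zeros((len(rho), len(c))) for m in models}
    for i, r in enumerate(rho):
        for j, cv in enumerate(c):
            if r == 0:
                continue
            spec = RdsSpec(
                center_size=side,
                surround_size=S,
                dot_density=float(r),
                binocular_correlation=float(cv),
                stimulus_disparity=stimulus_disparity,
            )
            acc = {m: 0.0 for m in models}
            for _ in range(n_runs):
                left, right = generate_rds_batch(spec, n_patterns, rng)
                for m in models:
                    op = FRAME_OPERATORS[m]
                    diff = op(left, right, near) - op(left, right, far)
                    acc[m] += float(np.std(diff, ddof=1))
            for m in models:
                out[m][i, j] = acc[m] / n_runs
    return {
        m: SignalSurface(f"sd({m})", c, rho, out[m]) for m in models
    }


def sd_surface(
    model: str,
    c_grid=None,
    rho_grid=None,
    k: int = 1024,
    n_patterns: int = 1000,
    n_runs: int = 200,
    seed: int | None = None,
    **kwargs,
) -> SignalSurface:
    """Single-operator convenience wrapper around :func:`sd_surfaces`."""
    return sd_surfaces(
        [model], c_grid, rho_grid, k, n_patterns, n_runs, seed, **kwargs
    )[model]
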