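"""Two-alternative forced-choice near/far discrimination by opponent decoding.

A near-preferring and a far-preferring detector view the same dynamic RDS.
On each trial the detector responses are averaged over a fixed number of
independent dot patterns, the far response is subtracted from the near
response, a single draw of Gaussian decision noise is added, and the sign
of the result yields the choice (near if positive; exact ties broken by a
fair coin).  Percent correct pools crossed trials (correct answer: near)
and uncrossed trials (correct answer: far) at each binocular-correlation
level, yielding a psychometric function of graded anticorrelation.

Four detector models are supported: the window operators ``correlation``
and ``matching`` (windows at d = -/+|d_s| on the square-in-surround RDS)
and the Gabor-based ``energy`` and ``threshold_energy`` detectors (units
at position disparities -/+|d_s| on multi-pixel-dot RDSs).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .energy import (
    EnergyUnit,
    GaborParams,
    energy_response_batch,
    make_energy_unit,
    threshold_energy_response_batch,
)
from .matching import FRAME_OPERATORS, MatchWindow
from .stimulus import (
    ParameterError,
    RdsSpec,
    generate_dot_rds_batch,
    generate_rds_batch,
)

__all__ = [
    "DecisionConfig",
    "PsychometricCurve",
    "run_trial",
    "psychometric_curve",
    "density_sweep",
    "noise_sweep",
    "estimate_zero_crossing",
    "WINDOW_MODELS",
    "ENERGY_MODELS",
]

WINDOW_MODELS = ("correlation", "matching")
ENERGY_MODELS = ("energy", "threshold_energy")

#: frames per batch cap when simulating many trials at once
_BATCH_FRAMES = 20000


@dataclass(frozen=True)
class DecisionConfig:
    """Decision-stage parameters of the simulated 2AFC task.

    ``noise_sigma`` is on the scale of the frame-averaged differential
    response: 0.1 suits the window operators (outputs in [-1, 1]); the
    energy detectors use raw inner-product units, where 1000 plays the
    same role.  Trials are organised as ``trials_per_side_per_block``
    crossed plus the same number uncrossed per block, times ``n_blocks``
    (defaults: 30 x 2 x 20 = 1200 trials per point).
    """

    frames_per_trial: int = 16
    noise_sigma: float = 0.1
    trials_per_side_per_block: int = 30
    n_blocks: int = 20
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.frames_per_trial < 1 or self.trials_per_side_per_block < 1 or self.n_blocks < 1:
            raise ParameterError("all trial counts must be positive")
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be >= 0")

    @property
    def trials_per_side(self) -> int:
        return self.trials_per_side_per_block * self.n_blocks

    @property
    def trials_per_point(self) -> int:
        return 2 * self.trials_per_side


def _window_detectors(spec: RdsSpec) -> tuple[MatchWindow, MatchWindow]:
    mag = abs(spec.stimulus_disparity)
    S, C = spec.surround_size, spec.center_size
    return MatchWindow.centered(S, C, -mag), MatchWindow.centered(S, C, +mag)


def _energy_detectors(gabor: GaborParams) -> tuple[EnergyUnit, EnergyUnit]:
    return make_energy_unit(gabor, -1), make_energy_unit(gabor, +1)


def trial_differentials(
    model: str,
    spec: RdsSpec,
    n_trials: int,
    cfg: DecisionConfig,
    rng: np.random.Generator,
    gabor: GaborParams | None = None,
) -> np.ndarray:
    """Noise-free near-minus-far differential, frame-averaged, per trial."""
    fpt = cfg.frames_per_trial
    n_frames = n_trials * fpt
    if model in WINDOW_MODELS:
        near, far = _window_detectors(spec)
        op = FRAME_OPERATORS[model]
        gen = generate_rds_batch

        def diff(left, right):
            return op(left, right, near) - op(left, right, far)

    elif model in ENERGY_MODELS:
        g = gabor if gabor is not None else GaborParams()
        near_u, far_u = _energy_detectors(g)
        resp = (
            energy_response_batch if model == "energy" else threshold_energy_response_batch
        )
        gen = generate_dot_rds_batch

        def diff(left, right):
            return resp(left, right, near_u) - resp(left, right, far_u)

    else:
        raise ValueError(
            f"unknown model {model!r}; choose from {WINDOW_MODELS + ENERGY_MODELS}"
        )

    chunks = []
    done = 0
    while done < n_frames:
        n = min(_BATCH_FRAMES, n_frames - done)
        left, right = gen(spec, n, rng)
        chunks.append(diff(left, right))
        done += n
    return np.concatenate(chunks).reshape(n_trials, fpt).mean(axis=1)


def _decide_near(diffs: np.ndarray, cfg: DecisionConfig, rng: np.random.Generator) -> np.ndarray:
    """Boolean 'near' choices from noise-corrupted differentials."""
    s = diffs + (rng.normal(0.0, cfg.noise_sigma, size=diffs.shape) if cfg.noise_sigma > 0 else 0.0)
    ties = s == 0.0
    near = s > 0.0
    if np.any(ties):
        near = near | (ties & (rng.random(size=diffs.shape) < 0.5))
    return near


def run_trial(
    model: str,
    spec: RdsSpec,
    cfg: DecisionConfig,
    rng: np.random.Generator,
    gabor: GaborParams | None = None,
) -> str:
    """Simulate a single 2AFC trial; returns ``"near"`` or ``"far"``."""
    d = trial_differentials(model, spec, 1, cfg, rng, gabor)
    return "near" if bool(_decide_near(d, cfg, rng)[0]) else "far"


@dataclass(frozen=True)
class PsychometricCurve:
    """Percent correct vs binocular correlation at one dot density."""

    model: str
    density: float
    noise_sigma: float
    levels: np.ndarray
    percent_correct: np.ndarray
    n_trials: np.ndarray

    def __post_init__(self) -> None:
        lv = np.asarray(self.levels, dtype=float)
        if lv.size >= 2 and not np.all(np.diff(lv) > 0):
            raise ParameterError("correlation levels must be strictly increasing")
        if np.any(self.percent_correct < 0) or np.any(self.percent_correct > 100):
            raise ParameterError("percent correct must lie in [0, 100]")

    @property
    def zero_crossing(self) -> float | None:
        return estimate_zero_crossing(self)

    def to_frame(self) -> pd.DataFrame:
        se = np.sqrt(
            np.maximum(self.percent_correct * (100 - self.percent_correct), 0.0)
            / self.n_trials
        )
        return pd.DataFrame(
            {
                "model": self.model,
                "density": self.density,
                "noise_sigma": self.noise_sigma,
                "correlation": self.levels,
                "n_trials": self.n_trials,
                "percent_correct": self.percent_correct,
                "se": se,
            }
        )

    def save(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def psychometric_curve(
    model: str,
    rho: float,
    levels,
    cfg: DecisionConfig | None = None,
    seed: int | None = None,
    spec: RdsSpec | None = None,
    gabor: GaborParams | None = None,
) -> PsychometricCurve:
    """Simulate percent correct across binocular-correlation levels.

    ``spec`` provides the stimulus geometry (defaults: 32-in-34 square RDS
    with |d_s| = 2 px for window models; 24 px field of 8 px dots with
    |d_s| = 8 px for energy models); its density and correlation fields are
    overridden per point, its disparity magnitude defines the task.
    """
    cfg = cfg if cfg is not None else DecisionConfig()
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(seed)
    if spec is None:
        if model in ENERGY_MODELS:
            spec = RdsSpec(
                center_size=24, surround_size=24, dot_size=8, stimulus_disparity=-8
            )
        else:
            spec = RdsSpec()
    levels = np.asarray(sorted(float(c) for c in levels))
    if np.any(np.abs(levels) > 1):
        raise ParameterError("correlation levels must lie in [-1, 1]")
    mag = abs(spec.stimulus_disparity)
    n_side = cfg.trials_per_side
    pc = np.zeros(levels.size)
    for i, c in enumerate(levels):
        correct = 0
        for ds, near_is_correct in ((-mag, True), (+mag, False)):
            s = replace(
                spec,
                dot_density=float(rho),
                binocular_correlation=float(c),
                stimulus_disparity=ds,
            )
            d = trial_differentials(model, s, n_side, cfg, rng, gabor)
            near = _decide_near(d, cfg, rng)
            correct += int(near.sum()) if near_is_correct else int((~near).sum())
        pc[i] = 100.0 * correct / (2 * n_side)
    return PsychometricCurve(
        model, float(rho), cfg.noise_sigma, levels, pc,
        np.full(levels.size, cfg.trials_per_point),
    )


def density_sweep(
    model: str,
    densities=(0.25, 0.5, 0.75, 1.0),
    levels=None,
    cfg: DecisionConfig | None = None,
    seed: int | None = None,
    spec: RdsSpec | None = None,
    gabor: GaborParams | None = None,
) -> list[PsychometricCurve]:
    """One psychometric curve per dot density (default 25/50/75/100%)."""
    if levels is None:
        levels = np.round(np.arange(-1.0, 1.0 + 1e-9, 0.25), 10)
    rng = np.random.default_rng(seed)
    return [
        psychometric_curve(
            model, rho, levels, cfg,
            seed=int(rng.integers(2**31)), spec=spec, gabor=gabor,
        )
        for rho in densities
    ]


def noise_sweep(
    model: str,
    sigmas=(0.025, 0.05, 0.1, 0.2),
    densities=(0.25, 0.5, 0.75, 1.0),
    levels=None,
    cfg: DecisionConfig | None = None,
    seed: int | None = None,
    spec: RdsSpec | None = None,
    gabor: GaborParams | None = None,
) -> dict[tuple[float, float], PsychometricCurve]:
    """Curves on a (noise sigma, density) grid, keyed by (sigma, density)."""
    cfg = cfg if cfg is not None else DecisionConfig()
    rng = np.random.default_rng(seed)
    out = {}
    for sigma in sigmas:
        for rho in densities:
            out[(float(sigma), float(rho))] = psychometric_curve(
                model, rho, levels if levels is not None
                else np.round(np.arange(-1.0, 1.0 + 1e-9, 0.25), 10),
                replace(cfg, noise_sigma=float(sigma)),
                seed=int(rng.integers(2**31)), spec=spec, gabor=gabor,
            )
    return out


def estimate_zero_crossing(curve: PsychometricCurve) -> float | None:
    """Correlation at which the curve crosses 50%, by linear interpolation.

    Uses the first pair of adjacent levels bracketing 50% (rising through
    chance); returns ``None`` when no bracket exists.
    """
    lv = np.asarray(curve.levels, dtype=float)
    pc = np.asarray(curve.percent_correct, dtype=float)
    if lv.size < 2:
        return None
    resid = pc - 50.0
    for i in range(lv.size - 1):
        a, b = resid[i], resid[i + 1]
        if a == 0.0:
            return float(lv[i])
        if a < 0.0 <= b or a > 0.0 >= b:
            if b == a:
                return float(lv[i])
            return float(lv[i] - a * (lv[i + 1] - lv[i]) / (b - a))
    if resid[-1] == 0.0:
        return float(lv[-1])
    return None
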