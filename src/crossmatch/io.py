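"""Serialization: half-images, text grids, and flat experiment configs.

Half-images are written as portable grayscale images (PGM/PNG via Pillow)
with background 128, dark dots 0, bright dots 255, and as delimited text
grids of the raw ternary codes.  Experiment configuration is a flat
key-value YAML file whose defaults are the package's reference stimulus
and decision parameters; unknown keys are rejected so a typo cannot
silently change an experiment.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from .energy import GaborParams
from .psychophysics import DecisionConfig
from .stimulus import ParameterError, RdsSpec, StereoPair

__all__ = [
    "ExperimentConfig",
    "save_image",
    "load_image",
    "save_text_grid",
    "load_text_grid",
    "save_pair",
    "load_pair",
]

_LEVELS = {-1: 0, 0: 128, 1: 255}
_CODES = {0: -1, 128: 0, 255: 1}


def save_image(img: np.ndarray, path) -> None:
    """Write a ternary contrast image as 8-bit grayscale (format by suffix)."""
    img = np.asarray(img)
    gray = np.zeros(img.shape, dtype=np.uint8)
    for code, level in _LEVELS.items():
        gray[img == code] = level
    Image.fromarray(gray, mode="L").save(path)


def load_image(path) -> np.ndarray:
    """Read a grayscale half-image back to ternary codes (0/128/255 only)."""
    gray = np.asarray(Image.open(path).convert("L"))
    out = np.zeros(gray.shape, dtype=np.int8)
    seen = set(np.unique(gray).tolist())
    bad = seen - set(_LEVELS.values())
    if bad:
        raise ParameterError(f"image has gray levels {sorted(bad)}; expected 0/128/255")
    for level, code in _CODES.items():
        out[gray == level] = code
    return out


def save_text_grid(img: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(img, dtype=int), fmt="%d", delimiter="\t")


def load_text_grid(path) -> np.ndarray:
    return np.loadtxt(path, dtype=np.int8, delimiter="\t", ndmin=2)


def save_pair(pair: StereoPair, directory, stem: str = "rds", fmt: str = "pgm") -> tuple[Path, Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    left = directory / f"{stem}_left.{fmt}"
    right = directory / f"{stem}_right.{fmt}"
    save_image(pair.left, left)
    save_image(pair.right, right)
    return left, right


def load_pair(left_path, right_path) -> StereoPair:
    return StereoPair(load_image(left_path), load_image(right_path))


@dataclass(frozen=True)
class ExperimentConfig:
    """Flat parameter set driving the command-line experiments.

    Defaults are the reference conditions used throughout the package:
    32-in-34 single-pixel RDS at 25% density, disparity -2 px, 16 frames
    per trial, decision noise 0.1, 1200 trials per psychometric point, and
    the 24-px Gabor geometry for the energy detectors.
    """

    # stimulus
    center_size: int = 32
    surround_size: int = 34
    dot_density: float = 0.25
    binocular_correlation: float = 1.0
    stimulus_disparity: int = -2
    dot_size: int = 1
    # decision stage
    frames_per_trial: int = 16
    noise_sigma: float = 0.1
    trials_per_side_per_block: int = 30
    n_blocks: int = 20
    # Gabor energy detectors
    sigma_deg: float = 0.05
    carrier_freq_cpd: float = 10.0
    pixel_pitch_deg: float = 0.0175
    field_size: int = 24
    position_disparity_deg: float = 0.14
    gabor_amplitude: float = 8.0
    # simulation sizes
    n_frames: int = 1000
    n_patterns: int = 1000
    n_runs: int = 200
    window_k: int = 1024
    seed: int = 0

    def rds_spec(self, **overrides) -> RdsSpec:
        base = dict(
            center_size=self.center_size,
            surround_size=self.surround_size,
            dot_density=self.dot_density,
            binocular_correlation=self.binocular_correlation,
            stimulus_disparity=self.stimulus_disparity,
            dot_size=self.dot_size,
        )
        base.update(overrides)
        return RdsSpec(**base)

    def decision_config(self, **overrides) -> DecisionConfig:
        base = dict(
            frames_per_trial=self.frames_per_trial,
            noise_sigma=self.noise_sigma,
            trials_per_side_per_block=self.trials_per_side_per_block,
            n_blocks=self.n_blocks,
        )
        base.update(overrides)
        return DecisionConfig(**base)

    def gabor_params(self, **overrides) -> GaborParams:
        base = dict(
            sigma_deg=self.sigma_deg,
            carrier_freq_cpd=self.carrier_freq_cpd,
            pixel_pitch_deg=self.pixel_pitch_deg,
            field_size=self.field_size,
            position_disparity_deg=self.position_disparity_deg,
            amplitude=self.gabor_amplitude,
        )
        base.update(overrides)
        return GaborParams(**base)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "ExperimentConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(
                f"unknown config keys {sorted(unknown)}; known keys: {sorted(known)}"
            )
        return cls(**data)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ParameterError("config file must hold a flat key-value mapping")
        return cls.from_dict(data)

    def hash(self) -> str:
        canonical = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]
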