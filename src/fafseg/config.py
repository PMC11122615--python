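"""Threshold configuration shared by the metric and map-building stages.

All thresholds that govern the ternary labeling, the edge/area-error
partition and the intensity-calibration baseline live in one dataclass so
that a single YAML file fully determines a pipeline run.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml


@dataclasses.dataclass
class MetricConfig:
    """Thresholds for segmentation evaluation and ternary map construction.

    Attributes
    ----------
    mu_ee_max:
        Largest edge-error distance threshold (pixels) used when averaging
        the area-error-adjusted Dice over thresholds ``0..mu_ee_max``.
    mu_c, mu_p:
        Upper/lower probability thresholds for the single-map ternary rule
        (``p >= mu_c`` is confident, ``p <= mu_p`` is background, anything
        in between is potential).
    mu_mean, mu_var:
        Ensemble mean/variance thresholds for the two-map ternary rule.
    mu_a_c, mu_a_p:
        Expert-count thresholds for the annotation-stack ternary rule
        (confident requires at least ``mu_a_c`` raters, potential at least
        ``mu_a_p``).
    mu_he:
        Intensity-probability threshold of the intensity-calibration
        baseline.
    mu_seg:
        Probability threshold turning an ensemble mean map into a binary
        segmentation (foreground strictly above the threshold).
    """

    mu_ee_max: int = 100
    mu_c: float = 0.9
    mu_p: float = 0.1
    mu_mean: float = 0.2
    mu_var: float = 0.1
    mu_a_c: int = 5
    mu_a_p: int = 2
    mu_he: float = 0.07
    mu_seg: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.mu_p < self.mu_c <= 1.0):
            raise ValueError("thresholds must satisfy 0 <= mu_p < mu_c <= 1")
        if not (1 <= self.mu_a_p <= self.mu_a_c):
            raise ValueError("expert-count thresholds must satisfy 1 <= mu_a_p <= mu_a_c")
        if self.mu_ee_max < 0:
            raise ValueError("mu_ee_max must be non-negative")
        for name in ("mu_mean", "mu_var", "mu_he", "mu_seg"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "MetricConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def load_config(path: str | Path) -> MetricConfig:
    """Read a :class:`MetricConfig` from a YAML file (missing keys default)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return MetricConfig.from_dict(data)


def save_config(config: MetricConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
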