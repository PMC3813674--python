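"""Run configuration: flat key-value files binding prior, link and design.

A configuration file is a flat YAML mapping whose keys use the block
prefixes ``prior.`` and ``link.`` (e.g. ``prior.alpha0: 1.0``,
``link.rt_slope: 20``).  Unknown keys are rejected outright so that typos
fail fast rather than silently falling back to defaults.
"""
from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .belief import ConfigError, PriorConfig
from .rt_link import LinkParams

_TOP_KEYS = {"experiment", "n_subjects", "seed", "outlier_fraction", "group"}
_PRIOR_KEYS = {f.name for f in dataclasses.fields(PriorConfig)}
_LINK_KEYS = {f.name for f in dataclasses.fields(LinkParams)}


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to regenerate and reanalyze one experiment run."""

    experiment: str = "exp1"
    group: str | None = None  # exp2 only; None means both groups
    n_subjects: int | None = None  # None: the design's default
    seed: int = 0
    outlier_fraction: float = 0.005
    prior: PriorConfig = field(default_factory=PriorConfig)
    link: LinkParams = field(default_factory=LinkParams)

    def __post_init__(self) -> None:
        if self.experiment not in ("exp1", "exp2"):
            raise ConfigError(f"experiment must be exp1 or exp2, got {self.experiment!r}")
        if not 0 <= self.outlier_fraction < 1:
            raise ConfigError(
                f"outlier_fraction must be in [0, 1), got {self.outlier_fraction}"
            )

    def digest(self) -> str:
        """Stable hash of the full configuration, for run logs."""
        text = repr(
            (self.experiment, self.group, self.n_subjects, self.seed,
             self.outlier_fraction, self.prior, self.link)
        )
        return hashlib.sha256(text.encode()).hexdigest()[:12]


def load_config(path: str | Path) -> RunConfig:
    """Parse a flat key-value configuration file into a :class:`RunConfig`."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a flat key-value mapping")
    top: dict = {}
    prior_kw: dict = {}
    link_kw: dict = {}
    for key, value in raw.items():
        if "." in str(key):
            block, _, name = str(key).partition(".")
            if block == "prior" and name in _PRIOR_KEYS:
                prior_kw[name] = value
            elif block == "link" and name in _LINK_KEYS:
                link_kw[name] = value
            else:
                raise ConfigError(f"{path}: unknown configuration key {key!r}")
        elif key in _TOP_KEYS:
            top[str(key)] = value
        else:
            raise ConfigError(f"{path}: unknown configuration key {key!r}")
    return RunConfig(
        prior=PriorConfig(**prior_kw), link=LinkParams(**link_kw), **top
    )
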