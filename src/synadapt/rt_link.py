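"""Log-linear mapping from surprisal to predicted reading times.

Reading times at a disambiguating region are assumed to increase linearly
with the surprisal of the structure the ambiguity resolves to, so the
predicted garden-path (ambiguity) effect is ``rt_slope`` milliseconds per
bit of surprisal.  The same parameter set carries the nuisance terms of the
generative reading-time model: per-subject baseline variability, word-length
sensitivity, a global task-adaptation speed-up in log stimulus order, and
trial noise.  Magnitudes are fixture conventions, not estimates from data.
"""
from __future__ import annotations

from dataclasses import dataclass

from .belief import ConfigError, surprisal_bits


@dataclass(frozen=True)
class LinkParams:
    """Surprisal-to-RT link and nuisance parameters of the RT model.

    All units are milliseconds unless noted.

    rt_intercept: baseline word RT.
    rt_slope: ms per bit of surprisal at the disambiguating region (> 0).
    unambig_offset: constant disambiguating-region cost in unambiguous
        conditions (default 0; the model prices only expectation violations).
    task_adapt_coef: ms per unit log stimulus order; non-positive, a global
        practice speed-up unrelated to syntactic expectations.
    noise_sd: trial noise SD.
    subj_intercept_sd: SD of per-subject baseline deviations.
    subj_length_slope_mean / subj_length_slope_sd: ms per character of word
        length, mean and between-subject SD.
    spillover_frac: fraction of the disambiguating-region cost carried onto
        the sentence-final word (generated but not modelled mechanistically).
    """

    rt_intercept: float = 350.0
    rt_slope: float = 20.0
    unambig_offset: float = 0.0
    task_adapt_coef: float = -20.0
    noise_sd: float = 60.0
    subj_intercept_sd: float = 50.0
    subj_length_slope_mean: float = 12.0
    subj_length_slope_sd: float = 4.0
    spillover_frac: float = 0.3

    def __post_init__(self) -> None:
        if not self.rt_slope > 0:
            raise ConfigError(f"rt_slope must be positive, got {self.rt_slope}")
        if self.task_adapt_coef > 0:
            raise ConfigError(
                f"task_adapt_coef must be <= 0, got {self.task_adapt_coef}"
            )
        for name in ("noise_sd", "subj_intercept_sd", "subj_length_slope_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")


def predicted_rt(surprisal: float, params: LinkParams) -> float:
    """Predicted disambiguating-region RT for a given surprisal (bits)."""
    if surprisal < 0:
        raise ValueError(f"surprisal must be non-negative, got {surprisal}")
    return params.rt_intercept + params.rt_slope * surprisal


def ambiguity_effect(p_structure: float, params: LinkParams) -> float:
    """Predicted ambiguous-minus-unambiguous RT difference (ms).

    ``p_structure`` is the comprehender's current predictive probability of
    the structure the ambiguity resolves to; a less-expected resolution
    yields a larger garden-path effect.
    """
    return params.rt_slope * surprisal_bits(p_structure) - params.unambig_offset
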