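"""Acquisition functions and next-candidate selection.

Everything here works in the internal maximization convention on
standardized posterior means/stds.  Expected Improvement integrates the
improvement over the incumbent under the Gaussian posterior; UCB is
mean + beta * std.  The hybrid schedule explores with UCB for the first
``hybrid_switch_iteration`` acquisition cycles and then exploits with EI
(boundary exclusive: the switch iteration itself already uses EI).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

ACQUISITION_KINDS = ("ei", "ucb", "hybrid")
TIE_RULES = ("lowest_index", "seeded_random")


@dataclass
class AcquisitionConfig:
    kind: str = "ei"
    beta: float = 2.0
    hybrid_switch_iteration: int = 100
    tie_rule: str = "lowest_index"

    def __post_init__(self) -> None:
        if self.kind not in ACQUISITION_KINDS:
            raise ValueError(f"kind must be one of {ACQUISITION_KINDS}")
        if not np.isfinite(self.beta) or self.beta < 0:
            raise ValueError("beta must be finite and >= 0")
        if self.hybrid_switch_iteration < 0:
            raise ValueError("hybrid_switch_iteration must be >= 0")
        if self.tie_rule not in TIE_RULES:
            raise ValueError(f"tie_rule must be one of {TIE_RULES}")


class CampaignComplete(Exception):
    """No unlabeled candidates remain."""


def expected_improvement(
    mean: np.ndarray, std: np.ndarray, best_observed: float
) -> np.ndarray:
    """EI = (mu - y*) Phi(z) + sigma phi(z), z = (mu - y*)/sigma.

    At sigma = 0 the improvement is certain: EI = max(mu - y*, 0).
    """
    mean = np.asarray(mean, float)
    std = np.asarray(std, float)
    if not (np.isfinite(mean).all() and np.isfinite(std).all() and np.isfinite(best_observed)):
        raise ValueError("non-finite acquisition inputs")
    if (std < 0).any():
        raise ValueError("negative posterior std")
    delta = mean - best_observed
    ei = np.maximum(delta, 0.0)
    # near-zero spread takes the deterministic sigma -> 0 limit, which also
    # keeps z = delta/sigma from overflowing
    pos = std > 1e-16
    if pos.any():
        z = delta[pos] / std[pos]
        ei = ei.copy()
        ei[pos] = delta[pos] * norm.cdf(z) + std[pos] * norm.pdf(z)
    return ei


def upper_confidence_bound(mean: np.ndarray, std: np.ndarray, beta: float) -> np.ndarray:
    """UCB = mu + beta * sigma, elementwise."""
    mean = np.asarray(mean, float)
    std = np.asarray(std, float)
    if not (np.isfinite(mean).all() and np.isfinite(std).all() and np.isfinite(beta)):
        raise ValueError("non-finite acquisition inputs")
    if (std < 0).any():
        raise ValueError("negative posterior std")
    return mean + beta * std


def active_acquisition(iteration: int, config: AcquisitionConfig) -> str:
    """Acquisition kind in force at a given (0-based) acquisition cycle."""
    if iteration < 0:
        raise ValueError("iteration must be >= 0")
    if config.kind != "hybrid":
        return config.kind
    return "ucb" if iteration < config.hybrid_switch_iteration else "ei"


def score_candidates(
    mean: np.ndarray,
    std: np.ndarray,
    best_observed: float,
    iteration: int,
    config: AcquisitionConfig,
) -> tuple[np.ndarray, str]:
    """Acquisition scores for the active kind at this cycle."""
    kind = active_acquisition(iteration, config)
    if kind == "ei":
        return expected_improvement(mean, std, best_observed), kind
    return upper_confidence_bound(mean, std, config.beta), kind


def select_next(
    scores: np.ndarray,
    unlabeled_mask: np.ndarray,
    tie_rule: str = "lowest_index",
    rng: int | np.random.Generator | None = None,
) -> int:
    """Argmax of scores over unlabeled candidates; exact ties by tie rule."""
    scores = np.asarray(scores, float)
    unlabeled_mask = np.asarray(unlabeled_mask, bool)
    if not unlabeled_mask.any():
        raise CampaignComplete("no unlabeled candidates remain")
    if tie_rule not in TIE_RULES:
        raise ValueError(f"tie_rule must be one of {TIE_RULES}")
    masked = np.where(unlabeled_mask, scores, -np.inf)
    best = masked.max()
    ties = np.flatnonzero(masked == best)
    if tie_rule == "lowest_index" or len(ties) == 1:
        return int(ties[0])
    gen = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return int(gen.choice(ties))
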