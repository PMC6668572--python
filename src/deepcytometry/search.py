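"""Coarse-to-fine random search over the two regularization hyperparameters.

Stage 1 samples twelve (L2 penalty multiplier, dropout keep probability)
pairs — L2 log-uniformly over [1e-4, 1] (its plausible values span four
decades; a linear-uniform mode is available), keep probability uniformly
over (0, 1].  Stage 2 contracts the box around the stage-1 optimum (one
decade of L2, +/-20 percentage points of keep probability, clipped to the
coarse bounds) and samples twelve more.  Every trial trains the full epoch
budget; the winner is the global argmin of final-epoch validation
cross-entropy over all 24 trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SearchSpace",
    "Trial",
    "sample_trial",
    "run_search",
    "trials_to_frame",
    "load_trials_csv",
]


@dataclass(frozen=True)
class SearchSpace:
    l2_bounds: tuple = (1e-4, 1.0)
    keep_prob_bounds: tuple = (0.0, 1.0)
    l2_log_uniform: bool = True
    n_trials_per_stage: int = 12
    stages: int = 2

    def __post_init__(self) -> None:
        lo, hi = self.l2_bounds
        if not 0 < lo < hi:
            raise ValueError("l2_bounds must satisfy 0 < low < high")
        klo, khi = self.keep_prob_bounds
        if not 0.0 <= klo < khi <= 1.0:
            raise ValueError("keep_prob_bounds must be within [0, 1]")
        if self.n_trials_per_stage < 1 or self.stages < 1:
            raise ValueError("need at least one trial and one stage")


@dataclass
class Trial:
    trial_number: int
    l2_multiplier: float
    keep_prob: float
    val_cross_entropy: float
    train_cross_entropy: float


def sample_trial(space: SearchSpace, seed) -> tuple[float, float]:
    """One seeded (L2 multiplier, keep probability) draw.

    ``seed`` may be an int or an existing numpy Generator.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    lo, hi = space.l2_bounds
    if space.l2_log_uniform:
        l2 = float(10.0 ** rng.uniform(math.log10(lo), math.log10(hi)))
    else:
        l2 = float(rng.uniform(lo, hi))
    klo, khi = space.keep_prob_bounds
    keep = float(rng.uniform(klo, khi))
    while keep <= 0.0:  # keep probability of exactly 0 is invalid
        keep = float(rng.uniform(klo, khi))
    return l2, keep


def _fine_space(space: SearchSpace, best_l2: float,
                best_keep: float) -> SearchSpace:
    """Contract to one decade of L2 and +/-0.2 keep probability around the
    coarse optimum, clipped to the coarse bounds."""
    lo, hi = space.l2_bounds
    l2_lo = max(lo, best_l2 / math.sqrt(10.0))
    l2_hi = min(hi, best_l2 * math.sqrt(10.0))
    klo, khi = space.keep_prob_bounds
    k_lo = max(klo, best_keep - 0.2)
    k_hi = min(khi, best_keep + 0.2)
    return SearchSpace(
        l2_bounds=(l2_lo, l2_hi), keep_prob_bounds=(k_lo, k_hi),
        l2_log_uniform=space.l2_log_uniform,
        n_trials_per_stage=space.n_trials_per_stage, stages=space.stages)


def run_search(objective, space: SearchSpace | None = None, seed: int = 0):
    """Run the staged random search.

    ``objective(l2_multiplier, keep_prob)`` must return
    (final validation cross-entropy, final train cross-entropy); a trial
    that raises or returns a non-finite validation loss is recorded with
    infinite loss and the search continues.

    Returns (trials, best).
    """
    space = space or SearchSpace()
    rng = np.random.default_rng(seed)
    trials: list[Trial] = []
    stage_space = space
    for stage in range(space.stages):
        for _ in range(space.n_trials_per_stage):
            l2, keep = sample_trial(stage_space, rng)
            try:
                val_ce, train_ce = objective(l2, keep)
            except (FloatingPointError, RuntimeError, ValueError):
                val_ce, train_ce = math.inf, math.inf
            if not math.isfinite(val_ce):
                val_ce = math.inf
            trials.append(Trial(len(trials) + 1, l2, keep,
                                float(val_ce), float(train_ce)))
        best = min(trials, key=lambda t: t.val_cross_entropy)
        if stage < space.stages - 1:
            stage_space = _fine_space(space, best.l2_multiplier, best.keep_prob)
    best = min(trials, key=lambda t: t.val_cross_entropy)
    return trials, best


def trials_to_frame(trials) -> pd.DataFrame:
    return pd.DataFrame([{
        "trial_number": t.trial_number,
        "l2_multiplier": t.l2_multiplier,
        "keep_prob": t.keep_prob,
        "val_cross_entropy": t.val_cross_entropy,
        "train_cross_entropy": t.train_cross_entropy,
    } for t in trials])


def load_trials_csv(path) -> list[Trial]:
    """Parse a trials table CSV.

    Columns ``trial_number``, ``l2_multiplier``, ``keep_prob`` are required;
    the loss columns are optional (NaN when absent).  ``keep_prob`` accepts
    either a fraction or a percentage string such as ``"55.14%"``.
    """
    df = pd.read_csv(path)
    trials = []
    for _, row in df.iterrows():
        keep = row["keep_prob"]
        if isinstance(keep, str) and keep.strip().endswith("%"):
            keep = float(keep.strip().rstrip("%")) / 100.0
        else:
            keep = float(keep)
        trials.append(Trial(
            trial_number=int(row["trial_number"]),
            l2_multiplier=float(row["l2_multiplier"]),
            keep_prob=keep,
            val_cross_entropy=float(row.get("val_cross_entropy", math.nan)),
            train_cross_entropy=float(row.get("train_cross_entropy", math.nan)),
        ))
    return trials
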