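"""Hyperparameter selection for the regularization weights.

The two penalty weights (on free moment entries and on network weights)
are chosen by minimizing the average validation loss over an
expanding-window schedule: with K time blocks and Nt stages, stage r trains
on the first r*K/Nt blocks of the training trajectories and evaluates the
rollout misfit on the same block range of the validation trajectories; the
objective is the mean of the per-stage validation losses.

The search is seeded random sampling over log-uniform ranges — sequential
model-based alternatives plug in through the same interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import TrajectoryDataset
from .training import LossConfig, PDEModel, data_loss, train

__all__ = [
    "SearchSpace",
    "ValidationSchedule",
    "expanding_validation_loss",
    "tune",
]


@dataclass
class SearchSpace:
    lam_moment_range: tuple = (1e-8, 1e-2)
    lam_symnet_range: tuple = (1e-8, 1e-2)
    n_trials: int = 25
    seed: int = 0

    def __post_init__(self):
        for lo, hi in (self.lam_moment_range, self.lam_symnet_range):
            if lo <= 0 or hi <= lo:
                raise ValueError("ranges must be positive and increasing")
        if self.n_trials < 1:
            raise ValueError("need at least one trial")

    def sample(self, rng: np.random.Generator) -> tuple[float, float]:
        lm = np.exp(rng.uniform(*np.log(self.lam_moment_range)))
        ls = np.exp(rng.uniform(*np.log(self.lam_symnet_range)))
        return float(lm), float(ls)


@dataclass
class ValidationSchedule:
    total_blocks: int  # K
    n_stages: int  # Nt

    def __post_init__(self):
        if self.total_blocks % self.n_stages:
            raise ValueError("n_stages must divide the number of blocks")

    @property
    def stage_blocks(self) -> list:
        step = self.total_blocks // self.n_stages
        return [step * (r + 1) for r in range(self.n_stages)]


def expanding_validation_loss(
    lam_moment: float,
    lam_symnet: float,
    train_set: TrajectoryDataset,
    valid_set: TrajectoryDataset,
    schedule: ValidationSchedule,
    model_factory,
    cfg_base: LossConfig,
    train_kwargs: dict | None = None,
) -> float:
    """Mean validation loss over the expanding-window stages.

    ``model_factory()`` builds a fresh model per call; training warm-starts
    stage to stage inside :func:`fracpde.training.train`.  Returns the
    +inf sentinel if any stage aborts.
    """
    if valid_set.n_init == 0:
        raise ValueError("empty validation set")
    cfg = LossConfig(
        lam_moment,
        lam_symnet,
        cfg_base.huber_s,
        cfg_base.n_blocks,
        cfg_base.dt,
        cfg_base.teacher_forcing,
    )
    model = model_factory()
    try:
        trained = train(
            model,
            train_set,
            cfg,
            n_stages=schedule.n_stages,
            total_blocks=schedule.total_blocks,
            valid_set=valid_set,
            **(train_kwargs or {}),
        )
    except RuntimeError:
        return float("inf")
    stage_losses = [
        h["valid_loss"] for h in trained.history if "valid_loss" in h
    ]
    if not stage_losses:
        raise ValueError("training produced no validation losses")
    return float(np.mean(stage_losses))


@dataclass
class TrialLog:
    trials: list = field(default_factory=list)

    def best(self) -> dict:
        finite = [t for t in self.trials if np.isfinite(t["loss"])]
        if not finite:
            raise RuntimeError("all trials failed (non-finite objective)")
        return min(finite, key=lambda t: t["loss"])


def tune(
    space: SearchSpace,
    objective=None,
    train_set=None,
    valid_set=None,
    schedule=None,
    model_factory=None,
    cfg_base=None,
    train_kwargs=None,
) -> tuple[float, float, TrialLog]:
    """Random search over (lam_moment, lam_symnet); deterministic in seed.

    Either pass a custom ``objective(lam_moment, lam_symnet) -> loss`` or
    the dataset pieces for :func:`expanding_validation_loss`.
    """
    rng = np.random.default_rng(space.seed)
    if objective is None:
        def objective(lm, ls):
            return expanding_validation_loss(
                lm, ls, train_set, valid_set, schedule, model_factory,
                cfg_base, train_kwargs,
            )

    log = TrialLog()
    for i in range(space.n_trials):
        lm, ls = space.sample(rng)
        loss = objective(lm, ls)
        log.trials.append(
            {"trial": i, "lam_moment": lm, "lam_symnet": ls, "loss": loss}
        )
    best = log.best()
    return best["lam_moment"], best["lam_symnet"], log
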