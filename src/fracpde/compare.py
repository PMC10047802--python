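"""Post-hoc parsimony test for a discovered PDE pair.

Model 2 is Model 1 with its weakest interaction term removed (smallest
data-weighted L2 norm) and its coefficients refitted.  Both models are then
simulated forward from the same initial state, and at every observation
time the paired (u, v) prediction residuals over the spatial grid are
compared with a two-sample bivariate Kolmogorov-Smirnov test
(Fasano-Franceschini orthant statistic, permutation null).  Per-time
p-values are adjusted for multiplicity by the Bonferroni, Holm and
Benjamini-Hochberg procedures; if the reduced model were equivalent, no
more than the nominal 5% of time points should be rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .grids import discrete_l2_sq
from .sparsify import SparseModel, SparseTerm, channel_env, evaluate_term

logger = logging.getLogger(__name__)

__all__ = [
    "ResidualSeries",
    "TestReport",
    "drop_smallest_term",
    "ks_two_sample",
    "adjust_pvalues",
    "posthoc_compare",
]

_ADJ_METHODS = {"bonferroni": "bonferroni", "holm": "holm", "bh": "fdr_bh"}


@dataclass
class ResidualSeries:
    """Per-time paired residual samples: list of (n_points, 2) arrays."""

    samples: list
    times: np.ndarray

    @property
    def n(self) -> int:
        return len(self.samples)


@dataclass
class TestReport:
    times: np.ndarray
    p_raw: np.ndarray
    p_adjusted: dict
    rejections: dict
    alpha: float = 0.05
    flags: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            f"{m}: {self.rejections[m]}/{len(self.times)} time points rejected"
            for m in self.p_adjusted
        ]
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        d = {"time": self.times, "p_raw": self.p_raw}
        for m, p in self.p_adjusted.items():
            d[f"p_{m}"] = p
            d[f"reject_{m}"] = p < self.alpha
        return pd.DataFrame(d)


def drop_smallest_term(model: SparseModel, dataset) -> SparseModel:
    """Remove the interaction term with the smallest data-weighted L2 norm.

    Diffusion terms are never candidates for removal.  Ties go to the
    later-listed term (logged).
    """
    cands = [
        (i, t) for i, t in enumerate(model.terms) if t.kind != "diffusion"
    ]
    if len(cands) < 1 or len(model.terms) < 2:
        raise ValueError("need at least two terms, one of them removable")
    env = channel_env(
        dataset.u, dataset.v, dataset.grid, alpha=model.alpha
    )
    norms = []
    for i, t in cands:
        col = np.broadcast_to(
            np.asarray(evaluate_term(t, env)), env["u"].shape
        )
        norms.append(
            np.sqrt(discrete_l2_sq(t.coeff * col, dataset.grid))
        )
    norms = np.asarray(norms)
    smallest = norms.min()
    ties = np.flatnonzero(np.isclose(norms, smallest))
    if len(ties) > 1:
        logger.info("tie in term norms; removing the later-listed term")
    drop_idx = cands[ties[-1]][0]
    kept = [t for i, t in enumerate(model.terms) if i != drop_idx]
    return SparseModel(kept, model.alpha, model.field, stage="PHrsmPDE")


def _ff_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Fasano-Franceschini two-sample statistic for bivariate samples.

    For each data point of either sample taken as origin, compare the two
    empirical fractions in the four open quadrants; D is the mean of the two
    per-sample maxima.
    """
    def quadrant_fracs(origins, pts):
        gx = pts[None, :, 0] > origins[:, None, 0]
        gy = pts[None, :, 1] > origins[:, None, 1]
        return np.stack(
            [
                (gx & gy).mean(axis=1),
                (gx & ~gy).mean(axis=1),
                (~gx & gy).mean(axis=1),
                (~gx & ~gy).mean(axis=1),
            ],
            axis=1,
        )

    def max_diff(origins):
        return np.max(
            np.abs(quadrant_fracs(origins, a) - quadrant_fracs(origins, b))
        )

    return 0.5 * (max_diff(a) + max_diff(b))


def ks_two_sample(
    a: np.ndarray,
    b: np.ndarray,
    n_permutations: int = 999,
    seed: int = 0,
    max_points: int = 100,
):
    """Two-sample bivariate K-S test by permutation.

    ``a`` and ``b`` are (n, 2) arrays of paired residuals.  Large samples
    are subsampled (deterministically given ``seed``) to ``max_points``
    per group before computing the orthant statistic.  Returns (D, p).
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    if min(len(a), len(b)) < 10:
        logger.warning("bivariate K-S with fewer than 10 points per sample")
    rng = np.random.default_rng(seed)
    if len(a) > max_points:
        a = a[rng.choice(len(a), max_points, replace=False)]
    if len(b) > max_points:
        b = b[rng.choice(len(b), max_points, replace=False)]
    d_obs = _ff_statistic(a, b)
    if np.array_equal(a, b):
        return d_obs, 1.0
    pooled = np.vstack([a, b])
    na = len(a)
    count = 1
    for _ in range(n_permutations):
        perm = rng.permutation(len(pooled))
        d = _ff_statistic(pooled[perm[:na]], pooled[perm[na:]])
        if d >= d_obs - 1e-12:
            count += 1
    return d_obs, count / (n_permutations + 1)


def adjust_pvalues(p: np.ndarray, method: str, alpha: float = 0.05):
    """Bonferroni / Holm / Benjamini-Hochberg adjusted p-values and
    rejections at the given level."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    key = method.lower().replace("-", "")
    if key not in _ADJ_METHODS:
        raise ValueError(f"unknown adjustment method {method}")
    reject, p_adj, *_ = multipletests(p, alpha=alpha, method=_ADJ_METHODS[key])
    return p_adj, reject


def residual_series(pred, truth, times_idx, times) -> ResidualSeries:
    """Pair the u- and v-residuals over the grid at each selected time."""
    u_p, v_p = pred
    u_t, v_t = truth
    samples = []
    for k in times_idx:
        eu = (u_p[k] - u_t[k]).ravel()
        ev = (v_p[k] - v_t[k]).ravel()
        samples.append(np.column_stack([eu, ev]))
    return ResidualSeries(samples, np.asarray(times))


def posthoc_compare(
    res1: ResidualSeries,
    res2: ResidualSeries,
    alpha: float = 0.05,
    n_permutations: int = 999,
    seed: int = 0,
    max_points: int = 100,
) -> TestReport:
    """Per-time bivariate K-S comparison of two residual series with
    Bonferroni/Holm/B-H adjustment."""
    if res1.n != res2.n:
        raise ValueError("residual series must share the time grid")
    p_raw = np.empty(res1.n)
    for i, (a, b) in enumerate(zip(res1.samples, res2.samples)):
        _, p_raw[i] = ks_two_sample(
            a, b, n_permutations, seed=seed + 7919 * i, max_points=max_points
        )
    p_adjusted, rejections = {}, {}
    for m in ("bonferroni", "holm", "bh"):
        p_adj, rej = adjust_pvalues(p_raw, m, alpha)
        p_adjusted[m] = p_adj
        rejections[m] = int(rej.sum())
    return TestReport(res1.times, p_raw, p_adjusted, rejections, alpha)
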