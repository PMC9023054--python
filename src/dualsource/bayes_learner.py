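"""Grid-based Bayesian learner for reward probabilities in a volatile world.

The learner maintains a joint posterior over three latent quantities on
a fixed grid: the current reward probability ``p``, the volatility ``v``
(how fast ``p`` can move between trials) and a volatility-trend
parameter ``k`` (how fast ``v`` itself can move).  Updates are
Markovian -- one transition plus one Bernoulli likelihood per trial --
so nothing beyond the current joint posterior needs to be stored.

Generative assumptions (one trial step):

* log-volatility performs a Gaussian random walk:
  ``log v' ~ Normal(log v, k**2)``;
* the reward probability diffuses with a beta kernel centred on its
  previous value, with spread set by the (new) volatility:
  ``p' ~ Beta(mu=p, concentration=1/v')``, so
  ``Var[p'] ~= p (1 - p) v'`` for small ``v'``;
* the outcome is Bernoulli in ``p'``.

The prior is uniform over the grid, which makes predictions symmetric
under relabelling of the two options.  All grid axes are configurable;
``v`` and ``k`` are log-spaced.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .schedules import TrialSequence


@dataclass(frozen=True)
class GridSpec:
    """Grid resolutions and ranges for the three latent axes."""

    n_p: int = 50
    n_v: int = 30
    n_k: int = 30
    v_range: tuple[float, float] = (5e-4, 0.25)
    k_range: tuple[float, float] = (5e-2, 5.0)

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        # cell midpoints for p so the grid never touches 0 or 1
        p = (np.arange(self.n_p) + 0.5) / self.n_p
        v = np.geomspace(*self.v_range, self.n_v)
        k = np.geomspace(*self.k_range, self.n_k)
        return p, v, k


@functools.lru_cache(maxsize=8)
def _kernels(spec: GridSpec):
    """Transition matrices for a grid spec (cached; specs are immutable).

    Kernels are discretised by integrating the transition density over
    destination cells (CDF differences) and, for the probability axis,
    averaging over source positions within each cell (Gauss-Legendre),
    so narrow kernels keep exact cell masses.
    """
    p, v_axis, k_axis = spec.axes()
    # volatility transition, one (n_v x n_v) column-stochastic matrix per k:
    # T_v[k][v_new, v_old] = P(v_new cell | v_old, k)
    logv = np.log(v_axis)
    if len(v_axis) > 1:
        log_edges = np.concatenate((
            [-np.inf], 0.5 * (logv[1:] + logv[:-1]), [np.inf]))
    else:
        log_edges = np.array([-np.inf, np.inf])
    tv = np.empty((len(k_axis), len(v_axis), len(v_axis)))
    for i, k in enumerate(k_axis):
        cdf = stats.norm.cdf((log_edges[:, None] - logv[None, :]) / k)
        m = np.diff(cdf, axis=0)
        tv[i] = m / m.sum(axis=0, keepdims=True)
    # probability transition, one (n_p x n_p) matrix per v:
    # T_p[v][p_new, p_old] = beta-kernel mass of the p_new cell given mean
    # p_old and concentration 1/v
    n_p = len(p)
    p_edges = np.arange(n_p + 1) / n_p
    gl_x, gl_w = np.polynomial.legendre.leggauss(4)
    gl_w = gl_w / gl_w.sum()
    src = p[None, :] + (gl_x[:, None] * 0.5 / n_p)   # (4, n_p) source points
    tp = np.empty((len(v_axis), n_p, n_p))
    for j, v in enumerate(v_axis):
        c = 1.0 / v
        m = np.zeros((n_p, n_p))
        for x, w in zip(src, gl_w):
            a = x * c
            b = (1.0 - x) * c
            cdf = stats.beta.cdf(p_edges[:, None], a[None, :], b[None, :])
            m += w * np.diff(cdf, axis=0)
        m = np.clip(m, 0.0, None)
        tp[j] = m / m.sum(axis=0, keepdims=True)
    tpT = np.ascontiguousarray(tp.swapaxes(1, 2))  # (v, p_old, p_new)
    return tv, tp, tpT


class BayesGrid:
    """Joint posterior over (k, v, p) with precomputed transition kernels."""

    def __init__(self, spec: GridSpec | None = None):
        self.spec = spec or GridSpec()
        self.p, self.v, self.k = self.spec.axes()
        self._tv, self._tp, self._tpT = _kernels(self.spec)
        self.reset()

    def reset(self) -> None:
        """Uniform prior over the whole grid."""
        shape = (len(self.k), len(self.v), len(self.p))
        self.post = np.full(shape, 1.0 / np.prod(shape))

    # -- queries --------------------------------------------------------
    @property
    def p_mean(self) -> float:
        return float(np.einsum("kvp,p->", self.post, self.p))

    @property
    def v_mean(self) -> float:
        return float(np.einsum("kvp,v->", self.post, self.v))

    def check_normalised(self) -> None:
        if abs(self.post.sum() - 1.0) > 1e-9:
            raise RuntimeError("posterior not normalised")

    # -- filtering ------------------------------------------------------
    def predict(self) -> None:
        """Apply the one-trial transition (v drift then p diffusion)."""
        # batched matmuls: v-drift per k, then p-diffusion per v
        post = np.matmul(self._tv, self.post)            # (k,w,v)@(k,v,p)
        post = np.matmul(post.swapaxes(0, 1), self._tpT)  # (v,k,p)@(v,p,q)
        self.post = (post / post.sum()).swapaxes(0, 1)

    def observe(self, outcome: int) -> None:
        """Multiply by the Bernoulli likelihood and renormalise."""
        if outcome not in (0, 1):
            raise ValueError("outcome must be binary")
        if abs(self.post.sum() - 1.0) > 1e-6:
            raise RuntimeError("step_posterior requires a normalised grid")
        lik = self.p if outcome == 1 else 1.0 - self.p
        self.post = self.post * lik[None, None, :]
        self.post /= self.post.sum()


def step_posterior(grid: BayesGrid, outcome: int) -> BayesGrid:
    """One filter step: transition, then condition on the outcome."""
    grid.predict()
    grid.observe(outcome)
    return grid


@dataclass
class OptimalTrajectory:
    """Forward-filtered predictions: ``p_hat(t)`` is computed *before*
    trial ``t``'s outcome is observed, so ``p_hat(1)`` is the prior mean."""

    p_hat: np.ndarray
    v_hat: np.ndarray


def run_bayes_learner(outcomes: np.ndarray,
                      spec: GridSpec | None = None) -> OptimalTrajectory:
    """Filter a binary outcome sequence, returning per-trial predictions."""
    outcomes = np.asarray(outcomes, dtype=int)
    if outcomes.size == 0:
        raise ValueError("outcome sequence is empty")
    grid = BayesGrid(spec)
    n = len(outcomes)
    p_hat = np.empty(n)
    v_hat = np.empty(n)
    for t in range(n):
        if t > 0:
            grid.predict()
        p_hat[t] = grid.p_mean
        v_hat[t] = grid.v_mean
        grid.observe(int(outcomes[t]))
    return OptimalTrajectory(p_hat, v_hat)


def optimal_prediction_series(trials: TrialSequence, source: str,
                              spec: GridSpec | None = None) -> OptimalTrajectory:
    """Optimal per-trial prediction for the primary-congruent option.

    ``source="primary"`` filters the reward outcomes directly.
    ``source="secondary"`` filters the advice-correctness sequence and
    converts each prediction into a primary-congruent choice probability
    through the advice weighting ``|advice(t) - p_hat(t)|``.
    """
    if source == "primary":
        return run_bayes_learner(trials.r, spec)
    if source == "secondary":
        traj = run_bayes_learner(trials.secondary_correct, spec)
        converted = np.abs(trials.advice - traj.p_hat)
        return OptimalTrajectory(converted, traj.v_hat)
    raise ValueError("source must be 'primary' or 'secondary'")
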