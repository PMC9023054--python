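"""Random-effects Bayesian model selection over a family of model variants.

Given a subjects x models matrix of (approximate) log model evidences,
the group-level scheme treats the model identity of each subject as a
draw from an unknown multinomial with a Dirichlet prior, and infers the
Dirichlet posterior by a fixed-point variational iteration.  The
*exceedance probability* of a model is the posterior probability that
it is the most frequent model in the population, estimated by Monte
Carlo sampling from the fitted Dirichlet.

The default model family is the 2 x 2 x 2 factorial of
{learning rates split by information source} x {split by phase
volatility} x {source weight free vs fixed}; any ordered list of
``ModelVariant`` objects can be supplied instead.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.special import digamma, logsumexp

from .fitting import ModelVariant


def default_model_space() -> list[ModelVariant]:
    """The eight-variant factorial family; the full model is last."""
    space = [ModelVariant(s, v, z)
             for s, v, z in itertools.product([False, True], repeat=3)]
    assert space[-1] == ModelVariant(True, True, True)
    return space


@dataclass
class BMSResult:
    """Group-level posterior over the model family."""

    alpha: np.ndarray                # Dirichlet parameters
    expected_frequencies: np.ndarray
    exceedance: np.ndarray
    model_names: list[str]
    n_subjects: int
    n_iterations: int

    @property
    def n_models(self) -> int:
        return len(self.alpha)

    def best(self) -> int:
        return int(np.argmax(self.exceedance))


def exceedance_from_dirichlet(alpha: np.ndarray, n_samples: int = 100_000,
                              seed: int = 0) -> np.ndarray:
    """Monte-Carlo P(frequency_k is the largest) under Dirichlet(alpha)."""
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=n_samples)
    winners = np.argmax(draws, axis=1)
    return np.bincount(winners, minlength=len(alpha)) / n_samples


def bms(log_evidence: np.ndarray, model_names: list[str] | None = None,
        tol: float = 1e-6, max_iter: int = 10_000,
        n_samples: int = 100_000, seed: int = 0) -> BMSResult:
    """Variational random-effects model selection.

    Parameters
    ----------
    log_evidence
        Array of shape (n_subjects, n_models); must be finite with at
        least two subjects and two models.
    tol, max_iter
        Convergence tolerance (max absolute change of the Dirichlet
        parameters) and iteration cap of the fixed-point scheme.
    n_samples, seed
        Monte-Carlo settings for the exceedance probabilities.
    """
    L = np.asarray(log_evidence, dtype=float)
    if L.ndim != 2 or L.shape[0] < 2 or L.shape[1] < 2:
        raise ValueError("log_evidence must be (>=2 subjects) x (>=2 models)")
    if not np.all(np.isfinite(L)):
        raise ValueError("log evidences must be finite")
    n_subjects, n_models = L.shape
    if model_names is None:
        model_names = [f"model_{k}" for k in range(n_models)]

    alpha0 = np.ones(n_models)
    alpha = alpha0.copy()
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        log_u = L + digamma(alpha) - digamma(alpha.sum())
        g = np.exp(log_u - logsumexp(log_u, axis=1, keepdims=True))
        alpha_new = alpha0 + g.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new

    freq = alpha / alpha.sum()
    xp = exceedance_from_dirichlet(alpha, n_samples=n_samples, seed=seed)
    return BMSResult(alpha=alpha, expected_frequencies=freq, exceedance=xp,
                     model_names=list(model_names), n_subjects=n_subjects,
                     n_iterations=n_iter)
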