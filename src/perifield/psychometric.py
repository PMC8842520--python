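"""Weibull psychometric function algebra for 2AFC contrast tasks.

The psychometric function maps stimulus contrast ``x`` (Michelson units,
linear scale in [0, 1]) to probability correct::

    psi(x) = gamma + (1 - gamma - lam) * (1 - exp(-(x / m) ** beta))

with scale (threshold) parameter ``m``, slope ``beta``, guess rate ``gamma``
(0.5 for a two-alternative forced choice) and lapse rate ``lam``.  The same
parameterization is used both to simulate observers and to estimate
thresholds from trial data, so the two sides of the package agree exactly
about what "threshold" means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["WeibullPF", "pf_eval", "pf_quantile", "pf_loglik"]


@dataclass(frozen=True)
class WeibullPF:
    """Weibull psychometric function for a 2AFC contrast task.

    Parameters
    ----------
    m : float
        Scale parameter in Michelson-contrast units, in (0, 1].
    beta : float
        Slope (steepness), dimensionless, > 0.
    gamma : float
        Guess rate (lower asymptote), in [0, 1).  0.5 for 2AFC.
    lam : float
        Lapse rate; the upper asymptote is ``1 - lam``.
    """

    m: float
    beta: float = 3.5
    gamma: float = 0.5
    lam: float = 0.02

    def __post_init__(self) -> None:
        if not np.isfinite(self.m) or self.m <= 0:
            raise ValueError(f"scale parameter m must be positive, got {self.m}")
        if not self.beta > 0:
            raise ValueError(f"slope beta must be positive, got {self.beta}")
        if not (0 <= self.gamma < 1) or not (0 <= self.lam < 1):
            raise ValueError("gamma and lam must lie in [0, 1)")
        if self.gamma + self.lam >= 1:
            raise ValueError(
                f"gamma + lam must be < 1, got {self.gamma} + {self.lam}"
            )

    @property
    def shape(self) -> tuple[float, float, float]:
        """The fixed shape triple ``(beta, gamma, lam)``."""
        return (self.beta, self.gamma, self.lam)


def pf_eval(pf: WeibullPF, x):
    """Probability correct at contrast ``x`` (scalar or array).

    Continuous and non-decreasing in ``x``; equals ``gamma`` at x = 0 and
    approaches ``1 - lam`` for large contrast.

    Raises
    ------
    ValueError
        If any contrast is negative.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("contrast must be non-negative")
    p = pf.gamma + (1.0 - pf.gamma - pf.lam) * (
        1.0 - np.exp(-((x / pf.m) ** pf.beta))
    )
    return p if p.ndim else float(p)


def pf_quantile(pf: WeibullPF, p: float) -> float:
    """Contrast at which the function reaches probability correct ``p``.

    Exact inverse of :func:`pf_eval`; ``p`` must lie strictly between the
    asymptotes ``gamma`` and ``1 - lam``.
    """
    if not (pf.gamma < p < 1.0 - pf.lam):
        raise ValueError(
            f"p={p} outside the open range ({pf.gamma}, {1.0 - pf.lam})"
        )
    frac = (p - pf.gamma) / (1.0 - pf.gamma - pf.lam)
    return float(pf.m * (-np.log1p(-frac)) ** (1.0 / pf.beta))


def _as_trial_arrays(trials):
    """Coerce trials to (contrast, correct) float/bool arrays.

    Accepts a sequence of ``(contrast, correct)`` pairs or a 2-tuple of
    array-likes ``(contrasts, corrects)``.
    """
    if isinstance(trials, tuple) and len(trials) == 2 and np.ndim(trials[0]) >= 1:
        x = np.asarray(trials[0], dtype=float)
        c = np.asarray(trials[1], dtype=float)
    else:
        arr = np.asarray(list(trials), dtype=float)
        if arr.size == 0:
            raise ValueError("trial list must be non-empty")
        x, c = arr[:, 0], arr[:, 1]
    if x.size == 0:
        raise ValueError("trial list must be non-empty")
    if np.any((x < 0) | (x > 1)):
        raise ValueError("trial contrasts must lie in [0, 1]")
    return x, c


def pf_loglik(m_candidate: float, fixed_shape, trials) -> float:
    """Bernoulli log-likelihood of 2AFC outcomes under a candidate scale.

    Parameters
    ----------
    m_candidate : float
        Candidate scale parameter (> 0).
    fixed_shape : tuple
        ``(beta, gamma, lam)`` held fixed during estimation.
    trials : sequence of (contrast, correct) or (contrasts, corrects)
        The observed trials; correctness coerced to {0, 1}.
    """
    beta, gamma, lam = fixed_shape
    pf = WeibullPF(m=m_candidate, beta=beta, gamma=gamma, lam=lam)
    x, c = _as_trial_arrays(trials)
    p = np.clip(pf_eval(pf, x), 1e-12, 1 - 1e-12)
    return float(np.sum(c * np.log(p) + (1.0 - c) * np.log1p(-p)))
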