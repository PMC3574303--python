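"""Weibull psychometric function for the 2AFC contrast-detection task.

Shared by the simulated observer (:mod:`streakmvpa.synthetic_data`) and the
QUEST likelihood (:mod:`streakmvpa.psychophysics`).
"""

from __future__ import annotations

import numpy as np

__all__ = ["weibull_2afc", "proportion_correct_at_threshold"]


def weibull_2afc(
    x: np.ndarray | float,
    threshold: np.ndarray | float,
    beta: float = 3.5,
    gamma: float = 0.5,
    delta: float = 0.01,
) -> np.ndarray | float:
    """Probability of a correct 2AFC response at log10 contrast ``x``.

    Uses the Watson–Pelli parameterization on log10 contrast::

        psi(x) = gamma + (1 - gamma - delta) * (1 - exp(-10 ** (beta * (x - T))))

    where ``T`` is the log10 threshold, ``beta`` the slope, ``gamma`` the
    guess rate (0.5 for 2AFC) and ``delta`` the lapse rate.  At ``x == T``
    the inner Weibull equals ``1 - exp(-1)``, so with the default
    ``gamma=0.5, delta=0.01`` the criterion proportion correct at threshold
    is ``0.5 + 0.49 * (1 - e**-1) = 0.80973...``.
    """
    x = np.asarray(x, dtype=float)
    threshold = np.asarray(threshold, dtype=float)
    p = gamma + (1.0 - gamma - delta) * (1.0 - np.exp(-(10.0 ** (beta * (x - threshold)))))
    if p.ndim == 0:
        return float(p)
    return p


def proportion_correct_at_threshold(gamma: float = 0.5, delta: float = 0.01) -> float:
    """Closed-form psi(T): the proportion correct that defines "threshold"."""
    return gamma + (1.0 - gamma - delta) * (1.0 - float(np.exp(-1.0)))
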