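"""Kimura 1980 (K80) nucleotide substitution model.

Equal base frequencies (1/4 each) and distinct transition/transversion rates.
The model is parameterized by the expected transition/transversion *ratio*
R = alpha / (2 beta) (default 2), i.e. kappa = alpha/beta = 2R, and is
normalized so that branch lengths are in expected substitutions per site
(alpha + 2 beta = 1).
"""
from __future__ import annotations

import numpy as np

__all__ = ["K80Model", "BASES", "default_gamma_grid"]

BASES = "ACGT"
# transitions: A<->G (purines), C<->T (pyrimidines)
_TRANSITION = np.zeros((4, 4), dtype=bool)
for _a, _b in ((0, 2), (2, 0), (1, 3), (3, 1)):
    _TRANSITION[_a, _b] = True
_TRANSVERSION = ~_TRANSITION & ~np.eye(4, dtype=bool)


class K80Model:
    """K80 model with closed-form transition probabilities."""

    def __init__(self, titv: float = 2.0):
        if titv <= 0:
            raise ValueError("transition/transversion ratio must be positive")
        self.titv = float(titv)
        kappa = 2.0 * self.titv
        self.alpha = kappa / (kappa + 2.0)  # transition rate
        self.beta = 1.0 / (kappa + 2.0)     # each transversion rate
        self.stationary = np.full(4, 0.25)

    @property
    def key(self) -> tuple:
        return ("K80", self.titv)

    @property
    def rate_matrix(self) -> np.ndarray:
        q = np.where(_TRANSITION, self.alpha, 0.0) + np.where(_TRANSVERSION, self.beta, 0.0)
        np.fill_diagonal(q, -(self.alpha + 2.0 * self.beta))
        return q

    def transition_matrix(self, t: float) -> np.ndarray:
        """4x4 matrix of P(b at time t | a at time 0); rows sum to one."""
        if t < 0:
            raise ValueError(f"branch length must be non-negative, got {t}")
        e2 = np.exp(-4.0 * self.beta * t)
        e1 = np.exp(-2.0 * (self.alpha + self.beta) * t)
        p_same = 0.25 + 0.25 * e2 + 0.5 * e1
        p_ti = 0.25 + 0.25 * e2 - 0.5 * e1
        p_tv = 0.25 - 0.25 * e2
        p = np.where(_TRANSITION, p_ti, p_tv)
        np.fill_diagonal(p, p_same)
        return p

    def expected_difference_fractions(self, t: float) -> tuple[float, float]:
        """(P(transition difference), P(transversion difference)) between the
        two ends of a path of total length t."""
        p = self.transition_matrix(t)
        return float(p[0, 2]), float(2.0 * p[0, 1])

    def __repr__(self) -> str:
        return f"K80Model(titv={self.titv})"


def default_gamma_grid() -> tuple[float, ...]:
    """Candidate inheritance probabilities {0.05, 0.10, ..., 0.50}."""
    return tuple(round(0.05 * i, 2) for i in range(1, 11))
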