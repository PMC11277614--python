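"""Success-probability kernels for the four nested latent trait models.

All four models give the probability that a person answers a binary item
correctly:

* LLTM: logistic(θ − Σ_k q_jk η_k) — Rasch-type, difficulty decomposed over
  item features.
* Constrained 2PL: logistic(α_j (θ − Σ_k q_jk η_k)) — adds a per-item slope.
* MLTM-D: Π_m logistic(θ_m − b_jm)^{C_jm} — non-compensatory product over
  components; a component absent from the item (C_jm = 0) contributes
  nothing.
* GMLTM-D: c_j + (1 − c_j) Π_m logistic(α_jm (θ_m − b_jm))^{C_jm} — adds
  group-shared slopes and a guessing floor in the three-parameter style.

Products are accumulated in log space; the logistic uses the log-sum-exp-safe
branch so arguments of magnitude ~700+ do not overflow.
"""

from __future__ import annotations

import numpy as np

from .structures import ComposedItemParameters

__all__ = [
    "log_logistic",
    "prob_lltm",
    "prob_constrained_2pl",
    "prob_mltmd",
    "prob_gmltmd",
]


def log_logistic(z):
    """log σ(z) = −log(1 + e^{−z}), stable for any finite z."""
    return -np.logaddexp(0.0, -np.asarray(z, dtype=float))


_SMALLEST = np.nextafter(0.0, 1.0)  # probabilities stay strictly positive


def _exp_pos(logp: float) -> float:
    """exp(logp) floored at the smallest positive float."""
    return max(float(np.exp(logp)), _SMALLEST)


def prob_lltm(theta_i: float, q_row, eta) -> float:
    """LLTM success probability: logistic(θ − Σ_k q_k η_k)."""
    q_row = np.asarray(q_row, dtype=float)
    eta = np.asarray(eta, dtype=float)
    z = theta_i - q_row @ eta
    return _exp_pos(log_logistic(z))


def prob_constrained_2pl(theta_i: float, q_row, eta, alpha_j: float) -> float:
    """Constrained 2PL: logistic(α_j (θ − Σ_k q_k η_k)); α_j = 1 recovers the LLTM."""
    if alpha_j < 0:
        raise ValueError(f"discrimination must be >= 0, got {alpha_j}")
    q_row = np.asarray(q_row, dtype=float)
    eta = np.asarray(eta, dtype=float)
    z = alpha_j * (theta_i - q_row @ eta)
    return _exp_pos(log_logistic(z))


def _active_logprod(theta_row, difficulty_row, active_row, discrimination_row=None):
    """Σ over active components of log σ(α_m (θ_m − b_m)).

    Inactive components are excluded from the sum entirely, so the result is
    bit-identical under any change of their θ.
    """
    idx = np.flatnonzero(active_row)
    theta = np.asarray(theta_row, dtype=float)[idx]
    b = np.asarray(difficulty_row, dtype=float)[idx]
    if discrimination_row is None:
        z = theta - b
    else:
        z = np.asarray(discrimination_row, dtype=float)[idx] * (theta - b)
    return float(np.sum(log_logistic(z)))


def prob_mltmd(theta_row, item: int, composed: ComposedItemParameters) -> float:
    """MLTM-D: non-compensatory product of component logistics for one item.

    With a single component this is exactly the LLTM.
    """
    logp = _active_logprod(
        theta_row, composed.difficulty[item], composed.active[item]
    )
    return _exp_pos(logp)


def prob_gmltmd(theta_row, item: int, composed: ComposedItemParameters) -> float:
    """GMLTM-D: guessing floor plus scaled non-compensatory product.

    p = c_j + (1 − c_j) Π_m σ(α_jm (θ_m − b_jm))^{C_jm}; the value lies in
    [c_j, 1) and tends to c_j as every active ability → −∞.
    """
    c = 0.0 if composed.guessing is None else float(composed.guessing[item])
    A = composed.discrimination
    logp = _active_logprod(
        theta_row,
        composed.difficulty[item],
        composed.active[item],
        None if A is None else A[item],
    )
    return c + (1.0 - c) * _exp_pos(logp)
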