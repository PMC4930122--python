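"""Compiled likelihood kernel for the hybrid family.

A single SARSA(lambda)/model-based hybrid forward pass serves all three
models: the pure model-free model is the hybrid with omega pinned to 0, the
pure model-based model the hybrid with omega pinned to 1 (alpha1 and lam
then inert). Kept minimal and allocation-free so that subject-level fitting,
the hierarchical EM loop and Monte-Carlo evidence estimation stay fast.
"""

from __future__ import annotations

import math

import numba
import numpy as np

# Underflow floor for a choice probability: keeps the objective finite for
# extreme temperatures; log(1e-300) ~= -690 per choice.
_P_FLOOR = 1e-300


@numba.njit(cache=False)
def nll_core(
    a1: np.ndarray,
    s2: np.ndarray,
    a2: np.ndarray,
    r: np.ndarray,
    valid: np.ndarray,
    omega: float,
    alpha1: float,
    alpha2: float,
    lam: float,
    beta1: float,
    beta2: float,
    rho: float,
    p_common: float,
    q_init: float,
) -> float:
    """Negative log-likelihood of one session under the hybrid model.

    Valid trials contribute -log P(a1) - log P(a2); invalid trials
    contribute nothing and trigger no value updates.
    """
    q10 = q_init
    q11 = q_init
    q2 = np.full((2, 2), q_init)
    prev = -1
    nll = 0.0
    for t in range(a1.shape[0]):
        if valid[t] == 0:
            continue
        a = a1[t]
        s = s2[t]
        b = a2[t]
        # prospective (model-based) first-stage values
        m0 = q2[0, 0] if q2[0, 0] > q2[0, 1] else q2[0, 1]
        m1 = q2[1, 0] if q2[1, 0] > q2[1, 1] else q2[1, 1]
        qmb0 = p_common * m0 + (1.0 - p_common) * m1
        qmb1 = p_common * m1 + (1.0 - p_common) * m0
        v0 = omega * qmb0 + (1.0 - omega) * q10
        v1 = omega * qmb1 + (1.0 - omega) * q11
        l0 = beta1 * v0
        l1 = beta1 * v1
        if prev == 0:
            l0 += rho
        elif prev == 1:
            l1 += rho
        mx = l0 if l0 > l1 else l1
        e0 = math.exp(l0 - mx)
        e1 = math.exp(l1 - mx)
        p1 = (e0 if a == 0 else e1) / (e0 + e1)
        # second stage
        la = beta2 * q2[s, 0]
        lb = beta2 * q2[s, 1]
        mx2 = la if la > lb else lb
        ea = math.exp(la - mx2)
        eb = math.exp(lb - mx2)
        p2 = (ea if b == 0 else eb) / (ea + eb)
        if p1 < _P_FLOOR:
            p1 = _P_FLOOR
        if p2 < _P_FLOOR:
            p2 = _P_FLOOR
        nll -= math.log(p1) + math.log(p2)
        # SARSA(lambda) updates on the shared tables
        d1 = q2[s, b] - (q10 if a == 0 else q11)
        d2 = r[t] - q2[s, b]
        q2[s, b] += alpha2 * d2
        if a == 0:
            q10 += alpha1 * d1 + alpha1 * lam * d2
        else:
            q11 += alpha1 * d1 + alpha1 * lam * d2
        prev = a
    return nll
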