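"""Forward-recursion likelihood for the three-state model.

The likelihood conditions on first capture (occasion and observed state,
assumed recorded without misclassification) and propagates a forward
vector over the augmented latent states {B, N, P, dead}.  Per interval the
chain first survives with phi(state), then transitions by the psi row;
at the following occasion a detection in state s contributes rho_s for the
matching latent state, and a non-detection contributes 1 - rho_s for live
states and 1 for dead.
"""

from __future__ import annotations

import numpy as np

from ..defs import ALLOWED_MOVE_INDEX, STATES
from .layout import ParamLayout

_NS = len(STATES)          # live states
_NA = _NS + 1              # augmented with dead


def transition_kernel(
    beta: np.ndarray, layout: ParamLayout, interval: int, colony: int | str
) -> tuple[np.ndarray, np.ndarray]:
    """Combined survival-transition matrix and next-occasion detection vector.

    Returns a (4, 4) row-stochastic matrix over {B, N, P, dead} for the
    given interval — row s is phi_s * psi(s -> .) over live destinations and
    1 - phi_s to dead, dead absorbing — and the detection probabilities for
    the live states at occasion ``interval + 1``.
    """
    if isinstance(colony, str):
        colony = layout.colonies.index(colony)
    params = layout.realize(beta)
    M = _kernels(params, layout.n_occasions)[0][interval, colony]
    detect = params["p"][:, interval + 1, colony].copy()
    return M, detect


def _kernels(params: dict, n_occasions: int) -> tuple[np.ndarray, np.ndarray]:
    """Stack transition matrices M[t, c] and emission blocks.

    Returns ``M`` of shape (T-1, nc, 4, 4) and ``E`` of shape
    (T, nc, 5, 4): E[t, c, o] is the emission vector over latent states for
    observed code o (0 = unseen, 1..3 = seen in state, 4 unused guard).
    """
    phi, p, mv = params["phi"], params["p"], params["psi_move"]
    nc = phi.shape[2]
    T = n_occasions
    M = np.zeros((T - 1, nc, _NA, _NA))
    for s in range(_NS):
        d = ALLOWED_MOVE_INDEX[s]
        M[:, :, s, s] = phi[s] * (1.0 - mv[s])
        M[:, :, s, d] = phi[s] * mv[s]
        M[:, :, s, _NS] = 1.0 - phi[s]
    M[:, :, _NS, _NS] = 1.0

    E = np.zeros((T, nc, _NS + 2, _NA))
    with np.errstate(invalid="ignore"):
        for s in range(_NS):
            E[:, :, 0, s] = 1.0 - p[s]
            E[:, :, s + 1, s] = p[s]
    E[:, :, 0, _NS] = 1.0  # dead emits nothing
    return M, E


def _history_arrays(histories):
    if isinstance(histories, tuple):
        return histories
    return histories.compressed()


def log_likelihood(histories, beta: np.ndarray, layout: ParamLayout) -> float:
    """Total log-likelihood of the encounter histories (<= 0).

    ``histories`` is a :class:`~msmr.states.HistorySet` or a precomputed
    ``(codes, colony_index, first_occasion, counts)`` tuple from
    :meth:`~msmr.states.HistorySet.compressed`.
    """
    codes, col, first, counts = _history_arrays(histories)
    T = layout.n_occasions
    if codes.shape[1] != T:
        raise ValueError(f"histories have {codes.shape[1]} occasions, layout {T}")
    if codes.min() < 0 or codes.max() > _NS:
        raise ValueError("invalid observed state code")

    params = layout.realize(beta)
    M, E = _kernels(params, T)
    n = codes.shape[0]
    alpha = np.zeros((n, _NA))
    for t in range(T):
        starting = first == t
        if starting.any():
            alpha[starting] = 0.0
            alpha[starting, codes[starting, t] - 1] = 1.0
        if t == T - 1:
            break
        active = first <= t
        for c in np.unique(col[active]):
            rows = np.flatnonzero(active & (col == c))
            a = alpha[rows] @ M[t, c]
            a *= E[t + 1, c, codes[rows, t + 1]]
            alpha[rows] = a
    tot = alpha.sum(axis=1)
    with np.errstate(divide="ignore"):
        ll = np.log(tot)
    if np.isnan(ll).any():
        raise FloatingPointError("NaN in likelihood; check fixed parameters")
    return float(np.dot(counts, ll))
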