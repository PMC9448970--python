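"""Independent oracles: brute-force enumeration over latent state paths.

Deliberately written without the forward recursion — a plain product over
explicit latent sequences — so the likelihood implementation is checked
against an independent path.
"""

from itertools import product

import numpy as np

# live states 0=B, 1=N, 2=P; 3 = dead; single permitted move per state
_MOVE = {0: 1, 1: 0, 2: 0}
_DEAD = 3


def history_probability(codes, first, colony, params) -> float:
    """P(observed codes | first capture) by explicit path enumeration.

    ``params`` holds real-scale arrays ``phi``/``p`` (state, time, colony)
    and ``psi_move`` (state, time, colony).
    """
    phi, p, mv = params["phi"], params["p"], params["psi_move"]
    T = len(codes)
    s0 = codes[first] - 1
    total = 0.0
    for path in product(range(4), repeat=T - 1 - first):
        seq = (s0,) + path
        pr = 1.0
        for k in range(len(seq) - 1):
            a, b = seq[k], seq[k + 1]
            t = first + k
            if a == _DEAD:
                step = 1.0 if b == _DEAD else 0.0
            elif b == _DEAD:
                step = 1.0 - phi[a, t, colony]
            elif b == a:
                step = phi[a, t, colony] * (1.0 - mv[a, t, colony])
            elif b == _MOVE[a]:
                step = phi[a, t, colony] * mv[a, t, colony]
            else:
                step = 0.0
            pr *= step
            if pr == 0.0:
                break
            o = codes[t + 1]
            if o == 0:
                pr *= 1.0 if b == _DEAD else 1.0 - p[b, t + 1, colony]
            else:
                pr *= p[b, t + 1, colony] if b == o - 1 else 0.0
        total += pr
    return total


def all_observation_histories(T, first, s0):
    """Every observation-code vector with first capture at (first, s0)."""
    for tail in product(range(4), repeat=T - 1 - first):
        codes = [0] * T
        codes[first] = s0
        codes[first + 1:] = tail
        yield np.array(codes, dtype=np.int8)


def binomial_se(p: float, n: int) -> float:
    return float(np.sqrt(p * (1.0 - p) / n))
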