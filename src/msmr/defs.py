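"""Shared constants for the three-state mark-recapture pipeline.

Live states are breeder (B), nonbreeder (N) and prebreeder (P); the
augmented latent chain adds an absorbing dead state.  Observed codes use
the MARK convention: 0 = not encountered, 1/2/3 = encountered in B/N/P.
"""

from __future__ import annotations

import datetime as _dt

#: default number of annual occasions (breeding seasons)
N_OCCASIONS = 8
#: calendar year of the first occasion
FIRST_YEAR = 2013

#: colony group labels, in frequency-column order of the .inp dialect
COLONIES = ("RobbenIsland", "StonyPoint")

#: live state labels, in observed-code order (code = index + 1)
STATES = ("B", "N", "P")
STATE_INDEX = {s: i for i, s in enumerate(STATES)}
#: truth-table code for the absorbing dead state
DEAD_CODE = 4

#: the single permitted non-stay destination per origin state; every other
#: move (P->N, N->P, B->P) is a structural zero
ALLOWED_MOVE = {"B": "N", "N": "B", "P": "B"}
ALLOWED_MOVE_INDEX = {STATE_INDEX[s]: STATE_INDEX[d] for s, d in ALLOWED_MOVE.items()}

#: detection season within each calendar year (month, day), inclusive
SEASON_START = (3, 1)
SEASON_END = (10, 31)


def season_window(year: int) -> tuple[_dt.date, _dt.date]:
    """Inclusive [start, end] detection window for one season."""
    return (_dt.date(year, *SEASON_START), _dt.date(year, *SEASON_END))


def interval_label(interval: int, first_year: int = FIRST_YEAR) -> str:
    """Human label for a survival interval, e.g. ``'2013-14'``."""
    y = first_year + interval
    return f"{y}-{str(y + 1)[-2:]}"
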