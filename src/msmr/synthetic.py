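"""Truth-known simulation of the mark-recapture study design.

Generates latent state trajectories, dated detection records (nest checks
plus ground-reader ping streams) and observed encounter histories under a
configurable three-state model, so every downstream stage can be tested
against known parameters.

Event order within an interval: survive first, then transition, with
detection at the following occasion (the conditional-on-first-capture
convention used by the likelihood).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .defs import (
    ALLOWED_MOVE_INDEX,
    COLONIES,
    DEAD_CODE,
    FIRST_YEAR,
    N_OCCASIONS,
    STATES,
    season_window,
)
from .states import EncounterHistory, HistorySet

__all__ = ["SimConfig", "TruthTable", "simulate_latent", "emit_detections",
           "simulate_histories"]

_N_STATES = len(STATES)


def _per_state(value, name: str) -> np.ndarray:
    """Scalar or {'B': x, ...} -> array over live states."""
    if np.isscalar(value):
        return np.full(_N_STATES, float(value))
    try:
        return np.array([float(value[s]) for s in STATES])
    except KeyError as e:
        raise ValueError(f"{name}: missing state {e}") from None


@dataclass
class SimConfig:
    """True parameters and study design for one simulated dataset.

    Array shapes: ``phi`` (state, interval, colony), ``p`` (state,
    occasion, colony), ``psi`` (origin, destination, interval, colony) over
    live states, ``marking_schedule`` (colony, occasion, state) counts of
    newly marked individuals.
    """

    n_occasions: int = N_OCCASIONS
    colonies: tuple[str, ...] = COLONIES
    marking_schedule: np.ndarray | None = None
    phi: np.ndarray | None = None
    p: np.ndarray | None = None
    psi: np.ndarray | None = None
    reader_rate_breeder: float = 20.0
    reader_rate_other: float = 2.0
    nest_check_rate: float = 0.9
    #: length (days) of a breeder's attendance window; breeder pings fall
    #: uniformly inside it so their span respects the classification rule,
    #: while non-breeder pings spread over the whole season
    attempt_days: int = 100
    first_year: int = FIRST_YEAR
    seed: int = 0

    @classmethod
    def constant(
        cls,
        phi=0.8,
        p=0.9,
        psi_move=0.15,
        n_per_colony: int = 250,
        breeders_only_first: bool = True,
        **kwargs,
    ) -> "SimConfig":
        """Time/colony-constant configuration from scalars or per-state dicts.

        ``psi_move`` is the probability of leaving the current state for its
        single permitted destination.  The default marking schedule marks
        breeders only at the first occasion and a breeder/prebreeder mix at
        later occasions, mirroring the study design (a newly marked
        nonbreeder has never been seen breeding, hence is a prebreeder).
        """
        cfg = cls(**kwargs)
        T, nc = cfg.n_occasions, len(cfg.colonies)
        phi_s = _per_state(phi, "phi")
        p_s = _per_state(p, "p")
        mv = _per_state(psi_move, "psi_move")
        cfg.phi = np.broadcast_to(phi_s[:, None, None], (_N_STATES, T - 1, nc)).copy()
        cfg.p = np.broadcast_to(p_s[:, None, None], (_N_STATES, T, nc)).copy()
        psi = np.zeros((_N_STATES, _N_STATES, T - 1, nc))
        for s, d in ALLOWED_MOVE_INDEX.items():
            psi[s, s] = 1.0 - mv[s]
            psi[s, d] = mv[s]
        cfg.psi = psi
        sched = np.zeros((nc, T, _N_STATES), dtype=int)
        sched[:, 0, 0] = n_per_colony
        if not breeders_only_first:
            sched[:, 0, 2] = n_per_colony // 2
        for t in range(1, T - 1):
            sched[:, t, 0] = max(n_per_colony // 10, 1)
            sched[:, t, 2] = max(n_per_colony // 20, 1)
        cfg.marking_schedule = sched
        cfg.validate()
        return cfg

    def validate(self) -> None:
        T, nc = self.n_occasions, len(self.colonies)
        shapes = {
            "phi": (self.phi, (_N_STATES, T - 1, nc)),
            "p": (self.p, (_N_STATES, T, nc)),
            "psi": (self.psi, (_N_STATES, _N_STATES, T - 1, nc)),
            "marking_schedule": (self.marking_schedule, (nc, T, _N_STATES)),
        }
        for name, (arr, shape) in shapes.items():
            if arr is None or np.asarray(arr).shape != shape:
                raise ValueError(f"{name}: expected array of shape {shape}")
        for name, arr in (("phi", self.phi), ("p", self.p), ("psi", self.psi)):
            bad = np.argwhere((arr < 0) | (arr > 1))
            if len(bad):
                idx = tuple(int(j) for j in bad[0])
                raise ValueError(f"{name}: probability outside [0,1] at index {idx}")
        rows = self.psi.sum(axis=1)
        bad = np.argwhere(~np.isclose(rows, 1.0, atol=1e-9))
        if len(bad):
            idx = tuple(int(j) for j in bad[0])
            raise ValueError(f"psi: row does not sum to 1 at index {idx}")
        for s in range(_N_STATES):
            for d in range(_N_STATES):
                if d != s and d != ALLOWED_MOVE_INDEX[s]:
                    if np.any(self.psi[s, d] != 0):
                        raise ValueError(
                            f"psi: structural zero violated for "
                            f"{STATES[s]}->{STATES[d]}"
                        )
        if np.any(self.marking_schedule < 0):
            raise ValueError("marking_schedule: negative count")
        if self.reader_rate_breeder < 0 or self.reader_rate_other < 0:
            raise ValueError("reader rates must be non-negative")
        if not 0 <= self.nest_check_rate <= 1:
            raise ValueError("nest_check_rate must be in [0,1]")

    def to_yaml(self, path) -> None:
        doc = {
            "n_occasions": self.n_occasions,
            "colonies": list(self.colonies),
            "first_year": self.first_year,
            "seed": self.seed,
            "reader_rate_breeder": self.reader_rate_breeder,
            "reader_rate_other": self.reader_rate_other,
            "nest_check_rate": self.nest_check_rate,
            "attempt_days": self.attempt_days,
            "marking_schedule": self.marking_schedule.tolist(),
            "phi": self.phi.tolist(),
            "p": self.p.tolist(),
            "psi": self.psi.tolist(),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        for key in ("marking_schedule", "phi", "p", "psi"):
            doc[key] = np.asarray(doc[key], dtype=float)
        doc["marking_schedule"] = doc["marking_schedule"].astype(int)
        doc["colonies"] = tuple(doc["colonies"])
        cfg = cls(**doc)
        cfg.validate()
        return cfg


@dataclass
class TruthTable:
    """Latent trajectories for simulated individuals.

    ``states[i, t]`` uses codes 0 (before marking), 1/2/3 (live B/N/P) and
    4 (dead).  Dead is absorbing and no trajectory revisits prebreeder
    after breeding.
    """

    ids: list[str]
    colony_index: np.ndarray
    first_occasion: np.ndarray
    states: np.ndarray

    def __len__(self) -> int:
        return len(self.ids)

    def to_frame(self, first_year: int = FIRST_YEAR) -> pd.DataFrame:
        T = self.states.shape[1]
        df = pd.DataFrame(
            self.states, columns=[f"state_{first_year + t}" for t in range(T)]
        )
        df.insert(0, "individual_id", self.ids)
        df.insert(1, "colony", [COLONIES[c] for c in self.colony_index])
        df.insert(2, "first_occasion", self.first_occasion)
        return df

    def to_csv(self, path, first_year: int = FIRST_YEAR) -> None:
        self.to_frame(first_year).to_csv(path, index=False)


def simulate_latent(config: SimConfig) -> TruthTable:
    """Draw latent trajectories: survive each interval, then transition."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    T = config.n_occasions

    ids: list[str] = []
    colony_idx: list[int] = []
    first_occ: list[int] = []
    first_state: list[int] = []
    for c, colony in enumerate(config.colonies):
        tag = "".join(w[0] for w in __split_words(colony))
        k = 0
        for t in range(T):
            for s in range(_N_STATES):
                for _ in range(int(config.marking_schedule[c, t, s])):
                    ids.append(f"{tag}-{k:06d}")
                    colony_idx.append(c)
                    first_occ.append(t)
                    first_state.append(s)
                    k += 1
    n = len(ids)
    colony_idx = np.array(colony_idx, dtype=np.int64)
    first_occ = np.array(first_occ, dtype=np.int64)
    states = np.zeros((n, T), dtype=np.int8)
    cur = np.full(n, -1, dtype=np.int64)  # live state index, or -2 dead

    for t in range(T):
        newly = first_occ == t
        cur[newly] = np.array(first_state, dtype=np.int64)[newly]
        marked = first_occ <= t
        live = marked & (cur >= 0)
        states[live, t] = cur[live] + 1
        states[marked & (cur == -2), t] = DEAD_CODE
        if t == T - 1:
            break
        u_surv = rng.random(n)
        u_move = rng.random(n)
        prev = cur.copy()  # snapshot: one survival + one transition per interval
        for c in range(len(config.colonies)):
            for s in range(_N_STATES):
                sel = live & (colony_idx == c) & (prev == s)
                if not sel.any():
                    continue
                died = sel & (u_surv >= config.phi[s, t, c])
                cur[died] = -2
                moved = sel & ~died & (u_move < config.psi[s, ALLOWED_MOVE_INDEX[s], t, c])
                cur[moved] = ALLOWED_MOVE_INDEX[s]
    return TruthTable(ids, colony_idx, first_occ, states)


def __split_words(name: str) -> list[str]:
    out, cur = [], ""
    for ch in name:
        if ch.isupper() and cur:
            out.append(cur)
            cur = ch
        else:
            cur += ch
    out.append(cur)
    return out


def emit_detections(truth: TruthTable, config: SimConfig) -> pd.DataFrame:
    """Emit dated nest-check and ground-reader records from latent truth.

    Breeders yield a nest record with breeding evidence with probability
    ``nest_check_rate`` per season, and reader ping counts are Poisson with
    state-dependent mean.  Breeder pings fall uniformly on days of a
    breeding-attempt window of ``attempt_days`` placed uniformly within the
    March-October season; other pings fall uniformly over the whole season.
    Dead or unmarked individual-occasions emit nothing and no record leaks
    the latent state.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    T = config.n_occasions
    rows = []
    for i in range(len(truth)):
        colony = COLONIES[truth.colony_index[i]]
        for t in range(T):
            s = truth.states[i, t]
            if s in (0, DEAD_CODE):
                continue
            year = config.first_year + t
            lo, hi = season_window(year)
            n_days = (hi - lo).days + 1
            window = min(config.attempt_days, n_days)
            start = int(rng.integers(n_days - window + 1)) if s == 1 else 0
            width = window if s == 1 else n_days
            if s == 1 and rng.random() < config.nest_check_rate:
                d = lo + dt.timedelta(days=start + int(rng.integers(width)))
                rows.append((truth.ids[i], colony, d.isoformat(), "nest", 1))
            rate = config.reader_rate_breeder if s == 1 else config.reader_rate_other
            for off in rng.integers(width, size=rng.poisson(rate)):
                d = lo + dt.timedelta(days=start + int(off))
                rows.append((truth.ids[i], colony, d.isoformat(), "reader", 0))
    df = pd.DataFrame(
        rows, columns=["individual_id", "colony", "date", "method", "breeding_evidence"]
    )
    df["date"] = pd.to_datetime(df["date"])
    return df.sort_values(["individual_id", "date"], kind="stable").reset_index(drop=True)


def simulate_histories(
    config: SimConfig, return_truth: bool = False
) -> HistorySet | tuple[HistorySet, TruthTable]:
    """Draw encounter histories directly at the occasion level.

    Observation equals the latent state with probability ``p(state,
    occasion, colony)`` and 0 otherwise, conditioned on the marking
    occasion and state (always observed when marked).
    """
    truth = simulate_latent(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    T = config.n_occasions
    n = len(truth)
    u = rng.random((n, T))
    codes = np.zeros((n, T), dtype=np.int8)
    for i in range(n):
        c = truth.colony_index[i]
        for t in range(T):
            s = truth.states[i, t]
            if s in (0, DEAD_CODE):
                continue
            if t == truth.first_occasion[i] or u[i, t] < config.p[s - 1, t, c]:
                codes[i, t] = s
    histories = HistorySet(
        EncounterHistory(truth.ids[i], COLONIES[truth.colony_index[i]],
                         tuple(int(x) for x in codes[i]))
        for i in range(n)
    )
    return (histories, truth) if return_truth else histories
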