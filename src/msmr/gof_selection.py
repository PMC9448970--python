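"""Goodness-of-fit components, overdispersion, QAICc and stepwise selection.

The omnibus goodness-of-fit statistic for the general multistate model is
assembled from contingency-table components on the encounter histories:

* ``Test3G.SR`` — per occasion and observed state, newly marked versus
  previously seen animals, crossed with seen-again-later versus never.
* ``Test3G.Sm`` — among animals seen again, new versus old crossed with the
  occasion of next re-encounter.
* ``TestM.ITEC`` — among animals seen at the next occasion, captured versus
  not captured now, crossed with the state observed next.
* ``TestM.LTEC`` — as ITEC but for animals next seen two or more occasions
  later, crossed with the state at that encounter.

Cells are pooled (smallest expected count merged into its neighbor) until
every expected count reaches 2; pooling can only reduce a table's degrees
of freedom.  The omnibus statistic and df are the sums over components.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.stats

from .model.spec import ModelSpec
from .model.fit import FitResult, fit as _fit

__all__ = [
    "GofComponent",
    "ModelRecord",
    "pearson_chi2",
    "pool_table",
    "jmv_components",
    "chat_from_gof",
    "qaicc",
    "rank_models",
    "select_parsimonious",
    "select_stepwise",
]


@dataclass
class GofComponent:
    name: str
    chi_square: float
    df: int
    p_value: float
    subtables: list = field(default_factory=list)


@dataclass
class ModelRecord:
    label: str
    K: int
    minus2ll: float
    qaicc: float
    delta: float = np.nan
    weight: float = np.nan
    fit: FitResult | None = None


# ---------------------------------------------------------------------------
# contingency machinery
# ---------------------------------------------------------------------------

def _trim(table: np.ndarray) -> np.ndarray:
    """Drop all-zero rows and columns."""
    table = np.asarray(table, dtype=float)
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    return table


def _expected(table: np.ndarray) -> np.ndarray:
    total = table.sum()
    return np.outer(table.sum(axis=1), table.sum(axis=0)) / total


def pool_table(table: np.ndarray, min_expected: float = 2.0) -> np.ndarray:
    """Merge sparse cells until every expected count is >= ``min_expected``.

    The cell with the smallest expected count is merged into its row
    neighbor (adjacent column) while more than two columns remain, then
    into its column neighbor while more than two rows remain; a 2x2 table
    is never reduced further.
    """
    table = _trim(table)
    while table.size and min(table.shape) >= 2:
        exp = _expected(table)
        if exp.min() >= min_expected:
            break
        r, c = np.unravel_index(np.argmin(exp), exp.shape)
        if table.shape[1] > 2:
            other = c - 1 if c > 0 else c + 1
            table[:, other] += table[:, c]
            table = np.delete(table, c, axis=1)
        elif table.shape[0] > 2:
            other = r - 1 if r > 0 else r + 1
            table[other, :] += table[r, :]
            table = np.delete(table, r, axis=0)
        else:
            break
        table = _trim(table)
    return table


def pearson_chi2(table: np.ndarray, pool: bool = True) -> tuple[float, int]:
    """Pearson chi-square and df of a contingency table (0 df if degenerate)."""
    table = pool_table(table) if pool else _trim(np.asarray(table, float))
    if table.size == 0 or min(table.shape) < 2:
        return 0.0, 0
    exp = _expected(table)
    chi2 = float(((table - exp) ** 2 / exp).sum())
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    return chi2, df


def _component(name: str, tables: list[tuple[str, np.ndarray]]) -> GofComponent:
    chi2 = 0.0
    df = 0
    subs = []
    for label, tab in tables:
        c, d = pearson_chi2(tab)
        chi2 += c
        df += d
        subs.append({"label": label, "table": np.asarray(tab, float),
                     "chi_square": c, "df": d})
    p = float(scipy.stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return GofComponent(name, chi2, df, p, subs)


# ---------------------------------------------------------------------------
# JMV components
# ---------------------------------------------------------------------------

def jmv_components(histories) -> tuple[list[GofComponent], tuple[float, int, float]]:
    """Goodness-of-fit components and the omnibus (chi2, df, p) sum.

    Requires at least two occasions; the TestM components are empty (0 df)
    when fewer than three occasions are available.  Degenerate sub-tables
    contribute zero df.
    """
    codes, _, first = histories.as_arrays()
    T = codes.shape[1]
    if T < 2:
        raise ValueError("goodness-of-fit needs >= 2 occasions")
    seen = codes != 0

    sr_tables, sm_tables = [], []
    for i in range(1, T - 1):
        for s in (1, 2, 3):
            here = codes[:, i] == s
            if not here.any():
                continue
            new = here & (first == i)
            old = here & (first < i)
            reseen = seen[:, i + 1:].any(axis=1)
            sr = np.array([
                [(new & reseen).sum(), (new & ~reseen).sum()],
                [(old & reseen).sum(), (old & ~reseen).sum()],
            ])
            sr_tables.append((f"occ{i}:state{s}", sr))
            nxt = np.where(reseen, seen[:, i + 1:].argmax(axis=1) + i + 1, -1)
            sm = np.array([
                [((grp & reseen) & (nxt == j)).sum() for j in range(i + 1, T)]
                for grp in (new, old)
            ])
            sm_tables.append((f"occ{i}:state{s}", sm))

    itec_tables, ltec_tables = [], []
    for i in range(1, T - 1):
        known = first < i
        caught = seen[:, i]
        nxt_seen = seen[:, i + 1]
        itec = np.array([
            [((known & (caught == was) & nxt_seen) & (codes[:, i + 1] == s)).sum()
             for s in (1, 2, 3)]
            for was in (True, False)
        ])
        itec_tables.append((f"occ{i}", itec))
        if i + 2 < T:
            later = seen[:, i + 2:].any(axis=1)
            sample = known & ~nxt_seen & later
            nxt = seen[:, i + 2:].argmax(axis=1) + i + 2
            nxt_state = codes[np.arange(len(codes)), np.where(sample, nxt, 0)]
            ltec = np.array([
                [((sample & (caught == was)) & (nxt_state == s)).sum()
                 for s in (1, 2, 3)]
                for was in (True, False)
            ])
            ltec_tables.append((f"occ{i}", ltec))

    components = [
        _component("Test3G.SR", sr_tables),
        _component("Test3G.Sm", sm_tables),
        _component("TestM.ITEC", itec_tables),
        _component("TestM.LTEC", ltec_tables),
    ]
    chi2 = sum(c.chi_square for c in components)
    df = sum(c.df for c in components)
    p = float(scipy.stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return components, (chi2, df, p)


def gof_report(components, omnibus) -> pd.DataFrame:
    rows = [
        {"component": c.name, "chi_square": c.chi_square, "df": c.df,
         "p_value": c.p_value}
        for c in components
    ]
    rows.append({"component": "omnibus", "chi_square": omnibus[0],
                 "df": omnibus[1], "p_value": omnibus[2]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# overdispersion and information criteria
# ---------------------------------------------------------------------------

def chat_from_gof(chi_square: float, df: int, floor_at_one: bool = False) -> float:
    """Variance inflation factor: the GOF chi-square over its df."""
    if df <= 0:
        raise ValueError("c-hat is undefined for df <= 0")
    chat = chi_square / df
    if chat < 1.0 and floor_at_one:
        return 1.0
    return chat


def qaicc(minus2lnl: float, K: int, ess: float, chat: float = 1.0) -> float:
    """Quasi-likelihood AIC with small-sample correction.

    ``(-2lnL)/chat + 2K + 2K(K+1)/(ess - K - 1)``; reduces to AICc at
    ``chat=1``.  Fails explicitly when ``ess <= K + 1``.
    """
    if chat <= 0:
        raise ValueError("chat must be positive")
    if ess <= K + 1:
        raise ValueError(
            f"effective sample size {ess} too small for K={K} "
            "(small-sample correction undefined)"
        )
    return minus2lnl / chat + 2 * K + 2 * K * (K + 1) / (ess - K - 1)


def rank_models(records: list[ModelRecord]) -> list[ModelRecord]:
    """Sort by QAICc and fill in delta and Akaike weights (sum to 1)."""
    ranked = sorted(records, key=lambda r: r.qaicc)
    best = ranked[0].qaicc
    raw = np.array([np.exp(-0.5 * (r.qaicc - best)) for r in ranked])
    w = raw / raw.sum()
    for r, wi in zip(ranked, w):
        r.delta = r.qaicc - best
        r.weight = float(wi)
    return ranked


def select_parsimonious(records: list[ModelRecord], delta_max: float = 2.0) -> ModelRecord:
    """Within ``delta < delta_max`` of the best QAICc, pick the fewest
    parameters; ties on K break by lower QAICc."""
    ranked = rank_models(records)
    close = [r for r in ranked if r.delta < delta_max]
    return min(close, key=lambda r: (r.K, r.qaicc))


# ---------------------------------------------------------------------------
# stepwise selection
# ---------------------------------------------------------------------------

_STAGE_ORDER = ("p", "phi", "psi")


def select_stepwise(
    histories,
    candidates: dict[str, list[str]],
    general: ModelSpec,
    chat: float = 1.0,
    *,
    seed: int = 0,
    n_starts: int = 2,
    first_year: int = 2013,
    colonies=None,
) -> tuple[ModelSpec, pd.DataFrame, dict[str, list[ModelRecord]]]:
    """The study's stepwise procedure: model recapture first, then survival,
    then transition, carrying each stage's most parsimonious winner forward.

    ``candidates`` maps each class name to its formula candidates; classes
    not under selection are held at the general structure until their stage
    (and at the chosen structure after).  Non-converged candidates are
    excluded with a logged reason.  Returns the chosen spec, the full model
    table and the per-stage records.
    """
    from .defs import COLONIES as _COL

    colonies = colonies or _COL
    chosen = {"phi": general.phi, "p": general.p, "psi": general.psi}
    all_rows = []
    stage_records: dict[str, list[ModelRecord]] = {}
    for stage in _STAGE_ORDER:
        formulas = candidates.get(stage) or [chosen[stage]]
        records = []
        for f in formulas:
            spec = replace(general, **{**chosen, stage: f},
                           label=f"{stage}({f})")
            try:
                res = _fit(spec, histories, seed=seed, n_starts=n_starts,
                           first_year=first_year, colonies=tuple(colonies))
            except (ValueError, FloatingPointError) as e:
                all_rows.append({"stage": stage, "model": f, "K": np.nan,
                                 "minus2ll": np.nan, "qaicc": np.nan,
                                 "note": f"failed: {e}"})
                continue
            if not res.converged:
                all_rows.append({"stage": stage, "model": f, "K": res.K,
                                 "minus2ll": res.minus2ll, "qaicc": np.nan,
                                 "note": "not converged"})
                continue
            records.append(ModelRecord(
                label=f, K=res.K, minus2ll=res.minus2ll,
                qaicc=qaicc(res.minus2ll, res.K, res.ess, chat), fit=res,
            ))
        if not records:
            raise RuntimeError(f"no candidate converged at stage {stage!r}")
        winner = select_parsimonious(records)
        chosen[stage] = winner.label
        stage_records[stage] = rank_models(records)
        for r in stage_records[stage]:
            all_rows.append({
                "stage": stage, "model": r.label, "K": r.K,
                "minus2ll": r.minus2ll, "qaicc": r.qaicc, "delta": r.delta,
                "weight": r.weight,
                "note": "selected" if r is winner else "",
            })

    final = replace(general, **chosen,
                    label=f"phi({chosen['phi']}) p({chosen['p']}) "
                          f"psi({chosen['psi']})")
    table = pd.DataFrame(all_rows)
    return final, table, stage_records
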