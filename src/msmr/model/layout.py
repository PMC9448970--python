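"""Realize symbolic model structures as design matrices on the link scale.

Each parameter class (phi, p, psi) has one real-parameter cell per
(state, time, colony) combination: survival and transition cells are
indexed by interval, recapture cells by occasion (the first occasion is
conditioned on and has no recapture cell).  Fixed cells are masked out of
the design entirely — they contribute nothing to K — and the design matrix
over the free cells is reduced to full column rank, so a saturated formula
on a partially fixed layout counts exactly one parameter per free cell
(the PIM convention of program MARK).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
import patsy
import scipy.linalg

from ..defs import COLONIES, STATES
from .spec import COVARIATE_NAMES, ModelSpec

_FACTORS = {"state", "time", "colony", "sardine", "anchovy", "combined"}


def _patsy_formula(formula: str) -> str:
    f = formula.strip().replace("×", "*")
    if f in ("", "1", "constant", "."):
        return "1"
    f = re.sub(r"\bcombined_biomass\b", "combined", f)
    names = set(re.findall(r"[A-Za-z_][A-Za-z_0-9]*", f)) - {"C"}
    unknown = names - _FACTORS
    if unknown:
        raise ValueError(f"unknown factor(s) in formula {formula!r}: {sorted(unknown)}")
    f = re.sub(r"\btime\b", "C(time)", f)
    return f


def _formula_covariates(formula: str) -> set[str]:
    f = formula.replace("combined_biomass", "combined")
    return set(re.findall(r"[A-Za-z_][A-Za-z_0-9]*", f)) & set(COVARIATE_NAMES)


@dataclass
class ClassLayout:
    """Design information for one parameter class."""

    name: str
    cells: pd.DataFrame        # one row per real cell: state, time, colony, fixed, value
    X: np.ndarray              # (n_free_cells, k) full-column-rank design
    colnames: list[str]
    design_info: object | None # patsy DesignInfo for prediction on new data
    free_rows: np.ndarray      # positional indices of non-fixed cells

    @property
    def k(self) -> int:
        return self.X.shape[1]


@dataclass
class ParamLayout:
    """Mapping from model structure to a single packed beta vector."""

    classes: dict[str, ClassLayout]
    slices: dict[str, slice]
    n_occasions: int
    colonies: tuple[str, ...]

    @property
    def K(self) -> int:
        return sum(cl.k for cl in self.classes.values())

    def split(self, beta: np.ndarray) -> dict[str, np.ndarray]:
        return {name: beta[sl] for name, sl in self.slices.items()}

    def realize(self, beta: np.ndarray) -> dict[str, np.ndarray]:
        """Real-scale parameter arrays from a packed beta vector.

        Returns ``phi`` (state, interval, colony), ``p`` (state, occasion,
        colony; first occasion NaN) and ``psi_move`` (state, interval,
        colony), with fixed cells at their fixed values.  ``psi_move`` is
        the probability of leaving the state for its single permitted
        destination (binary logit, stay as reference — the multinomial
        logit collapses to this under the structural zeros).
        """
        beta = np.asarray(beta, dtype=float)
        if beta.shape != (self.K,):
            raise ValueError(f"beta has length {beta.shape}, expected ({self.K},)")
        T, nc = self.n_occasions, len(self.colonies)
        shapes = {"phi": (len(STATES), T - 1, nc),
                  "p": (len(STATES), T, nc),
                  "psi": (len(STATES), T - 1, nc)}
        out: dict[str, np.ndarray] = {}
        for name, cl in self.classes.items():
            arr = np.full(shapes[name], np.nan)
            cells = cl.cells
            eta = cl.X @ beta[self.slices[name]]
            eta = np.clip(eta, -35.0, 35.0)
            vals = 1.0 / (1.0 + np.exp(-eta))
            free = cells.iloc[cl.free_rows]
            arr[free["state_idx"].to_numpy(),
                free["time"].to_numpy(),
                free["colony_idx"].to_numpy()] = vals
            fixed = cells[cells["fixed"]]
            arr[fixed["state_idx"].to_numpy(),
                fixed["time"].to_numpy(),
                fixed["colony_idx"].to_numpy()] = fixed["value"].to_numpy()
            out[name if name != "psi" else "psi_move"] = arr
        return out


def _cell_table(
    cls_name: str,
    spec: ModelSpec,
    n_occasions: int,
    colonies: tuple[str, ...],
    first_year: int,
) -> pd.DataFrame:
    times = range(1, n_occasions) if cls_name == "p" else range(n_occasions - 1)
    rows = []
    for si, s in enumerate(STATES):
        for t in times:
            for ci, c in enumerate(colonies):
                rows.append({"state": s, "state_idx": si, "time": t,
                             "colony": c, "colony_idx": ci})
    cells = pd.DataFrame(rows)

    formula = getattr(spec, cls_name)
    used_cov = _formula_covariates(formula)
    if used_cov:
        if cls_name == "p":
            raise ValueError("biomass covariates are not defined for recapture")
        if spec.covariates is None:
            raise ValueError(
                f"{cls_name} formula references {sorted(used_cov)} but no "
                "biomass series is attached"
            )
        cov = spec.covariates.covariates_for_intervals(first_year, n_occasions - 1)
        for name in COVARIATE_NAMES:
            cells[name] = cov[name].to_numpy()[cells["time"].to_numpy()]

    cells["fixed"] = False
    cells["value"] = np.nan
    for fp in spec.fixed:
        if fp.cls != cls_name:
            continue
        sel = (cells["state"] == fp.state) & (cells["time"] == fp.index)
        if fp.colony is not None:
            sel &= cells["colony"] == fp.colony
        if not sel.any():
            raise ValueError(f"fixed parameter addresses no cell: {fp}")
        cells.loc[sel, "fixed"] = True
        cells.loc[sel, "value"] = fp.value
    return cells


def _full_rank(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    """Drop linearly dependent columns (pivoted QR), preserving order."""
    if X.shape[1] == 0:
        return X, names
    _, r, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = max(X.shape) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
    rank = int((diag > tol).sum())
    keep = np.sort(piv[:rank])
    return X[:, keep], [names[j] for j in keep]


def build_layout(
    spec: ModelSpec,
    n_occasions: int,
    colonies: tuple[str, ...] = COLONIES,
    first_year: int = 2013,
) -> ParamLayout:
    """Build the design layout realizing a model spec.

    Raises on formulas naming unknown factors, covariate terms without an
    attached biomass series, and fixed parameters addressing no cell.
    """
    classes: dict[str, ClassLayout] = {}
    slices: dict[str, slice] = {}
    offset = 0
    for cls_name in ("phi", "p", "psi"):
        cells = _cell_table(cls_name, spec, n_occasions, colonies, first_year)
        free_rows = np.flatnonzero(~cells["fixed"].to_numpy())
        free = cells.iloc[free_rows]
        if len(free) == 0:
            X = np.zeros((0, 0))
            colnames: list[str] = []
            dinfo = None
        else:
            dm = patsy.dmatrix(_patsy_formula(getattr(spec, cls_name)), free,
                               return_type="dataframe")
            X, colnames = _full_rank(dm.to_numpy(), list(dm.columns))
            dinfo = dm.design_info
        classes[cls_name] = ClassLayout(cls_name, cells, X, colnames, dinfo,
                                        free_rows)
        slices[cls_name] = slice(offset, offset + X.shape[1])
        offset += X.shape[1]
    return ParamLayout(classes, slices, n_occasions, tuple(colonies))
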