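"""Maximum-likelihood fitting and real-scale estimates."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
import scipy.optimize
from statsmodels.tools.numdiff import approx_hess1

from ..defs import ALLOWED_MOVE, COLONIES, interval_label
from .layout import ParamLayout, build_layout
from .likelihood import log_likelihood
from .spec import ModelSpec

log = logging.getLogger(__name__)

_Z95 = 1.959963984540054


@dataclass
class FitResult:
    """A maximized model: estimates, covariance and QAICc inputs."""

    label: str
    spec: ModelSpec
    layout: ParamLayout
    beta: np.ndarray
    cov: np.ndarray | None
    minus2ll: float
    K: int
    ess: int
    n_histories: int
    converged: bool
    singular: bool
    message: str
    inestimable_cols: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))
    start_values: list[float] = field(default_factory=list)
    seed: int = 0

    @property
    def loglik(self) -> float:
        return -0.5 * self.minus2ll


def _expit(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -35, 35)))


def fit(
    spec: ModelSpec,
    histories,
    *,
    first_year: int = 2013,
    colonies: tuple[str, ...] = COLONIES,
    seed: int = 0,
    n_starts: int = 5,
    start_sd: float = 0.75,
    maxiter: int = 2000,
) -> FitResult:
    """Fit a model spec to encounter histories by quasi-Newton optimization.

    Multi-start L-BFGS-B (first start at zero on the link scale, the rest
    seeded perturbations); covariance from the inverse numerical Hessian at
    the optimum.  Non-convergence of every start yields a flagged result
    rather than an exception; a singular Hessian marks the parameters in
    its null space as inestimable (boundary or confounded cells).
    """
    layout = build_layout(spec, histories.n_occasions, colonies, first_year)
    data = histories.compressed()
    K = layout.K
    if K < 1:
        raise ValueError("model has no estimable parameter")

    def nll(beta):
        v = log_likelihood(data, beta, layout)
        return np.inf if not np.isfinite(v) else -v

    rng = np.random.default_rng(seed)
    best = None
    start_values = []
    for s in range(max(1, n_starts)):
        x0 = np.zeros(K) if s == 0 else rng.normal(0.0, start_sd, K)
        res = scipy.optimize.minimize(
            nll, x0, method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": 1e-10, "gtol": 1e-7},
        )
        start_values.append(float(res.fun))
        if best is None or res.fun < best.fun - 1e-9:
            best = res
    converged = bool(best.success) and np.isfinite(best.fun)
    if not converged:
        log.warning("fit %s did not converge: %s", spec.name, best.message)

    cov = None
    singular = False
    bad_cols = np.zeros(K, dtype=bool)
    if np.isfinite(best.fun):
        try:
            H = approx_hess1(best.x, nll)
            evals, evecs = np.linalg.eigh(H)
            tol = max(1e-8, np.abs(evals).max() * 1e-10)
            deficient = evals < tol
            if deficient.any():
                singular = True
                bad_cols = (np.abs(evecs[:, deficient]) > 1e-4).any(axis=1)
                cov = np.linalg.pinv(H)
            else:
                cov = np.linalg.inv(H)
            neg = np.diag(cov) <= 0
            if neg.any():
                singular = True
                bad_cols |= neg
        except (np.linalg.LinAlgError, FloatingPointError):
            singular = True
            bad_cols[:] = True

    return FitResult(
        label=spec.name, spec=spec, layout=layout, beta=best.x, cov=cov,
        minus2ll=float(2.0 * best.fun), K=K, ess=histories.n_release_events(),
        n_histories=len(histories), converged=converged, singular=singular,
        message=str(best.message), inestimable_cols=bad_cols,
        start_values=start_values, seed=seed,
    )


def _cell_frame(fit_result: FitResult, cls_name: str, first_year: int) -> pd.DataFrame:
    layout = fit_result.layout
    cl = layout.classes[cls_name]
    beta = fit_result.beta[layout.slices[cls_name]]
    cov = (
        fit_result.cov[layout.slices[cls_name], layout.slices[cls_name]]
        if fit_result.cov is not None
        else None
    )
    rows = []
    free_pos = {row: j for j, row in enumerate(cl.free_rows)}
    for i, cell in cl.cells.iterrows():
        entry = {
            "param": cls_name,
            "state": cell["state"],
            "time_index": int(cell["time"]),
            "colony": cell["colony"],
            "fixed": bool(cell["fixed"]),
        }
        if cls_name == "p":
            entry["label"] = str(first_year + cell["time"])
        else:
            entry["label"] = interval_label(int(cell["time"]), first_year)
        if cell["fixed"]:
            entry.update(estimate=float(cell["value"]), se=0.0,
                         lcl=float(cell["value"]), ucl=float(cell["value"]),
                         estimable=True)
        else:
            x = cl.X[free_pos[i]]
            eta = float(x @ beta)
            est = float(_expit(eta))
            bad = fit_result.inestimable_cols[layout.slices[cls_name]]
            inestimable = bool((np.abs(x)[bad] > 1e-8).any()) if bad.size else False
            if cov is None or inestimable:
                entry.update(estimate=est, se=np.nan, lcl=np.nan, ucl=np.nan,
                             estimable=False)
            else:
                var_eta = float(x @ cov @ x)
                var_eta = max(var_eta, 0.0)
                se_eta = np.sqrt(var_eta)
                grad = est * (1.0 - est)
                entry.update(
                    estimate=est,
                    se=grad * se_eta,
                    lcl=float(_expit(eta - _Z95 * se_eta)),
                    ucl=float(_expit(eta + _Z95 * se_eta)),
                    estimable=True,
                )
        rows.append(entry)
    return pd.DataFrame(rows)


def real_estimates(fit_result: FitResult, first_year: int = 2013) -> pd.DataFrame:
    """Real-scale estimate table with delta-method SEs and 95% CIs.

    Transition rows appear twice per origin state: the move probability to
    the single permitted destination and the stay probability obtained by
    subtraction (rows sum to 1).  Fixed cells carry SE 0; cells confounded
    at the optimum (singular Hessian) are marked inestimable with NaN SEs.
    """
    frames = []
    for cls_name in ("phi", "p", "psi"):
        df = _cell_frame(fit_result, cls_name, first_year)
        if cls_name == "psi":
            move = df.copy()
            move["transition"] = [f"{s}->{ALLOWED_MOVE[s]}" for s in move["state"]]
            stay = df.copy()
            stay["transition"] = [f"{s}->{s}" for s in stay["state"]]
            stay["estimate"] = 1.0 - stay["estimate"]
            stay[["lcl", "ucl"]] = np.column_stack(
                [1.0 - df["ucl"], 1.0 - df["lcl"]]
            )
            df = pd.concat([move, stay], ignore_index=True)
        else:
            df["transition"] = ""
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    cols = ["param", "state", "transition", "time_index", "label", "colony",
            "estimate", "se", "lcl", "ucl", "fixed", "estimable"]
    return out[cols]


def _new_data_rows(layout: ParamLayout, cls_name: str, values: dict) -> np.ndarray:
    cl = layout.classes[cls_name]
    if cl.design_info is None:
        raise ValueError(f"{cls_name} has no free design")
    df = pd.DataFrame([values])
    (X,) = patsy.build_design_matrices([cl.design_info], df)
    return np.asarray(X)[0]


def covariate_slopes(
    fit_result: FitResult, cls_name: str, covariate: str, state: str = "B"
) -> pd.DataFrame:
    """Per-colony link-scale slope of a covariate term (finite difference).

    Slopes are on the standardized-covariate scale; their signs are
    invariant to the standardization.
    """
    layout = fit_result.layout
    beta = fit_result.beta[layout.slices[cls_name]]
    base = {c: 0.0 for c in ("sardine", "anchovy", "combined")}
    rows = []
    for colony in layout.colonies:
        lo = _new_data_rows(layout, cls_name,
                            {**base, "state": state, "colony": colony, "time": 0})
        hi = _new_data_rows(layout, cls_name,
                            {**base, covariate: 1.0, "state": state,
                             "colony": colony, "time": 0})
        rows.append({"colony": colony, "slope": float((hi - lo) @ beta)})
    return pd.DataFrame(rows)


def predicted_curves(
    fit_result: FitResult,
    cls_name: str = "phi",
    covariate: str = "sardine",
    state: str = "B",
    n_grid: int = 50,
    pad: float = 0.0,
) -> pd.DataFrame:
    """Predicted real-scale curves over a standardized-covariate grid.

    One curve per colony with delta-method 95% CIs.  Points outside the
    observed covariate range are flagged ``extrapolated`` (``pad`` extends
    the grid beyond that range).  Requires a formula without a ``time``
    factor.
    """
    layout = fit_result.layout
    cl = layout.classes[cls_name]
    if "time" in " ".join(cl.colnames):
        raise ValueError("predicted curves need a time-free formula")
    if covariate not in cl.cells.columns:
        raise ValueError(f"{covariate!r} is not a covariate of the {cls_name} design")
    obs = cl.cells[covariate]
    lo, hi = float(obs.min()), float(obs.max())
    grid = np.linspace(lo - pad, hi + pad, n_grid)
    beta = fit_result.beta[layout.slices[cls_name]]
    cov = (
        fit_result.cov[layout.slices[cls_name], layout.slices[cls_name]]
        if fit_result.cov is not None
        else None
    )
    base = {c: 0.0 for c in ("sardine", "anchovy", "combined")}
    rows = []
    for colony in layout.colonies:
        for z in grid:
            x = _new_data_rows(layout, cls_name,
                               {**base, covariate: float(z), "state": state,
                                "colony": colony, "time": 0})
            eta = float(x @ beta)
            est = float(_expit(eta))
            if cov is None:
                se = lcl = ucl = np.nan
            else:
                se_eta = float(np.sqrt(max(x @ cov @ x, 0.0)))
                se = est * (1 - est) * se_eta
                lcl = float(_expit(eta - _Z95 * se_eta))
                ucl = float(_expit(eta + _Z95 * se_eta))
            rows.append({"param": cls_name, "state": state, "colony": colony,
                         covariate: float(z), "estimate": est, "se": se,
                         "lcl": lcl, "ucl": ucl,
                         "extrapolated": bool(z < lo or z > hi)})
    return pd.DataFrame(rows)
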