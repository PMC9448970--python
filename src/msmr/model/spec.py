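"""Model structures: formulas, fixed parameters and biomass covariates."""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

import pandas as pd

from ..defs import ALLOWED_MOVE, COLONIES, STATES

PARAM_CLASSES = ("phi", "p", "psi")
COVARIATE_NAMES = ("sardine", "anchovy", "combined")


def structural_zero_pairs() -> list[tuple[str, str]]:
    """Transitions fixed at zero by definition of the states."""
    return [
        (s, d)
        for s in STATES
        for d in STATES
        if d != s and d != ALLOWED_MOVE[s]
    ]


class FixedParam(NamedTuple):
    """One real parameter cell held at a known value (excluded from K).

    ``index`` is the survival/transition interval for phi/psi and the
    occasion for p.  ``colony=None`` applies to every colony.  For psi the
    value refers to the move probability out of ``state``.
    """

    cls: str
    state: str
    index: int
    colony: str | None
    value: float


def study_fixed_params(all_states_p_first: bool = False) -> list[FixedParam]:
    """The study's fixed-parameter set for the 2013-2020 design.

    Nonbreeder and prebreeder survival and transition are fixed to zero for
    the first interval (no such birds marked at the first occasion), as is
    their recapture at the second occasion; at Robben Island only, the
    prebreeder parameters stay fixed one step longer (no nonbreeders marked
    there in the second year).  ``all_states_p_first=True`` additionally
    fixes breeder recapture at the second occasion to zero (an alternative
    reading of the protocol).
    """
    fixed: list[FixedParam] = []
    for st in ("N", "P"):
        fixed.append(FixedParam("phi", st, 0, None, 0.0))
        fixed.append(FixedParam("psi", st, 0, None, 0.0))
        fixed.append(FixedParam("p", st, 1, None, 0.0))
    if all_states_p_first:
        fixed.append(FixedParam("p", "B", 1, None, 0.0))
    fixed += [
        FixedParam("phi", "P", 1, "RobbenIsland", 0.0),
        FixedParam("psi", "P", 1, "RobbenIsland", 0.0),
        FixedParam("p", "P", 2, "RobbenIsland", 0.0),
    ]
    return fixed


@dataclass
class BiomassSeries:
    """November spawner-biomass estimates by survey year (tonnes).

    ``table`` is indexed by survey year with columns ``sardine`` and
    ``anchovy``; ``combined`` is their raw sum.  Covariates enter the model
    z-scored over the supplied years.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"sardine", "anchovy"} - set(self.table.columns)
        if missing:
            raise ValueError(f"biomass table missing columns: {sorted(missing)}")
        if (self.table[["sardine", "anchovy"]] < 0).any().any():
            raise ValueError("biomass values must be non-negative")

    @classmethod
    def from_csv(cls, path) -> "BiomassSeries":
        df = pd.read_csv(path, comment="#")
        return cls(df.set_index("year")[["sardine", "anchovy"]])

    def standardized(self) -> pd.DataFrame:
        """Sardine, anchovy and combined biomass, z-scored over the series."""
        out = self.table[["sardine", "anchovy"]].astype(float).copy()
        out["combined"] = out["sardine"] + out["anchovy"]
        return (out - out.mean()) / out.std(ddof=0)

    def covariates_for_intervals(
        self, first_year: int, n_intervals: int
    ) -> pd.DataFrame:
        """Standardized covariate values aligned to survival intervals.

        Interval ``i`` (season ``first_year+i`` to ``first_year+i+1``)
        carries the November survey of year ``first_year+i`` — the survey
        at the start of the nonbreeding period.
        """
        std = self.standardized()
        rows = []
        for i in range(n_intervals):
            year = first_year + i
            if year not in std.index:
                raise ValueError(
                    f"biomass series lacks survey year {year} needed for "
                    f"survival interval {i} ({year}-{year + 1})"
                )
            rows.append(std.loc[year])
        out = pd.DataFrame(rows).reset_index(drop=True)
        out.index.name = "interval"
        return out


@dataclass(frozen=True)
class ModelSpec:
    """Symbolic structure of one candidate model.

    Formulas are additive/interactive term strings over the factors
    ``state``, ``time``, ``colony`` and the covariates ``sardine``,
    ``anchovy``, ``combined_biomass`` (``1`` or ``constant`` for an
    intercept-only structure), e.g. ``"state + sardine * colony"``.
    """

    phi: str = "1"
    p: str = "1"
    psi: str = "1"
    fixed: tuple[FixedParam, ...] = ()
    covariates: BiomassSeries | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        for fp in self.fixed:
            if fp.cls not in PARAM_CLASSES:
                raise ValueError(f"unknown parameter class {fp.cls!r}")
            if fp.state not in STATES:
                raise ValueError(f"unknown state {fp.state!r}")
            if fp.colony is not None and fp.colony not in COLONIES:
                raise ValueError(f"unknown colony {fp.colony!r}")
            if not 0.0 <= fp.value <= 1.0:
                raise ValueError(f"fixed value outside [0,1]: {fp}")

    @property
    def name(self) -> str:
        return self.label or f"phi({self.phi}) p({self.p}) psi({self.psi})"

    def with_formulas(self, **kwargs) -> "ModelSpec":
        return replace(self, label=None, **kwargs)


def attach_covariate(spec: ModelSpec, series: BiomassSeries) -> ModelSpec:
    """Return a spec carrying interval-aligned biomass covariates."""
    return replace(spec, covariates=series)
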