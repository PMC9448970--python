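"""Annual breeding-state classification and encounter-history construction.

Turns dated detection records (nest checks and ground-reader pings) into
per-individual annual observed-state codes and MARK-style encounter
histories.

Classification rules
--------------------
* An individual-season is coded **breeder (1)** if any nest record carries
  breeding evidence, or if the ground-reader rule passes: >=6 distinct
  in-season detection days whose overall span is 12-120 days (inclusive).
* Otherwise, any in-season detection codes the season **nonbreeder (2)**
  when the individual has previously been observed breeding, and
  **prebreeder (3)** when it has not.
* Seasons with no detections are coded **0** and handled by the detection
  probabilities of the model.

Encounter histories are written in a MARK ``.inp`` dialect::

    /* <individual_id> */ SSSSSSSS f_R f_S ;

one line per individual, where ``S`` is the observed state digit per
occasion and ``f_R``/``f_S`` are 1/0 frequency columns for the colony
groups in :data:`msmr.defs.COLONIES` order.
"""

from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .defs import COLONIES, FIRST_YEAR, N_OCCASIONS, season_window

RECORD_COLUMNS = ["individual_id", "colony", "date", "method", "breeding_evidence"]

__all__ = [
    "EncounterHistory",
    "HistorySet",
    "ground_reader_breeder_rule",
    "classify_annual_state",
    "apply_exclusion_filters",
    "build_encounter_histories",
    "read_detections",
    "write_detections",
]


@dataclass(frozen=True)
class EncounterHistory:
    """Observed-state codes for one individual over all occasions."""

    individual_id: str
    colony: str
    codes: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.colony not in COLONIES:
            raise ValueError(f"unknown colony {self.colony!r}")
        if not any(self.codes):
            raise ValueError(f"{self.individual_id}: history is all zeros")
        if any(c not in (0, 1, 2, 3) for c in self.codes):
            raise ValueError(f"{self.individual_id}: invalid code in {self.codes}")
        seen_b = False
        for c in self.codes:
            if c == 1:
                seen_b = True
            elif c == 3 and seen_b:
                raise ValueError(
                    f"{self.individual_id}: prebreeder code after first breeding"
                )

    @property
    def first_occasion(self) -> int:
        return next(i for i, c in enumerate(self.codes) if c != 0)

    @property
    def first_state(self) -> int:
        return self.codes[self.first_occasion]


class HistorySet:
    """An ordered collection of :class:`EncounterHistory`.

    Provides array views for the likelihood machinery and round-trippable
    CSV / ``.inp`` serialization.
    """

    def __init__(self, histories: Iterable[EncounterHistory]):
        self._items = list(histories)
        if not self._items:
            raise ValueError("empty history set")
        n = {len(h.codes) for h in self._items}
        if len(n) != 1:
            raise ValueError("histories of mixed length")
        self.n_occasions = n.pop()

    def __len__(self) -> int:
        return len(self._items)

    def __iter__(self):
        return iter(self._items)

    def __getitem__(self, i: int) -> EncounterHistory:
        return self._items[i]

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (codes[n, T], colony_index[n], first_occasion[n])."""
        codes = np.array([h.codes for h in self._items], dtype=np.int8)
        col = np.array([COLONIES.index(h.colony) for h in self._items], dtype=np.int64)
        first = np.array([h.first_occasion for h in self._items], dtype=np.int64)
        return codes, col, first

    def compressed(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Unique (codes, colony) rows with multiplicities, for fast fitting."""
        codes, col, first = self.as_arrays()
        key = np.concatenate([codes, col[:, None]], axis=1)
        uniq, counts = np.unique(key, axis=0, return_counts=True)
        ucodes = uniq[:, :-1].astype(np.int8)
        ucol = uniq[:, -1].astype(np.int64)
        ufirst = (ucodes != 0).argmax(axis=1)
        return ucodes, ucol, ufirst, counts

    def n_release_events(self) -> int:
        """Total number of live releases (detections before the last occasion).

        The MARK-style effective sample size used by the QAICc correction.
        """
        codes, _, _ = self.as_arrays()
        return int((codes[:, :-1] != 0).sum())

    # -- serialization ---------------------------------------------------

    def to_frame(self, first_year: int = FIRST_YEAR) -> pd.DataFrame:
        cols = [f"code_{first_year + t}" for t in range(self.n_occasions)]
        rows = [
            {"individual_id": h.individual_id, "colony": h.colony,
             **dict(zip(cols, h.codes))}
            for h in self._items
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path, first_year: int = FIRST_YEAR) -> None:
        self.to_frame(first_year).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "HistorySet":
        df = pd.read_csv(path, comment="#", dtype={"individual_id": str})
        code_cols = [c for c in df.columns if c.startswith("code_")]
        return cls(
            EncounterHistory(r["individual_id"], r["colony"],
                             tuple(int(r[c]) for c in code_cols))
            for _, r in df.iterrows()
        )

    def to_inp(self, path) -> None:
        with open(path, "w") as fh:
            for h in self._items:
                freq = " ".join("1" if h.colony == c else "0" for c in COLONIES)
                digits = "".join(str(c) for c in h.codes)
                fh.write(f"/* {h.individual_id} */ {digits} {freq} ;\n")

    @classmethod
    def from_inp(cls, path) -> "HistorySet":
        pat = re.compile(r"/\*\s*(?P<id>\S+)\s*\*/\s*(?P<codes>\d+)\s+(?P<freq>[\d\s]+);")
        out = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                m = pat.match(line)
                if m is None:
                    raise ValueError(f"unparseable .inp line: {line!r}")
                freqs = [int(x) for x in m.group("freq").split()]
                if len(freqs) != len(COLONIES) or sum(freqs) != 1:
                    raise ValueError(f"bad frequency columns in line: {line!r}")
                colony = COLONIES[freqs.index(1)]
                codes = tuple(int(ch) for ch in m.group("codes"))
                out.append(EncounterHistory(m.group("id"), colony, codes))
        return cls(out)


# ---------------------------------------------------------------------------
# classification rules
# ---------------------------------------------------------------------------

def ground_reader_breeder_rule(
    ping_dates: Iterable[dt.date],
    season_year: int | None = None,
    *,
    min_days: int = 6,
    min_span: int = 12,
    max_span: int = 120,
) -> bool:
    """Decide breeder status from ground-reader detections alone.

    True iff at least ``min_days`` distinct in-season detection days exist
    and their overall span (last - first, in days) lies in
    ``[min_span, max_span]`` inclusive.  Dates outside the March-October
    window of ``season_year`` are discarded first (pass ``season_year=None``
    to skip windowing).  Empty input returns False.
    """
    days = {d.date() if isinstance(d, dt.datetime) else d for d in ping_dates}
    if season_year is not None:
        lo, hi = season_window(season_year)
        days = {d for d in days if lo <= d <= hi}
    if len(days) < min_days:
        return False
    span = (max(days) - min(days)).days
    return min_span <= span <= max_span


def classify_annual_state(
    records: pd.DataFrame,
    prior_history: bool,
    season_year: int | None = None,
    **rule_kwargs,
) -> int:
    """Observed state code for one individual-season record block.

    Returns 1 (breeder) on nest evidence or a passing ground-reader rule;
    otherwise 2 (nonbreeder) if anything was recorded and the individual has
    bred before, 3 (prebreeder) if it has not, and 0 with no records.
    """
    if len(records) == 0:
        return 0
    if records["colony"].nunique() > 1:
        raise ValueError(
            "records for one individual-season span multiple colonies; "
            "apply exclusion filters first"
        )
    nest = records[records["method"] == "nest"]
    if nest["breeding_evidence"].astype(bool).any():
        return 1
    reader_dates = pd.to_datetime(
        records.loc[records["method"] == "reader", "date"]
    ).dt.date
    if ground_reader_breeder_rule(reader_dates, season_year, **rule_kwargs):
        return 1
    return 2 if prior_history else 3


def _season_of(dates: pd.Series) -> pd.Series:
    return pd.to_datetime(dates).dt.year


def _is_breeder_block(block: pd.DataFrame, year: int) -> bool:
    nest = block[block["method"] == "nest"]
    if nest["breeding_evidence"].astype(bool).any():
        return True
    reader_dates = pd.to_datetime(
        block.loc[block["method"] == "reader", "date"]
    ).dt.date
    return ground_reader_breeder_rule(reader_dates, year)


def apply_exclusion_filters(
    records: pd.DataFrame,
    double_marked_ids: Iterable[str] = (),
    multi_colony: str = "remove-breeding",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove flagged double-marked individuals and multi-colony breeders.

    ``multi_colony='remove-breeding'`` removes individuals observed breeding
    at more than one colony (the study rule); ``'remove-any'`` removes any
    individual with records at more than one colony.  Returns the filtered
    records and an exclusion report (individual_id, reason).
    """
    if multi_colony not in ("remove-breeding", "remove-any"):
        raise ValueError(f"unknown multi_colony policy {multi_colony!r}")
    records = records.copy()
    report_rows = []

    double_marked = set(double_marked_ids)
    present = sorted(double_marked & set(records["individual_id"]))
    for i in present:
        report_rows.append({"individual_id": i, "reason": "double-marked"})
    records = records[~records["individual_id"].isin(double_marked)]

    years = _season_of(records["date"])
    if multi_colony == "remove-any":
        ncol = records.groupby("individual_id")["colony"].nunique()
        bad = sorted(ncol[ncol > 1].index)
    else:
        breeding_colonies: dict[str, set] = {}
        for (ind, colony, year), block in records.groupby(
            [records["individual_id"], records["colony"], years]
        ):
            if _is_breeder_block(block, int(year)):
                breeding_colonies.setdefault(ind, set()).add(colony)
        bad = sorted(i for i, cs in breeding_colonies.items() if len(cs) > 1)
    for i in bad:
        report_rows.append({"individual_id": i, "reason": "multi-colony breeder"})
    records = records[~records["individual_id"].isin(bad)]

    report = pd.DataFrame(report_rows, columns=["individual_id", "reason"])
    return records.reset_index(drop=True), report


def build_encounter_histories(
    records: pd.DataFrame,
    n_occasions: int = N_OCCASIONS,
    first_year: int = FIRST_YEAR,
    impute_unobserved: bool = False,
    rule_kwargs: dict | None = None,
) -> tuple[HistorySet, pd.DataFrame]:
    """Build one encounter history per individual plus marking tallies.

    The individual's colony is taken from its earliest record (multi-colony
    breeders must already be filtered out).  ``impute_unobserved=True``
    codes unobserved-but-later-reobserved seasons as nonbreeder/prebreeder
    instead of 0 (an alternative reading of the source protocol; default
    keeps zeros so detection probabilities stay estimable).

    Returns the histories and a tally of newly marked individuals per
    season x colony x first observed state.
    """
    records = records.copy()
    records["date"] = pd.to_datetime(records["date"])
    years = records["date"].dt.year
    bad = records[(years < first_year) | (years >= first_year + n_occasions)]
    if len(bad):
        ids = ", ".join(sorted(bad["individual_id"].unique())[:5])
        raise ValueError(
            f"records outside the {first_year}-{first_year + n_occasions - 1} "
            f"study seasons for individual(s): {ids}"
        )
    records["season"] = years - first_year

    histories = []
    for ind, block in records.sort_values("date").groupby("individual_id", sort=True):
        colony = block["colony"].iloc[0]
        codes = [0] * n_occasions
        prior = False
        for t, season_block in block.groupby("season"):
            code = classify_annual_state(season_block, prior, int(first_year + t),
                                         **(rule_kwargs or {}))
            codes[int(t)] = code
            if code == 1:
                prior = True
        if impute_unobserved:
            seen = [t for t in range(n_occasions) if codes[t] != 0]
            bred_by = np.cumsum([c == 1 for c in codes])
            for t in range(seen[0] + 1, seen[-1]):
                if codes[t] == 0:
                    codes[t] = 2 if bred_by[t - 1] > 0 else 3
        histories.append(EncounterHistory(str(ind), colony, tuple(codes)))

    hset = HistorySet(histories)
    tally = (
        pd.DataFrame(
            {
                "season": first_year + h.first_occasion,
                "colony": h.colony,
                "state": "BNP"[h.first_state - 1],
            }
            for h in hset
        )
        .value_counts()
        .rename("n_marked")
        .reset_index()
        .sort_values(["season", "colony", "state"])
        .reset_index(drop=True)
    )
    return hset, tally


# ---------------------------------------------------------------------------
# detection-record IO
# ---------------------------------------------------------------------------

def read_detections(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", dtype={"individual_id": str})
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"detection CSV missing columns: {sorted(missing)}")
    df["date"] = pd.to_datetime(df["date"])
    df["breeding_evidence"] = df["breeding_evidence"].astype(int)
    if ((df["method"] != "nest") & (df["breeding_evidence"] == 1)).any():
        raise ValueError("breeding_evidence=1 is only valid for method='nest'")
    return df[RECORD_COLUMNS]


def write_detections(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        out = df.copy()
        out["date"] = pd.to_datetime(out["date"]).dt.date.astype(str)
        out.to_csv(fh, index=False)
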