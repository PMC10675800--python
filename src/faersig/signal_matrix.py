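"""The drugs x adverse-events lnROR matrix and its extraction filters.

The screening stage reduces the database to a grid of lnROR values, one row
per canonical drug and one column per MedDRA preferred term, together with the
total report count of each event and the unweighted mean lnROR over drugs.
Events are then filtered the way a signal study narrows its scope: keep events
reported more than ``min_event_reports`` times across the whole database
(strictly more), then keep those whose mean lnROR over the drug panel is
strictly positive, i.e. events over-reported for the panel as a whole.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["SignalMatrix", "FilterConfig", "assemble_matrix", "mean_ror_column",
           "filter_events", "round_half_away", "write_summary_tsv",
           "write_matrix_tsv", "read_matrix_tsv"]


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round with halves away from zero (so 0.125 -> 0.13, -0.125 -> -0.13)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SignalMatrix:
    """lnROR grid plus per-event totals and mean lnROR."""

    drugs: tuple[str, ...]
    events: tuple[str, ...]
    lnror: np.ndarray           # shape (len(drugs), len(events))
    event_totals: np.ndarray    # reports carrying the event, whole database

    def __post_init__(self):
        lnror = np.asarray(self.lnror, dtype=float)
        totals = np.asarray(self.event_totals, dtype=np.int64)
        object.__setattr__(self, "lnror", lnror)
        object.__setattr__(self, "event_totals", totals)
        if lnror.shape != (len(self.drugs), len(self.events)):
            raise ValueError(f"lnror grid shape {lnror.shape} does not match "
                             f"({len(self.drugs)}, {len(self.events)})")
        if totals.shape != (len(self.events),):
            raise ValueError("event_totals length does not match events")
        if not np.all(np.isfinite(lnror)):
            bad = np.argwhere(~np.isfinite(lnror))[0]
            raise ValueError(f"non-finite lnROR at drug {self.drugs[bad[0]]!r}, "
                             f"event {self.events[bad[1]]!r}")

    @property
    def mean_lnror(self) -> np.ndarray:
        """Unweighted arithmetic mean of each column over the drug panel."""
        return self.lnror.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.lnror, index=list(self.drugs), columns=list(self.events))


@dataclass(frozen=True)
class FilterConfig:
    """Event-extraction thresholds.

    ``min_event_reports`` keeps events with strictly more database reports than
    the threshold (the screening default mirrors a >100,000-report cut on a
    full-scale database); ``require_positive_mean`` keeps events whose mean
    lnROR over the drug panel is strictly positive; ``top_n`` optionally caps
    the retained events by report count (descending, ties broken
    lexicographically by preferred term).
    """

    min_event_reports: int = 100_000
    require_positive_mean: bool = True
    top_n: int | None = None

    def __post_init__(self):
        if self.min_event_reports < 0:
            raise ValueError("min_event_reports must be >= 0")
        if self.top_n is not None and self.top_n < 1:
            raise ValueError("top_n must be >= 1")


def assemble_matrix(signals: pd.DataFrame, drugs: Sequence[str],
                    events: Sequence[str]) -> SignalMatrix:
    """Build the lnROR grid from a :func:`faersig.disproportionality.signal_table`
    frame; every requested (drug, event) pair must be present."""
    drugs, events = list(drugs), list(events)
    indexed = signals.set_index(["drug", "pt"])
    lnror = np.empty((len(drugs), len(events)))
    totals = np.empty(len(events), dtype=np.int64)
    for j, ev in enumerate(events):
        for i, dr in enumerate(drugs):
            try:
                row = indexed.loc[(dr, ev)]
            except KeyError:
                raise KeyError(f"no signal result for pair ({dr!r}, {ev!r})") from None
            lnror[i, j] = row["lnror"]
        totals[j] = indexed.loc[(drugs[0], ev)]["event_total"]
    return SignalMatrix(drugs=tuple(drugs), events=tuple(events),
                        lnror=lnror, event_totals=totals)


def mean_ror_column(matrix: SignalMatrix) -> pd.DataFrame:
    """Per-event summary: total reports, mean lnROR and its exponential.

    ``mean_lnror_2dp`` / ``ror_2dp`` are the display values rounded half away
    from zero to 2 decimals; ``ror`` is exp(mean lnROR) unrounded.
    """
    mean = matrix.mean_lnror
    ror = np.exp(mean)
    return pd.DataFrame({
        "event": list(matrix.events),
        "n_reports": matrix.event_totals,
        "mean_lnror": mean,
        "ror": ror,
        "mean_lnror_2dp": [round_half_away(x, 2) for x in mean],
        "ror_2dp": [round_half_away(x, 2) for x in ror],
    })


def filter_events(matrix: SignalMatrix, config: FilterConfig) -> SignalMatrix:
    """Apply the event-extraction filters, preserving column order."""
    keep = matrix.event_totals > config.min_event_reports
    if config.require_positive_mean:
        keep &= matrix.mean_lnror > 0
    if config.top_n is not None and keep.sum() > config.top_n:
        cand = [(int(-matrix.event_totals[j]), matrix.events[j], j)
                for j in np.flatnonzero(keep)]
        chosen = {j for _, _, j in sorted(cand)[:config.top_n]}
        keep = np.array([j in chosen for j in range(len(matrix.events))])
    if not keep.any():
        raise ValueError("event filters removed every event; clustering needs "
                         "at least 2 event columns — relax min_event_reports "
                         "or require_positive_mean")
    idx = np.flatnonzero(keep)
    return SignalMatrix(
        drugs=matrix.drugs,
        events=tuple(matrix.events[j] for j in idx),
        lnror=matrix.lnror[:, idx],
        event_totals=matrix.event_totals[idx],
    )


# -- text exports -----------------------------------------------------------

def write_summary_tsv(matrix: SignalMatrix, path: str | Path) -> None:
    """Per-event summary table (event, reports, mean lnROR, ROR), sorted by
    report count descending."""
    df = mean_ror_column(matrix).sort_values(
        ["n_reports", "event"], ascending=[False, True], kind="mergesort")
    out = pd.DataFrame({
        "event": df["event"],
        "n_reports": df["n_reports"],
        "mean_lnror": df["mean_lnror_2dp"].map(lambda v: f"{v:.2f}"),
        "ror": df["ror_2dp"].map(lambda v: f"{v:.2f}"),
    })
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_matrix_tsv(matrix: SignalMatrix, path: str | Path) -> None:
    """Full-precision lnROR grid, drugs as rows and events as columns."""
    df = matrix.to_frame()
    df.index.name = "drug"
    df.to_csv(path, sep="\t", float_format="%.12g", lineterminator="\n")


def read_matrix_tsv(path: str | Path, event_totals: np.ndarray | None = None) -> SignalMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    totals = event_totals if event_totals is not None else np.zeros(df.shape[1], dtype=np.int64)
    return SignalMatrix(drugs=tuple(df.index), events=tuple(df.columns),
                        lnror=df.to_numpy(), event_totals=totals)
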