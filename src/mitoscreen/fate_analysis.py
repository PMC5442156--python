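"""Cell-fate classification from timed event sequences.

A phenotypic cell first arrests in prometaphase (time in mitosis exceeding
a threshold, default 2 h versus the ~1 h of a normal mitosis) and then
either dies in mitosis, exits mitosis without dividing, or fails
cytokinesis; alternatively it dies in interphase without any prior arrest
(direct apoptosis, typically early, 12-24 h post-transfection).  Cells
whose mitoses all complete normally are labelled ``normal``; anything else
(e.g. a censored mitosis at the end of the movie) is ``other``.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .synthetic_data import CellEventLog, MITOSIS_RESOLUTIONS

PHENOTYPIC_LABELS = ("mitotic_death", "mitotic_exit", "cytokinesis_failure", "direct_apoptosis")
ALL_LABELS = PHENOTYPIC_LABELS + ("normal", "other")


@dataclass(frozen=True)
class FateThresholds:
    """Durations separating a normal mitosis from a prometaphase arrest."""

    normal_mitosis_h: float = 1.0
    arrest_h: float = 2.0
    early_apoptosis_window: tuple[float, float] = (12.0, 24.0)

    def __post_init__(self) -> None:
        if self.arrest_h <= self.normal_mitosis_h:
            raise ValueError("arrest threshold must exceed the normal mitosis duration")


DEFAULT_THRESHOLDS = FateThresholds()


def classify_fate(
    seq: pd.DataFrame,
    thresholds: FateThresholds = DEFAULT_THRESHOLDS,
    t_end: float = 72.0,
) -> str:
    """Label one cell's event sequence (columns time_h, event).

    The first arrested mitosis (duration > arrest threshold) determines the
    label via its resolution; interphase death with no prior arrest is
    direct apoptosis; mitoses completing within the normal duration and
    ending in division — or an entirely uneventful history — are normal.
    """
    seq = seq.sort_values("time_h", kind="stable")
    kinds = list(seq["event"])
    if not kinds or kinds[0] != "birth":
        raise ValueError("sequence must start with a birth event")
    entry_t: float | None = None
    had_division = False
    for _, e in seq.iloc[1:].iterrows():
        kind, t = e["event"], float(e["time_h"])
        if kind == "mitosis_entry":
            if entry_t is not None:
                raise ValueError("nested mitosis_entry")
            entry_t = t
        elif kind in MITOSIS_RESOLUTIONS:
            if entry_t is None:
                raise ValueError(f"{kind} without mitosis_entry")
            duration = t - entry_t
            entry_t = None
            if duration > thresholds.arrest_h:
                # first arrest decides the fate; arrest ending in division is atypical
                return kind if kind != "division" else "other"
            if kind == "division":
                had_division = True
            elif kind == "mitotic_death":
                return "other"  # death after a short mitosis: not the arrest phenotype
            elif kind == "cytokinesis_failure":
                return "cytokinesis_failure"
        elif kind == "interphase_death":
            return "direct_apoptosis"
        else:
            raise ValueError(f"unexpected event {kind!r}")
    if entry_t is not None:
        return "other"  # mitosis censored by the end of the movie
    return "normal"


def classify_log(
    log: CellEventLog,
    thresholds: FateThresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Classify every cell in a log; returns columns cell_id, fate."""
    rows = [(cid, classify_fate(seq, thresholds, log.t_end)) for cid, seq in log.sequences()]
    return pd.DataFrame(rows, columns=["cell_id", "fate"])


def fate_profile(labels: Iterable[str]) -> pd.Series:
    """Fractions of each phenotypic fate among phenotypic cells.

    Non-phenotypic labels (normal, other) are excluded from the
    denominator; raises if no phenotypic cell is present.
    """
    counts = pd.Series(list(labels)).value_counts()
    phen = counts.reindex(PHENOTYPIC_LABELS, fill_value=0)
    total = int(phen.sum())
    if total == 0:
        raise ValueError("no phenotypic cells to profile")
    return phen / total


def arrest_durations(log: CellEventLog, thresholds: FateThresholds = DEFAULT_THRESHOLDS) -> np.ndarray:
    """Durations (h) of all arrested mitoses (> arrest threshold) in a log."""
    durations = []
    for _, seq in log.sequences():
        seq = seq.sort_values("time_h", kind="stable")
        entry = None
        for _, e in seq.iterrows():
            if e["event"] == "mitosis_entry":
                entry = float(e["time_h"])
            elif e["event"] in MITOSIS_RESOLUTIONS and entry is not None:
                d = float(e["time_h"]) - entry
                if d > thresholds.arrest_h:
                    durations.append(d)
                entry = None
    return np.asarray(durations)


def time_course(
    log: CellEventLog,
    timepoints: Sequence[float] = (24.0, 48.0, 72.0),
) -> pd.DataFrame:
    """Mitotic and apoptotic fractions at the given times.

    At each t, the mitotic fraction is the share of alive cells currently
    between mitosis_entry and its resolution; the apoptotic fraction is the
    cumulative deaths (mitotic + interphase) over the initial cell number.
    """
    for t in timepoints:
        if not (log.t_start - 1e-9 <= t <= log.t_end + 1e-9):
            raise ValueError(f"timepoint {t} h outside the movie range")
    ev = log.events
    n_initial = log.n_initial
    if n_initial == 0:
        raise ValueError("log has no founder cells")
    births = ev[ev["event"] == "birth"].set_index("cell_id")["time_h"]
    deaths = ev[ev["event"].isin(["mitotic_death", "interphase_death"])] \
        .set_index("cell_id")["time_h"]
    divisions = ev[ev["event"] == "division"].set_index("cell_id")["time_h"]
    entries = ev[ev["event"] == "mitosis_entry"][["cell_id", "time_h"]]
    resolutions = ev[ev["event"].isin(MITOSIS_RESOLUTIONS)][["cell_id", "time_h"]]
    rows = []
    for t in timepoints:
        born = births[births <= t + 1e-9]
        gone = set(deaths[deaths <= t + 1e-9].index) | set(divisions[divisions <= t + 1e-9].index)
        alive = set(born.index) - gone
        in_mitosis = 0
        for cid in alive:
            ent = entries.loc[entries["cell_id"] == cid, "time_h"]
            ent = ent[ent <= t + 1e-9]
            if ent.empty:
                continue
            last_entry = float(ent.max())
            res = resolutions.loc[resolutions["cell_id"] == cid, "time_h"]
            if res[(res >= last_entry) & (res <= t + 1e-9)].empty:
                in_mitosis += 1
        n_dead = int((deaths <= t + 1e-9).sum())
        rows.append({
            "time_h": float(t),
            "mitotic_fraction": in_mitosis / len(alive) if alive else 0.0,
            "apoptotic_fraction": n_dead / n_initial,
            "n_alive": len(alive),
        })
    return pd.DataFrame(rows)
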