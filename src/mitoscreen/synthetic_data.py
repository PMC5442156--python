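"""Generative models for a time-lapse RNAi screen.

This module builds every synthetic input the downstream analysis consumes:

* an siRNA library (hundreds of lncRNA targets, up to five siRNAs each),
* multiwell plate layouts carrying duplicated positive viability controls
  (COPB2, KIF11, PLK1), non-targeting negative controls (NC A/B/D), empty
  wells and optional mitotic-defect controls,
* per-well cell event logs from a discrete-time branching model of dividing,
  arresting and dying cells (imaged every 30 min from 4 h to 72 h
  post-transfection),
* rendered two-channel fluorescence movies (H2B nuclei in red, tubulin in
  green) with ground truth attached via the event log,
* ordinal manual phenotype scores (1 = normal .. 5 = strong), and
* peptide-intensity tables emulating an RNA-pulldown proteomics experiment.

All randomness flows from one integer seed; per-well / per-cell streams are
derived with ``numpy.random.SeedSequence`` so outputs are bit-reproducible.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# vocabulary

EVENT_TYPES = (
    "birth",
    "mitosis_entry",
    "division",
    "mitotic_death",
    "mitotic_exit",
    "cytokinesis_failure",
    "interphase_death",
)
#: events that terminate a mitosis begun by ``mitosis_entry``
MITOSIS_RESOLUTIONS = ("division", "mitotic_death", "mitotic_exit", "cytokinesis_failure")
#: events after which a cell no longer exists as a single tracked object
TERMINAL_EVENTS = ("division", "mitotic_death", "interphase_death")

POSITIVE_CONTROLS = ("COPB2", "KIF11", "PLK1")
NEGATIVE_CONTROLS = ("NC_A", "NC_B", "NC_D")
MITOTIC_CONTROLS = ("MITOTIC_CTRL_CENPA", "MITOTIC_CTRL_ZW10", "MITOTIC_CTRL_HJURP")
EMPTY = "EMPTY"
CONTROL_LABELS = frozenset(POSITIVE_CONTROLS + NEGATIVE_CONTROLS + MITOTIC_CONTROLS + (EMPTY,))


def is_sample(content: str) -> bool:
    """True if a well's content is a library siRNA rather than a control."""
    return content not in CONTROL_LABELS


def _rng(seed: int, *stream: int) -> np.random.Generator:
    """Derive an independent generator from (seed, stream ids) stably."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, stream)]))


# ---------------------------------------------------------------------------
# library and plates


@dataclass(frozen=True)
class LibraryDesign:
    """An siRNA library: target ids and 1-5 siRNA ids per target."""

    targets: tuple[str, ...]
    sirnas: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for t in self.targets:
            ids = self.sirnas[t]
            if not 1 <= len(ids) <= 5:
                raise ValueError(f"target {t} has {len(ids)} siRNAs, expected 1-5")
            for s in ids:
                if s in seen:
                    raise ValueError(f"duplicate siRNA id {s}")
                seen.add(s)

    @property
    def n_targets(self) -> int:
        return len(self.targets)

    @property
    def total_sirnas(self) -> int:
        return sum(len(self.sirnas[t]) for t in self.targets)

    def all_sirnas(self) -> list[str]:
        return [s for t in self.targets for s in self.sirnas[t]]

    def target_of(self) -> dict[str, str]:
        return {s: t for t in self.targets for s in self.sirnas[t]}


def make_library(
    n_targets: int = 638,
    max_sirnas_per_target: int = 5,
    seed: int = 0,
    policy: str = "weighted",
) -> LibraryDesign:
    """Build a synthetic siRNA library.

    ``policy="weighted"`` draws the per-target siRNA count from
    {max-2, max-1, max} with weights (0.01, 0.04, 0.95): most targets carry
    the full complement, a few lost one or two designs, which with the
    defaults (638 targets, up to 5 siRNAs) yields a library of >3100 siRNAs.
    ``policy="max"`` gives every target exactly ``max_sirnas_per_target``.
    """
    if n_targets < 0:
        raise ValueError("n_targets must be >= 0")
    if not 1 <= max_sirnas_per_target <= 5:
        raise ValueError("max_sirnas_per_target must be in 1..5")
    rng = _rng(seed, 101)
    targets = tuple(f"LNC{i:04d}" for i in range(n_targets))
    if policy == "max":
        counts = np.full(n_targets, max_sirnas_per_target)
    elif policy == "weighted":
        values = np.arange(max(1, max_sirnas_per_target - 2), max_sirnas_per_target + 1)
        weights = np.array([0.01, 0.04, 0.95][-len(values):], dtype=float)
        weights /= weights.sum()
        counts = rng.choice(values, size=n_targets, p=weights)
    else:
        raise ValueError(f"unknown policy {policy!r}")
    sirnas = {t: tuple(f"{t}_s{j + 1}" for j in range(int(c))) for t, c in zip(targets, counts)}
    return LibraryDesign(targets=targets, sirnas=sirnas)


@dataclass(frozen=True)
class PlateLayout:
    """One multiwell plate: well address (e.g. ``"B07"``) -> content.

    Content is either a control label (see :data:`CONTROL_LABELS`) or a
    library siRNA id for a sample well.
    """

    plate: str
    rows: int
    cols: int
    wells: Mapping[str, str]

    def contents(self) -> pd.DataFrame:
        rows = [
            {"plate": self.plate, "well": w, "content": c,
             "is_sample": is_sample(c)}
            for w, c in sorted(self.wells.items())
        ]
        return pd.DataFrame(rows)

    def sample_wells(self) -> list[tuple[str, str]]:
        return [(w, c) for w, c in sorted(self.wells.items()) if is_sample(c)]


def well_address(row: int, col: int) -> str:
    return f"{chr(ord('A') + row)}{col + 1:02d}"


def make_plates(
    library: LibraryDesign,
    rows: int = 16,
    cols: int = 24,
    seed: int = 0,
    include_mitotic_controls: bool = True,
) -> list[PlateLayout]:
    """Distribute the library over plates with the fixed control complement.

    Every plate receives 2 wells of each positive viability control
    (COPB2/KIF11/PLK1), 2 of each non-targeting negative control (NC A/B/D),
    at least one empty well and, optionally, 2 wells of each mitotic-defect
    control.  Each library siRNA appears exactly once across the plate set;
    leftover wells on the last plate are filled with EMPTY.
    """
    if library.total_sirnas == 0:
        raise ValueError("cannot lay out an empty library")
    controls: list[str] = []
    for label in POSITIVE_CONTROLS + NEGATIVE_CONTROLS:
        controls += [label, label]
    if include_mitotic_controls:
        for label in MITOTIC_CONTROLS:
            controls += [label, label]
    n_fixed = len(controls) + 1  # + one guaranteed empty well
    capacity = rows * cols - n_fixed
    if capacity < 1:
        raise ValueError(
            f"{rows}x{cols} format cannot hold {n_fixed} control wells plus a sample well"
        )
    sirnas = library.all_sirnas()
    n_plates = math.ceil(len(sirnas) / capacity)
    addresses = [well_address(r, c) for r in range(rows) for c in range(cols)]
    plates: list[PlateLayout] = []
    for p in range(n_plates):
        chunk = sirnas[p * capacity:(p + 1) * capacity]
        content = controls + [EMPTY] + chunk
        content += [EMPTY] * (rows * cols - len(content))
        rng = _rng(seed, 202, p)
        shuffled = list(addresses)
        rng.shuffle(shuffled)
        plates.append(
            PlateLayout(plate=f"P{p + 1:02d}", rows=rows, cols=cols,
                        wells=dict(zip(shuffled, content)))
        )
    return plates


# ---------------------------------------------------------------------------
# phenotypes


@dataclass(frozen=True)
class WellPhenotype:
    """Latent knockdown phenotype of a well.

    ``effect`` is a unitless severity in [0, 1].  For the ``viability``
    class it multiplies the division rate by (1 - effect); for
    ``mitotic_arrest`` it is the probability that a mitosis arrests in
    prometaphase instead of completing normally.  The phenotype only acts
    from ``delay_h`` hours post-transfection (siRNA penetration delay).
    """

    effect: float = 0.0
    klass: str = "none"
    delay_h: float = 12.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.effect <= 1.0:
            raise ValueError("effect must lie in [0, 1]")
        if self.klass not in ("viability", "mitotic_arrest", "nuclear_morphology", "none"):
            raise ValueError(f"unknown phenotype class {self.klass!r}")

    def rate_multiplier(self, t: float) -> float:
        if self.klass == "viability" and t >= self.delay_h:
            return 1.0 - self.effect
        return 1.0

    def arrest_prob(self, t: float) -> float:
        if self.klass == "mitotic_arrest" and t >= self.delay_h:
            return self.effect
        return 0.0


NULL_PHENOTYPE = WellPhenotype()


def control_phenotypes(
    positive_effect: float = 0.85,
    mitotic_effect: float = 0.15,
    delay_h: float = 12.0,
) -> dict[str, WellPhenotype]:
    """Default phenotypes of the control wells.

    Positive viability controls knock the division rate down to
    ``1 - positive_effect`` (default multiplier 0.15) after the penetration
    delay; mitotic-defect controls induce a mild arrest probability (their
    MitosisCount footprint is deliberately subtle); negative controls and
    empty wells behave like untreated cells.
    """
    phen: dict[str, WellPhenotype] = {}
    for label in POSITIVE_CONTROLS:
        phen[label] = WellPhenotype(positive_effect, "viability", delay_h)
    for label in NEGATIVE_CONTROLS:
        phen[label] = NULL_PHENOTYPE
    for label in MITOTIC_CONTROLS:
        phen[label] = WellPhenotype(mitotic_effect, "mitotic_arrest", delay_h)
    phen[EMPTY] = NULL_PHENOTYPE
    return phen


@dataclass(frozen=True)
class FateMixture:
    """Mixture over terminal fates of phenotypic cells.

    The first three components are fates of cells that first arrest in
    prometaphase; ``direct_apoptosis`` is interphase death without a prior
    arrest.  Defaults follow the observed fate split of arrested knockdown
    cells: 42% mitotic death, 28% mitotic exit, 5% cytokinesis failure and
    the remaining quarter direct apoptosis.
    """

    mitotic_death: float = 0.42
    mitotic_exit: float = 0.28
    cytokinesis_failure: float = 0.05
    direct_apoptosis: float = 0.25

    def __post_init__(self) -> None:
        p = self.as_array()
        if (p < 0).any():
            raise ValueError("mixture probabilities must be non-negative")
        if abs(p.sum() - 1.0) > 1e-6:
            raise ValueError(f"mixture probabilities sum to {p.sum():.6f}, expected 1")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.mitotic_death, self.mitotic_exit, self.cytokinesis_failure, self.direct_apoptosis]
        )

    def arrest_fates(self) -> np.ndarray:
        """Conditional distribution over arrest resolutions (first three fates)."""
        p = self.as_array()[:3]
        if p.sum() <= 0:
            raise ValueError("no probability mass on arrest fates")
        return p / p.sum()


DEFAULT_FATE_MIXTURE = FateMixture()


# ---------------------------------------------------------------------------
# movie geometry


@dataclass(frozen=True)
class MovieSpec:
    """Geometry and acquisition parameters of a synthetic movie.

    Defaults: 256x256 px at 1 um/px, one frame every 0.5 h from 4 h to 72 h
    post-transfection (137 frames), 8 um nuclei.
    """

    frame_px: int = 256
    pixel_um: float = 1.0
    interval_h: float = 0.5
    t_start: float = 4.0
    t_end: float = 72.0
    nucleus_radius_um: float = 8.0
    psf_sigma_px: float = 2.0
    background: float = 100.0
    noise_sd: float = 5.0
    nucleus_amplitude: float = 600.0
    brownian_sd_um: float = 2.0

    def __post_init__(self) -> None:
        if self.interval_h <= 0:
            raise ValueError("frame interval must be positive")
        if self.t_end <= self.t_start:
            raise ValueError("movie must end after it starts")

    @property
    def n_frames(self) -> int:
        return int(math.floor((self.t_end - self.t_start) / self.interval_h)) + 1

    def frame_times(self) -> np.ndarray:
        return self.t_start + self.interval_h * np.arange(self.n_frames)

    @property
    def size_um(self) -> float:
        return self.frame_px * self.pixel_um


DEFAULT_MOVIE_SPEC = MovieSpec()


# ---------------------------------------------------------------------------
# event logs

_EVENT_COLUMNS = ["cell_id", "parent_id", "time_h", "event", "x_um", "y_um"]


@dataclass
class CellEventLog:
    """Timed per-cell events of one well.

    ``events`` has columns cell_id, parent_id (-1 for founders), time_h,
    event, x_um, y_um.  Per cell the grammar is::

        birth -> (mitosis_entry -> division | mitotic_death | mitotic_exit
                  | cytokinesis_failure)* -> optional interphase_death

    where ``division`` and both death events are terminal for the cell, and
    a division spawns exactly two daughter births at the division time.
    """

    events: pd.DataFrame
    t_start: float = 4.0
    t_end: float = 72.0
    #: optional per-frame positions (cell_id, time_h, x_um, y_um); attached by
    #: simulate_well so rendering and ground truth share one trajectory
    tracks: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.events = pd.DataFrame(self.events, columns=_EVENT_COLUMNS)
        self.events = self.events.sort_values(["cell_id", "time_h"], kind="stable").reset_index(drop=True)

    @property
    def n_cells(self) -> int:
        return self.events["cell_id"].nunique()

    @property
    def n_initial(self) -> int:
        births = self.events[self.events["event"] == "birth"]
        return int((births["parent_id"] < 0).sum())

    @property
    def n_divisions(self) -> int:
        return int((self.events["event"] == "division").sum())

    def counts(self) -> pd.Series:
        return self.events["event"].value_counts()

    def sequences(self) -> Iterator[tuple[int, pd.DataFrame]]:
        """Yield (cell_id, events of that cell sorted by time)."""
        yield from self.events.groupby("cell_id", sort=True)

    def validate(self) -> None:
        """Check the event grammar and division conservation; raise on violation."""
        ev = self.events
        if not ev["event"].isin(EVENT_TYPES).all():
            bad = set(ev["event"]) - set(EVENT_TYPES)
            raise ValueError(f"unknown event types {bad}")
        if len(ev) and ((ev["time_h"] < self.t_start - 1e-9) | (ev["time_h"] > self.t_end + 1e-9)).any():
            raise ValueError("event outside the movie time range")
        for cid, seq in self.sequences():
            kinds = list(seq["event"])
            if kinds[0] != "birth" or kinds.count("birth") != 1:
                raise ValueError(f"cell {cid}: must start with exactly one birth")
            state = "interphase"
            for kind in kinds[1:]:
                if state == "dead":
                    raise ValueError(f"cell {cid}: event {kind} after terminal event")
                if state == "interphase":
                    if kind == "mitosis_entry":
                        state = "mitotic"
                    elif kind == "interphase_death":
                        state = "dead"
                    else:
                        raise ValueError(f"cell {cid}: {kind} not allowed in interphase")
                else:  # mitotic
                    if kind not in MITOSIS_RESOLUTIONS:
                        raise ValueError(f"cell {cid}: {kind} cannot resolve a mitosis")
                    state = "dead" if kind in ("division", "mitotic_death") else "interphase"
        n_births = int((ev["event"] == "birth").sum())
        if n_births != 2 * self.n_divisions + self.n_initial:
            raise ValueError("division conservation violated: births != 2*divisions + founders")
        # every division emits exactly two daughter births at that time
        divisions = ev[ev["event"] == "division"]
        births = ev[(ev["event"] == "birth") & (ev["parent_id"] >= 0)]
        daughter_counts = births.groupby("parent_id").size()
        for _, d in divisions.iterrows():
            if daughter_counts.get(d["cell_id"], 0) != 2:
                raise ValueError(f"division of cell {d['cell_id']} without two daughters")


def concat_logs(logs: Sequence[CellEventLog]) -> CellEventLog:
    """Merge logs of independent wells, re-keying cell ids to stay unique."""
    frames = []
    offset = 0
    for log in logs:
        ev = log.events.copy()
        ev["cell_id"] += offset
        ev.loc[ev["parent_id"] >= 0, "parent_id"] += offset
        frames.append(ev)
        if len(ev):
            offset = int(ev["cell_id"].max()) + 1
    t0 = min((l.t_start for l in logs), default=4.0)
    t1 = max((l.t_end for l in logs), default=72.0)
    return CellEventLog(pd.concat(frames, ignore_index=True) if frames else
                        pd.DataFrame(columns=_EVENT_COLUMNS), t0, t1)


# ---------------------------------------------------------------------------
# per-cell well simulation


def simulate_well(
    phenotype: WellPhenotype = NULL_PHENOTYPE,
    n_cells: int = 850,
    baseline_division_rate: float = 0.03,
    spec: MovieSpec = DEFAULT_MOVIE_SPEC,
    seed: int = 0,
    *,
    interphase_death_rate: float = 0.001,
    fate_mixture: FateMixture = DEFAULT_FATE_MIXTURE,
    normal_mitosis_h: float = 1.0,
    arrest_min_h: float = 2.0,
    arrest_max_h: float = 10.0,
) -> CellEventLog:
    """Simulate one well as a discrete-time branching process.

    Each interphase cell enters mitosis with probability ``rate * m(t) * dt``
    per 30-min step, where ``m(t)`` is the phenotype's rate multiplier, and
    dies in interphase at a small background rate.  A mitosis either runs
    its normal ~1 h course and divides, or (with the phenotype's arrest
    probability) arrests for a uniform (2, 10] h and resolves into mitotic
    death, mitotic exit or cytokinesis failure according to
    ``fate_mixture``.  Daughters are placed 1.2 nucleus radii either side of
    the parent; interphase cells random-walk with reflecting boundaries.

    With no phenotype and no deaths the expected number of divisions over a
    duration T is ``n_cells * (exp(rate*T) - 1)`` (exponential growth).

    Cells are seeded with a minimum spacing and softly repel below
    2 nucleus radii (nuclei exclude each other physically), which keeps
    the rendered movie resolvable by the segmenter at benchmark densities.
    The log carries the exact per-frame trajectory in ``log.tracks`` so the
    renderer and the ground truth agree.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    if baseline_division_rate < 0:
        raise ValueError("division rate must be >= 0")
    rng = _rng(seed, 303)
    dt = spec.interval_h
    size = spec.size_um
    sep = 1.4 * spec.nucleus_radius_um
    min_sep = 2.0 * spec.nucleus_radius_um
    lo, hi = spec.nucleus_radius_um, size - spec.nucleus_radius_um

    def reflect(v: float) -> float:
        # bounce off the field margin instead of piling up against it
        for _ in range(4):
            if v < lo:
                v = 2 * lo - v
            elif v > hi:
                v = 2 * hi - v
            else:
                break
        return float(np.clip(v, lo, hi))
    arrest_p = fate_mixture.arrest_fates()

    events: list[tuple] = []
    cells: list[dict] = []
    track_rows: list[tuple] = []

    def spawn(parent: int, t: float, x: float, y: float) -> None:
        cid = len(cells)
        cells.append({"id": cid, "x": x, "y": y, "state": "interphase",
                      "resolve_t": np.inf, "outcome": None})
        events.append((cid, parent, t, "birth", x, y))
        track_rows.append((cid, t, x, y))

    for _ in range(n_cells):
        for _attempt in range(50):  # rejection-sample a spaced position
            x, y = rng.uniform(lo, hi), rng.uniform(lo, hi)
            if all((cells[i]["x"] - x) ** 2 + (cells[i]["y"] - y) ** 2 >= min_sep**2
                   for i in range(len(cells))):
                break
        spawn(-1, spec.t_start, x, y)

    def repel(indices: list[int], passes: int = 3) -> None:
        """Push apart cell pairs closer than min_sep (a few relaxation passes).

        Mitotic cells have rounded up and stay put; only interphase cells
        yield, and each push is capped so a cell never jumps further per
        frame than a tracker could plausibly follow.
        """
        if len(indices) < 2:
            return
        from scipy.spatial import cKDTree

        pos = np.array([[cells[i]["x"], cells[i]["y"]] for i in indices])
        movable = np.array([cells[i]["state"] == "interphase" for i in indices])
        cap = 0.3 * spec.nucleus_radius_um
        for _ in range(passes):
            pairs = cKDTree(pos).query_pairs(min_sep, output_type="ndarray")
            if len(pairs) == 0:
                break
            for a, b in pairs:
                d = pos[b] - pos[a]
                norm = float(np.hypot(*d))
                if norm < 1e-9:
                    d, norm = np.array([1.0, 0.0]), 1.0
                step = min(0.5 * (min_sep - norm), cap)
                push = step * d / norm
                if movable[a]:
                    pos[a] -= push
                if movable[b]:
                    pos[b] += push
            pos = np.clip(pos, lo, hi)
        for k, i in enumerate(indices):
            cells[i]["x"], cells[i]["y"] = float(pos[k, 0]), float(pos[k, 1])

    alive = list(range(n_cells))
    for t in spec.frame_times()[1:]:
        t = float(t)
        nxt: list[int] = []
        for idx in alive:
            c = cells[idx]
            if c["state"] == "interphase":  # mitotic cells round up and stop
                c["x"] = reflect(c["x"] + rng.normal(0, spec.brownian_sd_um))
                c["y"] = reflect(c["y"] + rng.normal(0, spec.brownian_sd_um))
        repel(alive)
        for idx in alive:
            c = cells[idx]
            if c["state"] == "interphase":
                if rng.random() < interphase_death_rate * dt:
                    events.append((c["id"], -1, t, "interphase_death", c["x"], c["y"]))
                    continue
                m = phenotype.rate_multiplier(t)
                if rng.random() < baseline_division_rate * m * dt:
                    events.append((c["id"], -1, t, "mitosis_entry", c["x"], c["y"]))
                    if rng.random() < phenotype.arrest_prob(t):
                        c["outcome"] = str(rng.choice(MITOSIS_RESOLUTIONS[1:], p=arrest_p))
                        c["resolve_t"] = t + rng.uniform(arrest_min_h, arrest_max_h)
                    else:
                        c["outcome"] = "division"
                        c["resolve_t"] = t + normal_mitosis_h
                    c["state"] = "mitotic"
                nxt.append(idx)
            else:  # mitotic
                if t >= c["resolve_t"] - 1e-9:
                    out = c["outcome"]
                    events.append((c["id"], -1, t, out, c["x"], c["y"]))
                    if out == "division":
                        # divide along the least-crowded axis so daughters do
                        # not land on a neighbouring nucleus
                        theta0 = rng.uniform(0, 2 * np.pi)
                        others = np.array([[cells[i]["x"], cells[i]["y"]]
                                           for i in alive if i != idx] or [[1e9, 1e9]])
                        best, best_score = theta0, -np.inf
                        for theta in theta0 + np.pi * np.arange(8) / 8:
                            dxy = sep * np.array([np.cos(theta), np.sin(theta)])
                            score = np.inf
                            for s_ in (1.0, -1.0):
                                p_ = np.array([c["x"], c["y"]]) + s_ * dxy
                                margin = min(p_[0] - lo, hi - p_[0], p_[1] - lo, hi - p_[1])
                                d_others = float(np.hypot(*(others - p_).T).min())
                                # out-of-bounds daughters would reflect onto
                                # their sibling: treat as worst case
                                score = min(score, d_others if margin >= 0 else margin)
                            if score > best_score:
                                best, best_score = theta, score
                        dx, dy = sep * np.cos(best), sep * np.sin(best)
                        for sgn in (1.0, -1.0):
                            px_, py_ = reflect(c["x"] + sgn * dx), reflect(c["y"] + sgn * dy)
                            # nudge the newborn off a crowding neighbour
                            # (birth placement, not motion: the tracker only
                            # ever sees the final position)
                            if len(others) and others[0][0] < 1e8:
                                vec = np.array([px_, py_]) - others
                                dist = np.hypot(vec[:, 0], vec[:, 1])
                                j = int(dist.argmin())
                                if dist[j] < 1.5 * spec.nucleus_radius_um:
                                    shift = min(1.5 * spec.nucleus_radius_um - dist[j],
                                                0.5 * spec.nucleus_radius_um)
                                    u = vec[j] / max(dist[j], 1e-9)
                                    px_ = reflect(px_ + shift * u[0])
                                    py_ = reflect(py_ + shift * u[1])
                            spawn(c["id"], t, px_, py_)
                            nxt.append(len(cells) - 1)
                    elif out in ("mitotic_exit", "cytokinesis_failure"):
                        c["state"] = "interphase"
                        nxt.append(idx)
                    # mitotic_death: cell gone
                else:
                    nxt.append(idx)
        alive = nxt
        for idx in alive:
            c = cells[idx]
            track_rows.append((c["id"], t, c["x"], c["y"]))

    df = pd.DataFrame(events, columns=_EVENT_COLUMNS)
    tracks = pd.DataFrame(track_rows, columns=["cell_id", "time_h", "x_um", "y_um"]) \
        .drop_duplicates(["cell_id", "time_h"], keep="last") \
        .sort_values(["cell_id", "time_h"], kind="stable").reset_index(drop=True)
    return CellEventLog(df, spec.t_start, spec.t_end, tracks=tracks)


# ---------------------------------------------------------------------------
# fast aggregate count simulation (no per-cell state)


def simulate_well_counts(
    phenotypes: Sequence[WellPhenotype],
    n_cells: int = 850,
    baseline_division_rate: float = 0.03,
    t_start: float = 4.0,
    t_end: float = 72.0,
    dt: float = 0.5,
    *,
    interphase_death_rate: float = 0.001,
    rate_cv: float = 0.1,
    normal_mitosis_h: float = 1.0,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Per-well MitosisCount from the aggregate branching model.

    Runs the same discrete-time law as :func:`simulate_well` but tracks
    only cell counts per well: cells entering mitosis spend
    ``normal_mitosis_h`` in a pipeline before splitting; entries thinned by
    the arrest probability leave the proliferating pool and never split a
    track (arrest resolutions are not modelled at count level).
    ``rate_cv`` adds lognormal well-to-well variability (log-sd) to the
    division rate, emulating biological plate noise.  Vectorised over wells.
    """
    if rng is None:
        rng = _rng(seed, 404)
    n_wells = len(phenotypes)
    rates = baseline_division_rate * np.exp(rng.normal(0.0, rate_cv, size=n_wells))
    alive = np.full(n_wells, n_cells, dtype=np.int64)
    counts = np.zeros(n_wells, dtype=np.int64)
    times = np.arange(t_start + dt, t_end + dt / 2, dt)
    mult = np.empty(n_wells)
    arrest = np.empty(n_wells)
    m_steps = max(1, int(round(normal_mitosis_h / dt)))
    pipeline = [np.zeros(n_wells, dtype=np.int64) for _ in range(m_steps)]
    for t in times:
        for i, ph in enumerate(phenotypes):
            mult[i] = ph.rate_multiplier(float(t))
            arrest[i] = ph.arrest_prob(float(t))
        completing = pipeline.pop(0)
        p_div = np.clip(rates * mult * dt, 0.0, 1.0)
        entering = rng.binomial(alive, p_div)
        dividing = rng.binomial(entering, 1.0 - arrest)
        dying = rng.binomial(alive - entering, min(interphase_death_rate * dt, 1.0))
        counts += completing
        # daughters of completing mitoses join; entrants (and arrested
        # cells, permanently) leave the interphase pool
        alive = alive + 2 * completing - entering - dying
        pipeline.append(dividing)
    return counts


# ---------------------------------------------------------------------------
# standalone fate sequences


def assign_fates(
    n: int,
    mixture: FateMixture = DEFAULT_FATE_MIXTURE,
    seed: int = 0,
    *,
    arrest_entry_range: tuple[float, float] = (12.0, 60.0),
    arrest_duration_range: tuple[float, float] = (2.0, 10.0),
    apoptosis_range: tuple[float, float] = (12.0, 24.0),
    t_start: float = 4.0,
    t_end: float = 72.0,
    field_um: float = 256.0,
) -> CellEventLog:
    """Generate ``n`` phenotypic cell histories from a fate mixture.

    Arrest-first fates carry a mitosis_entry with an arrest duration drawn
    uniformly on (2, 10] h; direct-apoptosis cells die in interphase between
    12 and 24 h post-transfection without any mitosis.
    """
    mixture.__post_init__()  # re-validate (callers may pass a tampered instance)
    rng = _rng(seed, 505)
    fates = ("mitotic_death", "mitotic_exit", "cytokinesis_failure", "direct_apoptosis")
    choice = rng.choice(4, size=n, p=mixture.as_array())
    rows: list[tuple] = []
    for cid in range(n):
        x, y = rng.uniform(0, field_um, size=2)
        rows.append((cid, -1, t_start, "birth", x, y))
        fate = fates[choice[cid]]
        if fate == "direct_apoptosis":
            t_d = rng.uniform(*apoptosis_range)
            rows.append((cid, -1, t_d, "interphase_death", x, y))
        else:
            t_m = rng.uniform(*arrest_entry_range)
            lo, hi = arrest_duration_range
            dur = lo + (hi - lo) * (1.0 - rng.random())  # uniform on (lo, hi]
            rows.append((cid, -1, t_m, "mitosis_entry", x, y))
            rows.append((cid, -1, min(t_m + dur, t_end), fate, x, y))
    df = pd.DataFrame(rows, columns=_EVENT_COLUMNS)
    return CellEventLog(df, t_start, t_end)


# ---------------------------------------------------------------------------
# rendering


def _add_gaussian(img: np.ndarray, x: float, y: float, sigma: float, amp: float) -> None:
    """Accumulate an isotropic Gaussian blob at (x, y) px; x = column."""
    h, w = img.shape
    r = int(3 * sigma) + 1
    x0, x1 = max(0, int(x) - r), min(w, int(x) + r + 1)
    y0, y1 = max(0, int(y) - r), min(h, int(y) + r + 1)
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1) - x
    ys = np.arange(y0, y1) - y
    img[y0:y1, x0:x1] += amp * np.exp(
        -(ys[:, None] ** 2 + xs[None, :] ** 2) / (2 * sigma**2)
    )


def _cell_render_plan(log: CellEventLog) -> list[dict]:
    """Per-cell birth/end times, mitosis intervals and death mode."""
    plan = []
    for cid, seq in log.sequences():
        seq = seq.sort_values("time_h", kind="stable")
        birth = seq.iloc[0]
        end_t, end_kind = np.inf, None
        mitoses: list[tuple[float, float]] = []
        entry = None
        enlarged = False
        for _, e in seq.iloc[1:].iterrows():
            if e["event"] == "mitosis_entry":
                entry = e["time_h"]
            elif e["event"] in MITOSIS_RESOLUTIONS:
                mitoses.append((entry if entry is not None else e["time_h"], e["time_h"]))
                entry = None
                if e["event"] == "cytokinesis_failure":
                    enlarged = True
                if e["event"] in ("division", "mitotic_death"):
                    end_t, end_kind = e["time_h"], e["event"]
            elif e["event"] == "interphase_death":
                end_t, end_kind = e["time_h"], e["event"]
        if entry is not None:  # censored mitosis: render mitotic to the end
            mitoses.append((entry, np.inf))
        plan.append({"cell_id": int(cid), "birth_t": float(birth["time_h"]),
                     "x0": float(birth["x_um"]), "y0": float(birth["y_um"]),
                     "end_t": float(end_t), "end_kind": end_kind,
                     "mitoses": mitoses, "enlarged": enlarged})
    return plan


def render_movie(
    log: CellEventLog,
    spec: MovieSpec = DEFAULT_MOVIE_SPEC,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Render an event log into two uint16 stacks: ``H2B_red``, ``TUB_green``.

    Nuclei are Gaussian blobs in the red channel; mitotic cells condense
    (smaller, brighter); dying cells shrink over the hour before death and
    fragment into four dim blobs for the hour after, then vanish; a division
    removes the parent blob and places two separating daughter blobs; cells
    that failed cytokinesis render enlarged (binucleate).  Tubulin renders a
    broad dim halo per cell and is not meant to be segmented.
    """
    times = spec.frame_times()
    F, N = len(times), spec.frame_px
    red = np.zeros((F, N, N), dtype=np.float64)
    green = np.zeros_like(red)
    sigma0 = 0.5 * spec.nucleus_radius_um / spec.pixel_um
    plan = _cell_render_plan(log)
    trajectories: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    if log.tracks is not None:
        for cid, grp in log.tracks.groupby("cell_id"):
            trajectories[int(cid)] = (grp["time_h"].to_numpy(),
                                      grp["x_um"].to_numpy(), grp["y_um"].to_numpy())

    for cell in plan:
        crng = _rng(seed, 606, cell["cell_id"])
        # frames where the cell (or its remnant) appears
        first = int(np.searchsorted(times, cell["birth_t"] - 1e-9))
        x, y = cell["x0"], cell["y0"]
        traj = trajectories.get(cell["cell_id"])
        for fi in range(first, F):
            t = times[fi]
            if traj is not None:
                # exact simulated trajectory; hold the last position after death
                j = min(int(np.searchsorted(traj[0], t + 1e-9)) - 1, len(traj[0]) - 1)
                if j >= 0:
                    x, y = float(traj[1][j]), float(traj[2][j])
            elif fi > first:
                x = float(np.clip(x + crng.normal(0, spec.brownian_sd_um), 0, spec.size_um))
                y = float(np.clip(y + crng.normal(0, spec.brownian_sd_um), 0, spec.size_um))
            px, py = x / spec.pixel_um, y / spec.pixel_um
            if t >= cell["end_t"] - 1e-9:
                if cell["end_kind"] == "division":
                    break  # replaced by daughters (their own plan entries)
                # apoptotic fragments for up to 1 h after death, then vanish
                if t - cell["end_t"] > 1.0 + 1e-9:
                    break
                fade = 1.0 - (t - cell["end_t"]) / 1.2
                for _ in range(4):
                    fx = px + crng.normal(0, sigma0)
                    fy = py + crng.normal(0, sigma0)
                    _add_gaussian(red[fi], fx, fy, sigma0 * 0.3,
                                  0.8 * spec.nucleus_amplitude * fade)
                continue
            mitotic = any(a - 1e-9 <= t < b - 1e-9 for a, b in cell["mitoses"])
            dying_soon = cell["end_kind"] in ("mitotic_death", "interphase_death") and \
                cell["end_t"] - t <= 1.0 + 1e-9
            sigma, amp = sigma0, spec.nucleus_amplitude
            if cell["enlarged"]:
                sigma *= 1.25
            if mitotic:
                sigma, amp = sigma * 0.7, amp * 2.0
            if dying_soon:
                sigma, amp = sigma * 0.7, amp * 1.3
            _add_gaussian(red[fi], px, py, sigma, amp)
            _add_gaussian(green[fi], px, py, sigma * 2.5, 0.25 * spec.nucleus_amplitude)

    nrng = _rng(seed, 707)
    out = {}
    for name, stack in (("H2B_red", red), ("TUB_green", green)):
        noisy = stack + spec.background + nrng.normal(0, spec.noise_sd, size=stack.shape)
        out[name] = np.clip(noisy, 0, 65535).astype(np.uint16)
    return out


def alive_cells_per_frame(log: CellEventLog, spec: MovieSpec) -> np.ndarray:
    """Ground-truth count of intact (renderable, unfragmented) cells per frame."""
    times = spec.frame_times()
    counts = np.zeros(len(times), dtype=int)
    for cell in _cell_render_plan(log):
        start = cell["birth_t"] - 1e-9
        end = cell["end_t"] - 1e-9
        counts += (times >= start) & (times < end)
    return counts


def division_truth(log: CellEventLog) -> pd.DataFrame:
    """Ground-truth division times/positions, for benchmarking split detection."""
    ev = log.events
    d = ev[ev["event"] == "division"]
    return d[["cell_id", "time_h", "x_um", "y_um"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# manual scores


def synthesize_manual_scores(
    effects: Iterable[float],
    noise_sd: float = 0.5,
    seed: int = 0,
) -> np.ndarray:
    """Ordinal phenotype severity scores 1-5 from latent effects in [0, 1].

    score = clamp(round(1 + 4*effect + eps), 1, 5) with eps ~ N(0, noise_sd);
    the expected score is monotone non-decreasing in the effect.
    """
    e = np.asarray(list(effects), dtype=float)
    if e.size and ((e < 0) | (e > 1)).any():
        raise ValueError("effects must lie in [0, 1]")
    rng = _rng(seed, 808)
    eps = rng.normal(0.0, noise_sd, size=e.shape) if noise_sd > 0 else np.zeros_like(e)
    return np.clip(np.rint(1.0 + 4.0 * e + eps), 1, 5).astype(int)


# ---------------------------------------------------------------------------
# pulldown proteomics tables


def make_peptide_tables(
    n_proteins: int = 400,
    n_enriched: int = 132,
    seed: int = 0,
    *,
    fold_change: float = 8.0,
    peptide_range: tuple[int, int] = (3, 12),
    n_controls: int = 2,
) -> tuple[pd.DataFrame, list[pd.DataFrame], dict[str, int]]:
    """Synthetic peptide-intensity tables for one target and control pulldowns.

    Returns (target_table, control_tables, n_theoretical_peptides).  Tables
    have columns protein_id, peptide_id, intensity.  A designated subset of
    ``n_enriched`` proteins carries ``fold_change``-fold higher intensities
    in the target pulldown; the ground-truth enriched set is the first
    ``n_enriched`` protein ids (``PROT0000``...).
    """
    if n_enriched > n_proteins:
        raise ValueError("n_enriched cannot exceed n_proteins")
    rng = _rng(seed, 909)
    proteins = [f"PROT{i:04d}" for i in range(n_proteins)]
    n_theo = {p: int(rng.integers(peptide_range[0], peptide_range[1] + 1)) for p in proteins}
    base = {p: float(np.exp(rng.normal(np.log(1e5), 0.8))) for p in proteins}

    def table(boost: Mapping[str, float], stream: int) -> pd.DataFrame:
        trng = _rng(seed, 910, stream)
        rows = []
        for p in proteins:
            for j in range(n_theo[p]):
                inten = base[p] * boost.get(p, 1.0) * np.exp(trng.normal(0, 0.3))
                rows.append((p, f"{p}_pep{j + 1}", float(inten)))
        return pd.DataFrame(rows, columns=["protein_id", "peptide_id", "intensity"])

    boost = {p: fold_change for p in proteins[:n_enriched]}
    target = table(boost, 0)
    controls = [table({}, k + 1) for k in range(n_controls)]
    return target, controls, n_theo


def make_term_annotation(
    proteins: Sequence[str],
    enriched: Sequence[str],
    n_terms: int = 25,
    seed: int = 0,
    *,
    focus_term: str = "M_PHASE",
    focus_capture: float = 0.6,
) -> dict[str, set[str]]:
    """Random term -> protein annotation with one term concentrated on the
    enriched set (emulating a cell-cycle process standing out in a
    functional-enrichment scan)."""
    rng = _rng(seed, 1001)
    ann: dict[str, set[str]] = {}
    proteins = list(proteins)
    for i in range(n_terms):
        size = int(rng.integers(10, max(11, len(proteins) // 5)))
        ann[f"TERM{i:03d}"] = set(rng.choice(proteins, size=min(size, len(proteins)), replace=False))
    focus = set(rng.choice(list(enriched), size=int(focus_capture * len(enriched)), replace=False))
    filler = set(rng.choice(proteins, size=max(5, len(focus) // 4), replace=False))
    ann[focus_term] = focus | filler
    return ann
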