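"""Stochastic simulator of mother-machine trenches under an antimicrobial
treatment schedule.

The mother machine holds single-file bacterial lineages in dead-end trenches
(here 75 um x 1 um) under constant media flow; the cell at the dead end is
retained indefinitely while offspring are pushed out of the open end.  This
module generates synthetic single-cell observations of that device together
with the full ground truth (lineage forest and event log), which the rest of
the pipeline treats as its oracle.

Model
-----
* Each cell elongates exponentially, ``L(t) = L_birth * exp(int alpha(s) ds)``,
  with ``alpha(t) = alpha0 * (1 - inhibition)`` inside the treatment window
  ``[treat_start, treat_end)`` and ``alpha0`` outside it.
* Division follows a sizer: a per-cell threshold length is drawn at birth
  (lognormal; mean ``div_len_mean``, CV ``div_len_cv``) and the cell splits
  into daughters of fractions ``f`` and ``1 - f`` when it reaches it, with
  ``f ~ N(0.5, div_asym_sd)``.
* Lysis is a Poisson event with piecewise-constant rate ``lambda0`` outside
  and ``lambda_treat`` inside the treatment window (events/cell/h).
* Cells are stacked from the dead end; whenever the stack outgrows the trench
  the distal-most cells are evicted (resolved at frame resolution).
* Observations are sampled every ``frame_interval`` minutes with
  multiplicative lognormal length noise ``exp(N(0, obs_noise_sd**2))``.

Division and lysis times are sampled exactly in continuous time (next-event
scheduling against the piecewise-constant rates), so recovered rates carry no
frame-discretisation bias.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SimulationParams",
    "GroundTruth",
    "simulate_trench",
    "simulate_experiment",
    "simulate_population",
    "load_params",
    "save_params",
]

OBS_COLUMNS = ["trench_id", "frame", "time_min", "rank", "length_um", "centroid_um"]
LINEAGE_COLUMNS = ["cell_id", "trench_id", "parent_id", "birth_frame", "last_frame", "fate"]
EVENT_COLUMNS = ["time_min", "trench_id", "cell_id", "event"]


@dataclass(frozen=True)
class SimulationParams:
    """Ground-truth parameters of the trench simulator.

    Rates ``lambda0``/``lambda_treat`` are in events/cell/h; ``alpha0`` is the
    elongation rate in 1/min; lengths in um; times in min.
    """

    alpha0: float = 0.03
    inhibition: float = 0.15
    lambda0: float = 0.01
    lambda_treat: float = 0.05
    div_len_mean: float = 4.5
    div_len_cv: float = 0.10
    div_asym_sd: float = 0.04
    obs_noise_sd: float = 0.02
    trench_len: float = 75.0
    frame_interval: float = 1.0
    t_total: float = 360.0
    treat_start: float = 90.0
    treat_end: float = 270.0
    n_trenches: int = 20
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.alpha0 < 0 or self.lambda0 < 0 or self.lambda_treat < 0:
            raise ValueError("rates must be non-negative")
        if not 0 <= self.inhibition < 1:
            raise ValueError("inhibition must lie in [0, 1)")
        if not 0 <= self.treat_start < self.treat_end <= self.t_total:
            raise ValueError("require 0 <= treat_start < treat_end <= t_total")
        if not self.div_len_mean < self.trench_len:
            raise ValueError("div_len_mean must be smaller than trench_len")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.div_len_cv < 0 or self.div_asym_sd < 0 or self.obs_noise_sd < 0:
            raise ValueError("dispersion parameters must be non-negative")
        if self.n_trenches < 1:
            raise ValueError("n_trenches must be >= 1")

    def require_seed(self) -> int:
        if self.seed is None:
            raise ValueError("SimulationParams.seed must be set explicitly "
                             "(no implicit global RNG)")
        return int(self.seed)


class _PiecewiseRate:
    """Piecewise-constant rate with exact cumulative integral and inversion."""

    def __init__(self, breaks: Sequence[float], rates: Sequence[float]):
        # breaks: [b0, b1, ..., bk]; rates r_i applies on [b_i, b_{i+1}),
        # r_k beyond b_k.
        if len(rates) != len(breaks):
            raise ValueError("need one rate per breakpoint")
        self.breaks = np.asarray(breaks, dtype=float)
        self.rates = np.asarray(rates, dtype=float)
        if np.any(self.rates < 0):
            raise ValueError("rates must be non-negative")
        seg = np.diff(self.breaks) * self.rates[:-1]
        self._cum = np.concatenate([[0.0], np.cumsum(seg)])

    def cumulative(self, t: float) -> float:
        i = int(np.searchsorted(self.breaks, t, side="right")) - 1
        i = max(i, 0)
        return float(self._cum[i] + self.rates[i] * (t - self.breaks[i]))

    def invert_from(self, t0: float, target: float) -> float:
        """Smallest t >= t0 with integral over [t0, t] equal to target."""
        if target <= 0:
            return t0
        goal = self.cumulative(t0) + target
        i = int(np.searchsorted(self.breaks, t0, side="right")) - 1
        i = max(i, 0)
        for j in range(i, len(self.rates)):
            start = max(t0, self.breaks[j])
            base = self.cumulative(start)
            rate = self.rates[j]
            end = self.breaks[j + 1] if j + 1 < len(self.breaks) else math.inf
            if rate > 0:
                t = start + (goal - base) / rate
                if t <= end:
                    return t
        return math.inf


def _alpha_profile(p: SimulationParams) -> _PiecewiseRate:
    a1 = p.alpha0 * (1.0 - p.inhibition)
    return _PiecewiseRate([0.0, p.treat_start, p.treat_end], [p.alpha0, a1, p.alpha0])


def _lysis_profile(p: SimulationParams) -> _PiecewiseRate:
    per_min = (p.lambda0 / 60.0, p.lambda_treat / 60.0)
    return _PiecewiseRate([0.0, p.treat_start, p.treat_end],
                          [per_min[0], per_min[1], per_min[0]])


@dataclass
class _Cell:
    cell_id: int
    parent_id: int | None
    birth_time: float
    birth_len: float
    threshold: float
    div_time: float
    lysis_time: float
    death_time: float | None = None
    fate: str | None = None
    children: tuple[int, int] | None = None


@dataclass
class GroundTruth:
    """Noise-free truth emitted alongside observations.

    ``lineage`` is the frame-resolution lineage forest (same schema the
    tracker outputs); ``events`` the continuous-time event log;
    ``assignments`` maps every observation row (trench_id, frame, rank) to its
    true lineage-record id.
    """

    lineage: pd.DataFrame
    events: pd.DataFrame
    assignments: pd.DataFrame

    def merge(self, other: "GroundTruth") -> "GroundTruth":
        return GroundTruth(
            lineage=pd.concat([self.lineage, other.lineage], ignore_index=True),
            events=pd.concat([self.events, other.events], ignore_index=True),
            assignments=pd.concat([self.assignments, other.assignments],
                                  ignore_index=True),
        )


def _draw_threshold(rng: np.random.Generator, p: SimulationParams) -> float:
    if p.div_len_cv == 0:
        return p.div_len_mean
    sigma = math.sqrt(math.log(1.0 + p.div_len_cv ** 2))
    mu = math.log(p.div_len_mean) - 0.5 * sigma ** 2
    return float(rng.lognormal(mu, sigma))


def _schedule(cell_id: int, parent_id: int | None, t: float, length: float,
              rng: np.random.Generator, p: SimulationParams,
              alpha: _PiecewiseRate, lam: _PiecewiseRate) -> _Cell:
    threshold = _draw_threshold(rng, p)
    if threshold <= length:
        # A cell born at or above its division threshold cannot be given a
        # positive cycle time; with zero growth this is a degenerate
        # parameterisation, otherwise nudge the threshold just above birth.
        if alpha.cumulative(t + 1.0) == alpha.cumulative(t):
            raise ValueError(
                "degenerate parameters: division threshold below birth length "
                "with zero elongation rate")
        threshold = length * 1.001
    div_time = alpha.invert_from(t, math.log(threshold / length))
    lysis_time = lam.invert_from(t, float(rng.exponential()))
    return _Cell(cell_id, parent_id, t, length, threshold, div_time, lysis_time)


def simulate_trench(params: SimulationParams, trench_id: int = 0,
                    ) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate one trench; return (observations, ground truth).

    The trench is seeded with a single cell at the dead end.  Division and
    lysis are scheduled exactly in continuous time; eviction (the stack
    outgrowing the trench) is resolved at each frame before sampling, so
    observed lengths always fit in ``[0, trench_len]``.
    """
    seed = params.require_seed()
    rng = np.random.default_rng(np.random.SeedSequence((seed, int(trench_id))))
    alpha = _alpha_profile(params)
    lam = _lysis_profile(params)
    p = params

    n_frames = int(math.floor(p.t_total / p.frame_interval)) + 1
    frame_times = np.arange(n_frames) * p.frame_interval
    horizon = float(frame_times[-1])

    cells: dict[int, _Cell] = {}
    next_id = 0

    def new_cell(parent: int | None, t: float, length: float) -> _Cell:
        nonlocal next_id
        c = _schedule(next_id, parent, t, length, rng, p, alpha, lam)
        cells[c.cell_id] = c
        next_id += 1
        return c

    def length_at(c: _Cell, t: float) -> float:
        return c.birth_len * math.exp(alpha.cumulative(t) - alpha.cumulative(c.birth_time))

    init_len = 0.5 * p.div_len_mean
    if p.div_len_cv > 0:
        init_len *= math.exp(rng.normal(0.0, math.sqrt(math.log(1 + p.div_len_cv ** 2))))
    stack: list[_Cell] = [new_cell(None, 0.0, init_len)]  # proximal -> distal

    events: list[tuple[float, int, str]] = []  # (time, cell_id, event)
    obs_rows: list[tuple] = []
    assign_rows: list[tuple] = []
    # cell_id -> list of frames observed
    observed: dict[int, list[int]] = {}

    frame_idx = 0
    t_now = 0.0
    while True:
        # next stochastic event among live cells (ties broken by id, then
        # lysis before division; ties have probability zero anyway)
        ev_time, ev_cell, ev_kind = math.inf, None, ""
        for c in stack:
            for t_ev, kind in ((c.lysis_time, "lysis"), (c.div_time, "division")):
                if t_ev < ev_time:
                    ev_time, ev_cell, ev_kind = t_ev, c, kind
        next_frame_t = frame_times[frame_idx] if frame_idx < n_frames else math.inf
        if ev_time == math.inf and next_frame_t == math.inf:
            break

        if next_frame_t <= ev_time:
            # -- frame: evict overflow, then observe
            t_now = next_frame_t
            total = sum(length_at(c, t_now) for c in stack)
            while stack and total > p.trench_len:
                out = stack.pop()
                out.death_time = t_now
                out.fate = "evicted"
                events.append((t_now, out.cell_id, "eviction"))
                total -= length_at(out, t_now)
            for rank, c in enumerate(stack):
                true_len = length_at(c, t_now)
                if p.obs_noise_sd > 0:
                    obs_len = true_len * math.exp(rng.normal(0.0, p.obs_noise_sd))
                else:
                    obs_len = true_len
                obs_rows.append((trench_id, frame_idx, t_now, rank, obs_len, 0.0))
                assign_rows.append((trench_id, frame_idx, rank, c.cell_id))
                observed.setdefault(c.cell_id, []).append(frame_idx)
            frame_idx += 1
            if frame_idx >= n_frames:
                break
            continue

        if ev_time >= horizon:
            break
        t_now = ev_time
        assert ev_cell is not None
        if ev_kind == "lysis":
            ev_cell.death_time = t_now
            ev_cell.fate = "lysed"
            events.append((t_now, ev_cell.cell_id, "lysis"))
            stack.remove(ev_cell)  # distal cells translate toward the dead end
        else:  # division
            L = length_at(ev_cell, t_now)
            f = 0.5
            if p.div_asym_sd > 0:
                f = float(np.clip(rng.normal(0.5, p.div_asym_sd), 0.2, 0.8))
            ev_cell.death_time = t_now
            ev_cell.fate = "divided"
            events.append((t_now, ev_cell.cell_id, "division"))
            idx = stack.index(ev_cell)
            d1 = new_cell(ev_cell.cell_id, t_now, f * L)
            d2 = new_cell(ev_cell.cell_id, t_now, (1.0 - f) * L)
            ev_cell.children = (d1.cell_id, d2.cell_id)
            stack[idx:idx + 1] = [d1, d2]

    for c in stack:  # alive at the end of the movie
        c.fate = "censored"

    obs = pd.DataFrame(obs_rows, columns=OBS_COLUMNS)
    # observed centroids: stack the *observed* lengths from the dead end so
    # that within-frame ordering invariants hold under measurement noise
    obs["centroid_um"] = (obs.groupby("frame")["length_um"].cumsum()
                          - 0.5 * obs["length_um"])

    lineage, record_of = _coarse_grain(cells, observed, trench_id)
    assign = pd.DataFrame(assign_rows, columns=["trench_id", "frame", "rank", "cell_id"])
    assign["cell_id"] = assign["cell_id"].map(record_of)
    evt = pd.DataFrame(events, columns=["time_min", "cell_id", "event"])
    evt.insert(1, "trench_id", trench_id)
    truth = GroundTruth(lineage=lineage, events=evt[EVENT_COLUMNS], assignments=assign)
    return obs, truth


def _coarse_grain(cells: dict[int, _Cell], observed: dict[int, list[int]],
                  trench_id: int) -> tuple[pd.DataFrame, dict[int, str]]:
    """Collapse the continuous-time cell tree to frame-resolution records.

    A division whose daughter never appears in any frame (it lysed or was
    evicted within the same sampling interval) is invisible to any tracker;
    the parent's record is merged with the surviving daughter's so that the
    table is exactly what an ideal observer could reconstruct.
    """
    rows: list[tuple] = []
    record_of: dict[int, str] = {}

    def subtree_fate(cid: int) -> str:
        # fate label for a record whose continuation is entirely unobserved
        c = cells[cid]
        if c.fate == "divided":
            assert c.children is not None
            fates = {subtree_fate(ch) for ch in c.children}
            return "evicted" if "evicted" in fates else "lysed"
        return c.fate or "censored"

    def emit(cid: int, parent_record: str | None) -> None:
        rec_id = f"t{trench_id}c{cid}"
        start = cid
        frames = list(observed.get(cid, []))
        cur = cells[cid]
        record_of[cid] = rec_id
        while True:
            if cur.fate == "divided":
                assert cur.children is not None
                kids = cur.children
                seen = [k for k in kids if observed.get(k)]
                if len(seen) == 2:
                    rows.append((rec_id, trench_id, parent_record,
                                 frames[0], frames[-1], "divided"))
                    for k in kids:
                        emit(k, rec_id)
                    return
                if len(seen) == 1:
                    # invisible division: continue this record as the survivor
                    hidden = kids[0] if kids[1] == seen[0] else kids[1]
                    record_of[hidden] = rec_id
                    record_of[seen[0]] = rec_id
                    cur = cells[seen[0]]
                    frames.extend(observed[seen[0]])
                    continue
                rows.append((rec_id, trench_id, parent_record,
                             frames[0], frames[-1], subtree_fate(cur.cell_id)))
                for k in kids:
                    record_of[k] = rec_id
                return
            rows.append((rec_id, trench_id, parent_record,
                         frames[0], frames[-1], cur.fate or "censored"))
            return

    roots = [c.cell_id for c in cells.values() if c.parent_id is None]
    for r in sorted(roots):
        if observed.get(r):
            emit(r, None)
    lineage = pd.DataFrame(rows, columns=LINEAGE_COLUMNS)
    return lineage, record_of


def simulate_experiment(params: SimulationParams) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate ``params.n_trenches`` independent trenches (one device lane)."""
    obs_parts: list[pd.DataFrame] = []
    truth: GroundTruth | None = None
    for tid in range(params.n_trenches):
        o, g = simulate_trench(params, trench_id=tid)
        obs_parts.append(o)
        truth = g if truth is None else truth.merge(g)
    assert truth is not None
    return pd.concat(obs_parts, ignore_index=True), truth


def simulate_population(params: SimulationParams, n0: int,
                        max_cells: int = 2_000_000) -> pd.DataFrame:
    """Well-mixed agent simulation with the trench division/lysis laws.

    No trench geometry, no eviction: every daughter is kept.  Returns a tidy
    frame (time_min, n_cells, biomass_um) sampled at the frame grid; used to
    cross-validate the deterministic birth-death model
    (:mod:`wormamp.population_model`).
    """
    if n0 < 1:
        raise ValueError("n0 must be >= 1")
    seed = params.require_seed()
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x9090)))
    p = params
    alpha = _alpha_profile(p)
    lam = _lysis_profile(p)

    n_frames = int(math.floor(p.t_total / p.frame_interval)) + 1
    frame_times = np.arange(n_frames) * p.frame_interval
    horizon = float(frame_times[-1])

    heap: list[tuple] = []  # (event_time, seq, kind, birth_time, birth_len, div_len)
    births: list[tuple[float, float]] = []  # (birth_time, birth_len)
    deaths: list[tuple[float, float]] = []  # (death_time, length_at_death)
    seq = 0

    def push(t: float, length: float) -> None:
        nonlocal seq
        if seq > max_cells:
            raise RuntimeError(
                "population exceeded max_cells; shorten t_total or lower n0")
        c = _schedule(seq, None, t, length, rng, p, alpha, lam)
        births.append((t, length))
        if c.div_time <= c.lysis_time:
            first, kind, at_death = c.div_time, "division", c.threshold
        else:
            first, kind = c.lysis_time, "lysis"
            at_death = length * math.exp(alpha.cumulative(c.lysis_time)
                                         - alpha.cumulative(t))
        if first <= horizon:
            heapq.heappush(heap, (first, c.cell_id, kind, at_death))
        seq += 1

    for _ in range(n0):
        push(0.0, float(p.div_len_mean * rng.uniform(0.5, 1.0)))

    while heap:
        t, _, kind, at_death = heapq.heappop(heap)
        deaths.append((t, at_death))
        if kind == "division":
            f = 0.5
            if p.div_asym_sd > 0:
                f = float(np.clip(rng.normal(0.5, p.div_asym_sd), 0.2, 0.8))
            push(t, f * at_death)
            push(t, (1 - f) * at_death)

    phi = np.array([alpha.cumulative(ft) for ft in frame_times])
    counts = np.empty(n_frames, dtype=int)
    biomass = np.empty(n_frames)
    b_t = np.array([b[0] for b in births])
    b_w = np.array([b[1] for b in births]) * np.exp(
        -np.array([alpha.cumulative(b[0]) for b in births]))
    order_b = np.argsort(b_t, kind="stable")
    b_t, b_w = b_t[order_b], b_w[order_b]
    if deaths:
        d_t = np.array([d[0] for d in deaths])
        d_w = np.array([d[1] for d in deaths]) * np.exp(
            -np.array([alpha.cumulative(d[0]) for d in deaths]))
        order_d = np.argsort(d_t, kind="stable")
        d_t, d_w = d_t[order_d], d_w[order_d]
    else:
        d_t = np.array([])
        d_w = np.array([])
    cb_w = np.concatenate([[0.0], np.cumsum(b_w)])
    cd_w = np.concatenate([[0.0], np.cumsum(d_w)])
    for i, ft in enumerate(frame_times):
        nb = int(np.searchsorted(b_t, ft, side="right"))
        nd = int(np.searchsorted(d_t, ft, side="right"))
        counts[i] = nb - nd
        # each alive cell's length is birth_len * exp(phi(t) - phi(birth))
        biomass[i] = math.exp(phi[i]) * (cb_w[nb] - cd_w[nd])
    return pd.DataFrame({"time_min": frame_times, "n_cells": counts,
                         "biomass_um": biomass})


# ---------------------------------------------------------------------------
# I/O

def save_params(params: SimulationParams, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclass_to_dict(params), fh, sort_keys=False)


def load_params(path, **overrides) -> SimulationParams:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    raw.update(overrides)
    return SimulationParams(**raw)


def dataclass_to_dict(params: SimulationParams) -> dict:
    return {k: getattr(params, k) for k in SimulationParams.__dataclass_fields__}


def with_seed(params: SimulationParams, seed: int) -> SimulationParams:
    return replace(params, seed=seed)
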