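"""Lineage reconstruction from per-frame trench observations.

Reconstructs cell tracks, divisions, lyses and evictions from the tabular
observations emitted by :mod:`wormamp.trench_sim` (or by a segmentation
pipeline producing the same dialect).  Because trench cells are single-file
and cannot swap places, frame-to-frame correspondence is an order-preserving
assignment: each cell in frame ``t`` maps to one successor (growth), two
consecutive successors (division), or none (lysis / eviction), and every cell
in frame ``t+1`` must descend from some cell in frame ``t``.  The optimal
assignment is found by dynamic programming over the ranked sequences with a
log-length prediction cost.

Cost model
----------
For a cell of observed length ``L`` and a running elongation-rate estimate
``a``, the predicted next length is ``L * exp(a * dt)``.  Mapping it to a
successor of length ``L'`` costs ``|log(L'/L_pred)| + gamma * |dc|`` where
``dc`` is the centroid displacement; mapping it to two successors costs the
same with ``L'`` the daughter-length sum (rejected outright if the sum is
more than ``div_tol`` away from the prediction).  Terminating a track costs a
fixed ``term_cost``.  Ties are broken toward growth, then division, then
termination (the most parsimonious history).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trench_sim import LINEAGE_COLUMNS

__all__ = ["TrackerConfig", "LineageRecord", "track_trench", "track_experiment",
           "classify_fate", "assignment_accuracy", "forests_equal"]

_GROWTH, _DIVISION, _TERM = 0, 1, 2


@dataclass(frozen=True)
class TrackerConfig:
    """Tunable knobs of the order-preserving tracker.

    eviction_margin defaults to one typical cell length (the division
    threshold scale): a disappearing distal cell whose far edge is within
    this distance of the open end is deemed evicted rather than lysed.
    """

    gamma: float = 0.0           # weight of the centroid term (1/um); off by
                                 # default: after a lysis the true successor
                                 # shifts toward the dead end, so centroid
                                 # displacement penalises the correct match
    div_tol: float = 0.15        # daughter-sum tolerance around prediction
    term_cost: float = 0.5       # cost of ending a track mid-movie (lysis);
                                 # kept below log 2 so that a true lysis next
                                 # to a true division is never cheaper to read
                                 # as a halving "growth"
    div_evict_pen: float = 0.35  # penalty of the "distal cell divided and one
                                 # daughter left before being seen" hypothesis
                                 # (only offered when the trench is full)
    evict_cost: float = 0.25     # cheaper termination for a distal cell at the
                                 # open end of a full trench (eviction)
    div_bias: float = 1e-6       # tie-break: growth < division < termination
    eviction_margin: float = 4.5  # um, ~ one cell length
    trench_len: float = 75.0
    alpha_ema: float = 0.05      # EMA weight of the global rate estimate
    rate_ema: float = 0.5        # EMA weight of each track's own rate
    rate_gate: float = 0.3       # |log ratio - prediction| above this is not
                                 # ordinary growth; the track rate is frozen
    alpha_init: float | None = None  # None: estimate from the data

    @classmethod
    def from_params(cls, params, **overrides) -> "TrackerConfig":
        """Geometry-consistent config for tracking simulator output."""
        kw = dict(trench_len=params.trench_len,
                  eviction_margin=params.div_len_mean)
        kw.update(overrides)
        return cls(**kw)


@dataclass
class LineageRecord:
    cell_id: str
    trench_id: int
    parent_id: str | None
    birth_frame: int
    last_frame: int
    fate: str


class _Track:
    __slots__ = ("rec", "obs", "rate")

    def __init__(self, rec: LineageRecord, rate: float):
        self.rec = rec
        self.obs: list[tuple[int, int]] = []  # (frame, rank)
        self.rate = rate  # per-track elongation-rate estimate (1/min)


def _initial_alpha(frames: list[pd.DataFrame], dt: float) -> float:
    """Robust startup growth-rate guess: median same-rank log length ratio
    between consecutive frames with unchanged cell count."""
    ratios: list[float] = []
    for a, b in zip(frames[:-1], frames[1:]):
        if len(a) == len(b) and len(a) > 0:
            r = np.log(b["length_um"].to_numpy() / a["length_um"].to_numpy()) / dt
            ratios.extend(r.tolist())
        if len(ratios) > 2000:
            break
    if not ratios:
        return 0.0
    return float(np.median(ratios))


def _pair_dp(lens_a, cents_a, lens_b, cents_b, pred, cfg: TrackerConfig,
             full_trench: bool = False):
    """Order-preserving DP.  ``pred`` holds the predicted next-frame length of
    every current cell.  Returns per-a assignment: list of lists of b indices
    (empty = terminated, one = growth, two = division)."""
    m, n = len(lens_a), len(lens_b)
    INF = math.inf
    # D[i][j]: min cost assigning first i a-cells to first j b-cells
    D = np.full((m + 1, n + 1), INF)
    choice = np.full((m + 1, n + 1), -1, dtype=np.int8)
    D[0, 0] = 0.0
    for i in range(1, m + 1):
        for j in range(0, n + 1):
            best, arg = INF, -1
            # termination (preference order: growth, division, termination —
            # evaluate in reverse so later, preferred options win ties)
            c = D[i - 1, j] + cfg.term_cost
            if c <= best:
                best, arg = c, _TERM
            if j >= 2:
                s = lens_b[j - 2] + lens_b[j - 1]
                if abs(s / pred[i - 1] - 1.0) <= cfg.div_tol:
                    mid = 0.5 * (cents_b[j - 2] + cents_b[j - 1])
                    c = (D[i - 1, j - 2] + abs(math.log(s / pred[i - 1]))
                         + cfg.gamma * abs(mid - cents_a[i - 1]) + cfg.div_bias)
                    if c <= best:
                        best, arg = c, _DIVISION
            if j >= 1:
                c_len = abs(math.log(lens_b[j - 1] / pred[i - 1]))
                if full_trench and i == m:
                    # the distal cell of a full trench may have divided with
                    # one daughter evicted before ever being observed; its
                    # survivor then looks like a halving
                    c_len = min(c_len,
                                abs(math.log(lens_b[j - 1] / (0.5 * pred[i - 1])))
                                + cfg.div_evict_pen)
                c = (D[i - 1, j - 1] + c_len
                     + cfg.gamma * abs(cents_b[j - 1] - cents_a[i - 1]))
                if c <= best:
                    best, arg = c, _GROWTH
            D[i, j] = best
            choice[i, j] = arg
    # trailing cells may terminate at eviction cost when their far edge is
    # near the open end (cells leave a full trench only from there)
    edge = cents_a + 0.5 * lens_a
    evictable = edge >= cfg.trench_len - cfg.eviction_margin
    suffix = np.zeros(m + 1)
    for i in range(m - 1, -1, -1):
        suffix[i] = suffix[i + 1] + (cfg.evict_cost if evictable[i] else cfg.term_cost)
    totals = D[:, n] + suffix
    if not np.isfinite(totals).any():
        return None
    i_star = int(np.argmin(totals))
    # backtrack
    out: list[list[int]] = [[] for _ in range(m)]
    i, j = i_star, n
    while i > 0:
        c = choice[i, j]
        if c == _GROWTH:
            out[i - 1] = [j - 1]
            j -= 1
        elif c == _DIVISION:
            out[i - 1] = [j - 2, j - 1]
            j -= 2
        i -= 1
    return out


def classify_fate(last_len: float, last_centroid: float, distal_all_terminated: bool,
                  cfg: TrackerConfig) -> str:
    """Fate of a track that disappeared mid-movie.

    Evicted: the cell (and everything distal to it) left via the open end —
    recognised by its far edge lying within ``eviction_margin`` of the trench
    end with no surviving distal neighbour.  Otherwise lysed.
    """
    distal_edge = last_centroid + 0.5 * last_len
    if distal_all_terminated and distal_edge >= cfg.trench_len - cfg.eviction_margin:
        return "evicted"
    return "lysed"


def track_trench(observations: pd.DataFrame, config: TrackerConfig | None = None,
                 last_frame: int | None = None,
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Track one trench.  Returns (lineage table, assignments).

    ``observations`` must hold a single trench_id, sorted by frame with
    contiguous ranks in each frame.  Missing frames split all live tracks
    with fate ``censored`` (the gap destroys identifiability), and cells
    after the gap start fresh root tracks.  ``last_frame`` is the final frame
    of the whole movie: a trench whose observations stop earlier emptied out,
    and its remaining tracks are terminated (lysed/evicted), not censored.

    Each track carries its own elongation-rate estimate (EMA of its recent
    log length ratios, gated against hidden-event jumps), used to predict the
    next length in the assignment cost.
    """
    cfg = config or TrackerConfig()
    obs = observations.sort_values(["frame", "rank"]).reset_index(drop=True)
    trench_ids = obs["trench_id"].unique()
    if len(trench_ids) != 1:
        raise ValueError("track_trench expects a single trench; use track_experiment")
    tid = trench_ids[0]

    frame_nos = sorted(obs["frame"].unique())
    by_frame = {f: g.reset_index(drop=True) for f, g in obs.groupby("frame")}
    for f, g in by_frame.items():
        if not (g["rank"].to_numpy() == np.arange(len(g))).all():
            raise ValueError(f"frame {f}: ranks must be contiguous 0..k")

    if len(frame_nos) == 0:
        return (pd.DataFrame(columns=LINEAGE_COLUMNS),
                pd.DataFrame(columns=["trench_id", "frame", "rank", "cell_id"]))
    if last_frame is None:
        last_frame = frame_nos[-1]

    dts = np.diff(obs.sort_values("frame")["time_min"].unique())
    dt = float(np.median(dts)) if len(dts) else 1.0
    frames_list = [by_frame[f] for f in frame_nos]
    alpha = cfg.alpha_init if cfg.alpha_init is not None else _initial_alpha(frames_list, dt)

    records: list[LineageRecord] = []
    assigns: list[tuple] = []
    counter = 0

    def new_track(frame: int, rate: float) -> _Track:
        nonlocal counter
        rec = LineageRecord(f"t{tid}c{counter}", tid, None, frame, frame, "censored")
        counter += 1
        records.append(rec)
        return _Track(rec, rate)

    def observe(tr: _Track, frame: int, rank: int) -> None:
        tr.obs.append((frame, rank))
        tr.rec.last_frame = frame
        assigns.append((tid, frame, rank, tr.rec.cell_id))

    live: list[_Track] = []
    first = frame_nos[0]
    for rank in range(len(by_frame[first])):
        tr = new_track(first, alpha)
        observe(tr, first, rank)
        live.append(tr)

    for prev_f, next_f in zip(frame_nos[:-1], frame_nos[1:]):
        a = by_frame[prev_f]
        b = by_frame[next_f]
        if next_f != prev_f + 1:
            # gap: close everything as censored, restart roots
            for tr in live:
                tr.rec.fate = "censored"
            live = []
            for rank in range(len(b)):
                tr = new_track(next_f, alpha)
                observe(tr, next_f, rank)
                live.append(tr)
            continue
        lens_a = a["length_um"].to_numpy()
        cents_a = a["centroid_um"].to_numpy()
        lens_b = b["length_um"].to_numpy()
        cents_b = b["centroid_um"].to_numpy()
        step_dt = float(b["time_min"].iloc[0] - a["time_min"].iloc[0])
        pred = lens_a * np.exp(np.array([tr.rate for tr in live]) * step_dt)
        full = float(lens_a.sum()) >= cfg.trench_len - cfg.eviction_margin
        if len(lens_a) == 0:
            mapping: list[list[int]] = []
        else:
            mapping = _pair_dp(lens_a, cents_a, lens_b, cents_b, pred, cfg, full)
            if mapping is None:
                # no order-preserving history within div_tol; relax the
                # division gate rather than dropping the frame pair
                relaxed = TrackerConfig(**{**cfg.__dict__, "div_tol": math.inf})
                mapping = _pair_dp(lens_a, cents_a, lens_b, cents_b, pred, relaxed, full)
        next_live: list[_Track] = []
        terminated_mask = [len(mp) == 0 for mp in mapping]
        # a terminated track is eligible for eviction only if every cell
        # distal to it also terminated
        distal_clear = [False] * len(mapping)
        clear = True
        for i in range(len(mapping) - 1, -1, -1):
            distal_clear[i] = clear and terminated_mask[i]
            clear = clear and terminated_mask[i]
        growth_ratios: list[float] = []
        for i, tr in enumerate(live):
            mp = mapping[i]
            if len(mp) == 0:
                tr.rec.fate = classify_fate(lens_a[i], cents_a[i], distal_clear[i], cfg)
            elif len(mp) == 1:
                j = mp[0]
                observe(tr, next_f, j)
                r = math.log(lens_b[j] / lens_a[i]) / step_dt
                if abs(r - tr.rate) * step_dt <= cfg.rate_gate:
                    tr.rate = (1 - cfg.rate_ema) * tr.rate + cfg.rate_ema * r
                    growth_ratios.append(r)
                next_live.append(tr)
            else:
                tr.rec.fate = "divided"
                for j in mp:
                    child = new_track(next_f, tr.rate)  # daughters inherit rate
                    child.rec.parent_id = tr.rec.cell_id
                    observe(child, next_f, j)
                    next_live.append(child)
        # unassigned b cells (only possible when the trench was empty)
        assigned = {j for mp in mapping for j in mp}
        for j in range(len(lens_b)):
            if j not in assigned:
                tr = new_track(next_f, alpha)
                observe(tr, next_f, j)
                next_live.append(tr)
        next_live.sort(key=lambda t: t.obs[-1][1])
        live = next_live
        if growth_ratios:
            # global estimate seeds new roots and fresh daughters
            alpha = (1 - cfg.alpha_ema) * alpha + cfg.alpha_ema * float(np.mean(growth_ratios))

    if frame_nos[-1] < last_frame:
        # the trench emptied before the movie ended: everything terminated
        g = by_frame[frame_nos[-1]]
        lens = g["length_um"].to_numpy()
        cents = g["centroid_um"].to_numpy()
        for i, tr in enumerate(live):
            tr.rec.fate = classify_fate(lens[i], cents[i], True, cfg)
    else:
        for tr in live:
            tr.rec.fate = "censored"
            tr.rec.last_frame = frame_nos[-1]

    lineage = pd.DataFrame(
        [(r.cell_id, r.trench_id, r.parent_id, r.birth_frame, r.last_frame, r.fate)
         for r in records], columns=LINEAGE_COLUMNS)
    assignments = pd.DataFrame(assigns, columns=["trench_id", "frame", "rank", "cell_id"])
    return lineage, assignments


def track_experiment(observations: pd.DataFrame, config: TrackerConfig | None = None,
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Track every trench in an observation table."""
    last_frame = int(observations["frame"].max())
    lin_parts, as_parts = [], []
    for _, g in observations.groupby("trench_id"):
        lin, asg = track_trench(g, config, last_frame=last_frame)
        lin_parts.append(lin)
        as_parts.append(asg)
    return (pd.concat(lin_parts, ignore_index=True),
            pd.concat(as_parts, ignore_index=True))


# ---------------------------------------------------------------------------
# comparison against ground truth

def _links(lineage: pd.DataFrame, assignments: pd.DataFrame) -> dict:
    """Map each observation (trench, frame, rank) to its predecessor
    observation: the same track's previous frame, or the parent's last
    observation for a newborn."""
    key = {}
    last_obs: dict[str, tuple] = {}
    rec_parent = lineage.set_index("cell_id")["parent_id"].to_dict()
    ordered = assignments.sort_values(["frame", "rank"])
    for row in ordered.itertuples(index=False):
        k = (row.trench_id, row.frame, row.rank)
        cid = row.cell_id
        if cid in last_obs:
            key[k] = last_obs[cid]
        else:
            par = rec_parent.get(cid)
            key[k] = last_obs.get(par) if par is not None and not pd.isna(par) else None
        last_obs[cid] = k
    return key


def assignment_accuracy(truth_lineage: pd.DataFrame, truth_assign: pd.DataFrame,
                        lineage: pd.DataFrame, assign: pd.DataFrame) -> float:
    """Fraction of observations whose predecessor link matches ground truth
    (over observations where the truth defines a predecessor)."""
    t_links = _links(truth_lineage, truth_assign)
    p_links = _links(lineage, assign)
    num = den = 0
    for k, v in t_links.items():
        if v is None:
            continue
        den += 1
        if p_links.get(k) == v:
            num += 1
    if den == 0:
        raise ValueError("no linked observations to score")
    return num / den


def forests_equal(truth_lineage: pd.DataFrame, truth_assign: pd.DataFrame,
                  lineage: pd.DataFrame, assign: pd.DataFrame,
                  compare_fates: bool = True) -> bool:
    """True iff the two lineage forests are identical: same partition of
    observations into tracks, same parent links, same fates."""
    t_links = _links(truth_lineage, truth_assign)
    p_links = _links(lineage, assign)
    if t_links != p_links:
        return False
    if not compare_fates:
        return True
    t_fate = _fate_by_first_obs(truth_lineage, truth_assign)
    p_fate = _fate_by_first_obs(lineage, assign)
    return t_fate == p_fate


def _fate_by_first_obs(lineage: pd.DataFrame, assign: pd.DataFrame) -> dict:
    first = (assign.sort_values(["frame", "rank"])
             .groupby("cell_id").first().reset_index())
    fate = lineage.set_index("cell_id")["fate"].to_dict()
    return {(r.trench_id, r.frame, r.rank): fate[r.cell_id]
            for r in first.itertuples(index=False)}
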