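"""Single-molecule tracking: linking, condensate membership, and MSD.

The analysis chain mirrors the live-cell workflow for HaloTag-fused
transcription factors:

1. per-frame localizations are linked into gap-free trajectories by a
   globally optimal (Hungarian) frame-pair assignment with a hard distance
   cap (default 400 nm, no gaps);
2. a localization is *inside a condensate* when strictly more than
   ``min_neighbors`` (default 4) other localizations fall within ``radius``
   (default 7.5 nm) of it, pooled over the total imaging time; flagged points
   are partitioned into condensate clusters by single linkage at the same
   radius;
3. a trajectory inherits condensate status when more than half of its points
   are flagged;
4. displacement statistics are time-averaged per trajectory and then averaged
   across trajectories (mean ± SD per lag).
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .io import (
    ConsistencyError,
    Localization,
    RunConfig,
    Trajectory,
    UndefinedValueError,
)

__all__ = [
    "CondensateFlagSet",
    "MSDCurve",
    "link_trajectories",
    "filter_trajectories",
    "flag_condensate_localizations",
    "classify_trajectories",
    "fraction_in_condensates",
    "msd_curve",
    "rms_displacement",
    "mean_displacement",
]


@dataclass
class CondensateFlagSet:
    """Per-localization condensate-membership flags and cluster labels.

    ``cluster_id[i] >= 0`` iff ``in_condensate[i]``; clusters are the
    connected components of flagged points under the radius relation.
    """

    localizations: tuple[Localization, ...]
    in_condensate: np.ndarray  # bool, per localization
    cluster_id: np.ndarray     # int, −1 for unflagged points
    radius_nm: float
    min_neighbors: int

    def __post_init__(self) -> None:
        if not np.array_equal(self.cluster_id >= 0, self.in_condensate):
            raise ValueError("cluster_id >= 0 must hold exactly for flagged points")


@dataclass
class MSDCurve:
    """Across-trajectory mean ± SD of the time-averaged MSD per lag.

    ``lags_ms`` ascending; ``msd_mean``/``msd_sd`` in µm²; ``n_trajectories``
    counts the trajectories contributing at each lag.  The SD is NaN where
    fewer than two trajectories contribute.
    """

    lags_ms: np.ndarray
    msd_mean: np.ndarray
    msd_sd: np.ndarray
    n_trajectories: np.ndarray


# ---------------------------------------------------------------------------
# linking


def link_trajectories(
    locs: list[Localization],
    max_link_distance: float | None = None,
    config: RunConfig | None = None,
) -> list[Trajectory]:
    """Link localizations into gap-free trajectories (Hungarian assignment).

    Localizations are grouped by ``(cell_id, channel)`` and linked per
    consecutive frame pair with a minimum-total-cost one-to-one assignment
    restricted to pairs within ``max_link_distance`` (nm).  Unassigned points
    terminate or start trajectories; every localization belongs to exactly
    one trajectory and no link spans more than one frame.
    """
    config = config or RunConfig()
    cap = config.max_link_distance_nm if max_link_distance is None else max_link_distance
    groups: dict[tuple[int, int], list[Localization]] = defaultdict(list)
    for p in locs:
        groups[(p.cell_id, p.channel)].append(p)

    trajectories: list[Trajectory] = []
    next_id = 0
    for key in sorted(groups):
        by_frame: dict[int, list[Localization]] = defaultdict(list)
        for p in groups[key]:
            by_frame[p.frame].append(p)
        frames = sorted(by_frame)
        # open chains: list of point lists whose last frame is the previous one
        open_chains: list[list[Localization]] = []
        prev_frame: int | None = None
        for f in frames:
            pts = by_frame[f]
            if prev_frame is not None and f == prev_frame + 1 and open_chains:
                links = _assign_frame_pair(
                    [c[-1] for c in open_chains], pts, cap
                )
            else:
                # gap in acquisition or first frame: close everything
                links = {}
                trajectories.extend(
                    Trajectory(next_id + i, c) for i, c in enumerate(open_chains)
                )
                next_id += len(open_chains)
                open_chains = []
            new_chains: list[list[Localization]] = []
            claimed = set(links.values())
            for i, chain in enumerate(open_chains):
                if i in links:
                    chain.append(pts[links[i]])
                    new_chains.append(chain)
                else:
                    trajectories.append(Trajectory(next_id, chain))
                    next_id += 1
            for j, p in enumerate(pts):
                if j not in claimed:
                    new_chains.append([p])
            open_chains = new_chains
            prev_frame = f
        trajectories.extend(
            Trajectory(next_id + i, c) for i, c in enumerate(open_chains)
        )
        next_id += len(open_chains)
    return trajectories


def _assign_frame_pair(
    prev: list[Localization], curr: list[Localization], cap: float
) -> dict[int, int]:
    """Minimum-cost one-to-one matching between two frames under a hard cap.

    Returns ``{prev_index: curr_index}``.  Pairs farther apart than ``cap``
    are forbidden; squared Euclidean distance is the cost, which gives the
    same optimum ranking as plain distance for the feasible set and keeps the
    matrix well scaled.
    """
    if not prev or not curr:
        return {}
    a = np.array([(p.x, p.y) for p in prev])
    b = np.array([(p.x, p.y) for p in curr])
    d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)
    cap2 = cap * cap
    feasible = d2 <= cap2
    if not feasible.any():
        return {}
    # Forbidden links get a cost larger than any feasible total so the solver
    # only uses them when structurally unavoidable; such links are discarded.
    big = cap2 * (max(len(prev), len(curr)) + 1) + 1.0
    cost = np.where(feasible, d2, big)
    rows, cols = linear_sum_assignment(cost)
    return {int(r): int(c) for r, c in zip(rows, cols) if feasible[r, c]}


def filter_trajectories(
    trajs: list[Trajectory],
    min_points: int | None = None,
    min_duration_ms: float | None = None,
    config: RunConfig | None = None,
) -> list[Trajectory]:
    """Keep trajectories with at least ``min_points`` localizations AND a
    duration of at least ``min_duration_ms``; order is preserved.

    Defaults (5 points, 80 ms) select the trajectories that enter the
    displacement statistics.
    """
    config = config or RunConfig()
    min_points = config.min_track_points if min_points is None else min_points
    if min_points < 1:
        raise ValueError("min_points must be >= 1")
    min_dur = config.min_track_duration_ms if min_duration_ms is None else min_duration_ms
    dt = config.frame_interval_ms
    return [t for t in trajs if len(t) >= min_points and t.duration_ms(dt) >= min_dur]


# ---------------------------------------------------------------------------
# condensate membership


def flag_condensate_localizations(
    locs: list[Localization],
    radius: float = 7.5,
    min_neighbors: int = 4,
    strict: bool = True,
) -> CondensateFlagSet:
    """Flag localizations inside condensates by the pooled density rule.

    All localizations of one cell/channel are pooled across the total imaging
    time; a localization is flagged iff strictly more than ``min_neighbors``
    *other* localizations lie within ``radius`` nm of it (``strict=False``
    relaxes the comparison to >=).  Flagged points are partitioned into
    clusters by single linkage at the same radius.
    """
    n = len(locs)
    if n == 0:
        return CondensateFlagSet((), np.zeros(0, bool), np.full(0, -1), radius,
                                 min_neighbors)
    xy = np.array([(p.x, p.y) for p in locs])
    tree = cKDTree(xy)
    counts = np.array(tree.query_ball_point(xy, r=radius, return_length=True))
    counts = counts - 1  # self is always within radius; exclude it
    flagged = counts > min_neighbors if strict else counts >= min_neighbors

    cluster_id = np.full(n, -1, dtype=int)
    idx = np.flatnonzero(flagged)
    if idx.size:
        sub = cKDTree(xy[idx])
        pairs = sub.query_pairs(radius, output_type="ndarray")
        adj = csr_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])),
            shape=(idx.size, idx.size),
        )
        _, labels = connected_components(adj, directed=False)
        # renumber components in order of first appearance for determinism
        order: dict[int, int] = {}
        for lab in labels:
            order.setdefault(int(lab), len(order))
        cluster_id[idx] = [order[int(lab)] for lab in labels]
    return CondensateFlagSet(tuple(locs), flagged, cluster_id, radius, min_neighbors)


def classify_trajectories(
    trajs: list[Trajectory],
    flags: CondensateFlagSet,
    member_fraction: float = 0.5,
) -> dict[int, str]:
    """Classify each trajectory as ``"condensate"`` or ``"free"``.

    A trajectory is condensate-resident iff the fraction of its localizations
    flagged as in-condensate exceeds ``member_fraction``.  ``flags`` must have
    been computed on the same localizations the trajectories reference.
    """
    lookup = {id(p): i for i, p in enumerate(flags.localizations)}
    by_key = defaultdict(list)
    for i, p in enumerate(flags.localizations):
        by_key[(p.frame, p.x, p.y, p.channel, p.cell_id)].append(i)
    out: dict[int, str] = {}
    for t in trajs:
        flagged = 0
        for p in t.points:
            i = lookup.get(id(p))
            if i is None:
                cands = by_key.get((p.frame, p.x, p.y, p.channel, p.cell_id))
                if not cands:
                    raise ConsistencyError(
                        f"trajectory {t.id} references a localization absent from "
                        "the flag set"
                    )
                i = cands[0]
            flagged += bool(flags.in_condensate[i])
        out[t.id] = "condensate" if flagged / len(t) > member_fraction else "free"
    return out


def fraction_in_condensates(flags: CondensateFlagSet) -> float:
    """Fraction of localizations flagged as inside condensates, in [0, 1]."""
    n = len(flags.localizations)
    if n == 0:
        raise UndefinedValueError("fraction undefined for an empty flag set")
    return float(flags.in_condensate.sum()) / n


# ---------------------------------------------------------------------------
# displacement statistics


def _time_averaged_msd(xy_nm: np.ndarray, max_lag_frames: int) -> np.ndarray:
    """Time-averaged MSD (µm²) of one track for lags 1..max_lag_frames.

    Entry k−1 is the mean over all ordered point pairs (i, i+k); NaN where the
    track is too short to contribute.
    """
    n = len(xy_nm)
    out = np.full(max_lag_frames, np.nan)
    xy_um = xy_nm / 1000.0
    for k in range(1, min(max_lag_frames, n - 1) + 1):
        d = xy_um[k:] - xy_um[:-k]
        out[k - 1] = float(np.mean((d * d).sum(axis=1)))
    return out


def msd_curve(
    trajs: list[Trajectory],
    frame_interval_ms: float = 20.0,
    max_lag_ms: float | None = None,
) -> MSDCurve:
    """Ensemble MSD curve: per-trajectory time average, then mean ± SD across
    trajectories at each lag.

    Lags run from one frame interval up to ``max_lag_ms`` (default: the
    longest trajectory).  At each lag only trajectories long enough to
    contribute are averaged; the SD is NaN with fewer than two contributors.
    """
    if not trajs:
        return MSDCurve(np.zeros(0), np.zeros(0), np.zeros(0), np.zeros(0, int))
    longest = max(t.n_steps for t in trajs)
    if max_lag_ms is None:
        max_lag = longest
    else:
        max_lag = min(longest, int(round(max_lag_ms / frame_interval_ms)))
    max_lag = max(max_lag, 1)
    per_traj = np.vstack([_time_averaged_msd(t.xy(), max_lag) for t in trajs])
    n_contrib = np.sum(~np.isnan(per_traj), axis=0)
    import warnings

    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(per_traj, axis=0)
        sd = np.where(
            n_contrib >= 2, np.nanstd(per_traj, axis=0, ddof=1), np.nan
        )
    lags = frame_interval_ms * np.arange(1, max_lag + 1)
    keep = n_contrib > 0
    return MSDCurve(lags[keep], mean[keep], sd[keep], n_contrib[keep].astype(int))


def _lag_index(curve: MSDCurve, lag_ms: float) -> int:
    hits = np.flatnonzero(np.isclose(curve.lags_ms, lag_ms))
    if not hits.size:
        raise KeyError(f"lag {lag_ms} ms not present in curve lags {curve.lags_ms}")
    return int(hits[0])


def rms_displacement(curve: MSDCurve, lag_ms: float) -> float:
    """Root-mean-square displacement (nm) at one lag of an MSD curve."""
    msd_um2 = curve.msd_mean[_lag_index(curve, lag_ms)]
    return math.sqrt(msd_um2) * 1000.0


def mean_displacement(
    trajs: list[Trajectory], lag_ms: float, frame_interval_ms: float = 20.0
) -> float:
    """Mean displacement magnitude (nm) over all point pairs at one lag."""
    k = int(round(lag_ms / frame_interval_ms))
    if k < 1:
        raise ValueError("lag must be at least one frame interval")
    mags: list[np.ndarray] = []
    for t in trajs:
        xy = t.xy()
        if len(xy) > k:
            d = xy[k:] - xy[:-k]
            mags.append(np.hypot(d[:, 0], d[:, 1]))
    if not mags:
        raise UndefinedValueError(f"no trajectory long enough for lag {lag_ms} ms")
    return float(np.mean(np.concatenate(mags)))
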