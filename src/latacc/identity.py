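"""Cultural identities as latitudes of acceptance, and the attitude kernel.

An agent's stance on one cultural worldview is an *acceptance segment*
``[b, B]`` on the position axis ``[-1, 1]`` containing its most acceptable
position ``a`` (``b <= a <= B``).  Positions strictly inside the segment are
fully acceptable (attitude 1); positions outside are evaluated through a
sigmoid that falls from 0 at the bound toward an asymptote at -1, and falls
faster when the margin on that side (``a - b`` below, ``B - a`` above) is
narrower.  Attitudes about segments and whole identities are grid averages
of this kernel, and a population's pairwise attitudes aggregate into
group-level means and standard deviations used for survey calibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Fixed worldview ordering: Muslim, Christian, areligious.  The order is
#: part of the model contract (deterministic iteration and argmax
#: tie-breaking), not merely cosmetic.
DEFAULT_WORLDVIEWS: tuple[str, ...] = ("M", "C", "A")

AGENT_TYPES = ("inclusive", "exclusive", "terrorist")


class UnresolvableSegmentError(ValueError):
    """Raised when no grid point falls strictly inside a target segment.

    The segment is narrower than the grid spacing, so the attitude about it
    is undefined at resolution D; the caller may raise D.
    """


@dataclass(frozen=True)
class AcceptanceSegment:
    """One worldview's acceptance segment ``[lower_bound, upper_bound]``
    with most acceptable position ``ma_position`` inside it."""

    lower_bound: float  # b
    ma_position: float  # a
    upper_bound: float  # B

    def __post_init__(self) -> None:
        b, a, B = self.lower_bound, self.ma_position, self.upper_bound
        if not (-1.0 <= b <= a <= B <= 1.0):
            raise ValueError(
                f"acceptance segment requires -1 <= b <= a <= B <= 1, "
                f"got b={b}, a={a}, B={B}"
            )

    @property
    def margin_l(self) -> float:
        """Width of the lower margin of acceptance, ``a - b``."""
        return self.ma_position - self.lower_bound

    @property
    def margin_h(self) -> float:
        """Width of the higher margin of acceptance, ``B - a``."""
        return self.upper_bound - self.ma_position

    @property
    def width(self) -> float:
        return self.upper_bound - self.lower_bound

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.lower_bound, self.ma_position, self.upper_bound)


@dataclass(frozen=True)
class CulturalIdentity:
    """An agent's acceptance segments, one per worldview.

    ``worldviews`` fixes the iteration/tie-break order; ``segments`` must
    contain exactly those keys.
    """

    segments: dict[str, AcceptanceSegment]
    worldviews: tuple[str, ...] = DEFAULT_WORLDVIEWS

    def __post_init__(self) -> None:
        if len(self.worldviews) < 2:
            raise ValueError("at least two worldviews are required")
        if len(set(self.worldviews)) != len(self.worldviews):
            raise ValueError("worldview labels must be unique")
        if set(self.segments) != set(self.worldviews):
            raise ValueError(
                f"identity must define exactly the worldviews {self.worldviews}, "
                f"got {sorted(self.segments)}"
            )

    def segment(self, worldview: str) -> AcceptanceSegment:
        return self.segments[worldview]

    def ma_positions(self) -> np.ndarray:
        return np.array(
            [self.segments[k].ma_position for k in self.worldviews], dtype=float
        )

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(b, a, B) arrays in worldview order, each of shape (K,)."""
        trips = [self.segments[k].as_tuple() for k in self.worldviews]
        arr = np.array(trips, dtype=float)
        return arr[:, 0], arr[:, 1], arr[:, 2]


@dataclass(frozen=True)
class Agent:
    agent_id: str
    identity: CulturalIdentity
    weight: float
    type_tag: str = "inclusive"

    def __post_init__(self) -> None:
        if self.type_tag not in AGENT_TYPES:
            raise ValueError(f"unknown agent type {self.type_tag!r}")
        if not self.weight > 0:
            raise ValueError("agent weight must be positive")
        if self.weight > 1:
            raise ValueError("agent weight must be at most 1")
        if self.type_tag != "terrorist":
            # population agents must find at least one worldview positively
            # acceptable at their preferred position
            if not any(
                s.ma_position > 0 for s in self.identity.segments.values()
            ):
                raise ValueError(
                    f"agent {self.agent_id!r}: population agents need a "
                    "positive m.a.position on at least one worldview"
                )

    @property
    def is_terrorist(self) -> bool:
        return self.type_tag == "terrorist"


@dataclass(frozen=True)
class Population:
    """Ordered, weighted list of agents.

    Non-terrorist weights must sum to 1; terrorist agents (if embedded) sit
    outside the normalization and are excluded from group statistics.
    """

    agents: tuple[Agent, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "agents", tuple(self.agents))
        ids = [ag.agent_id for ag in self.agents]
        if len(set(ids)) != len(ids):
            raise ValueError("agent ids must be unique")
        total = sum(ag.weight for ag in self.non_terrorists)
        if self.non_terrorists and abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"non-terrorist weights must sum to 1, got {total!r}"
            )

    @property
    def non_terrorists(self) -> tuple[Agent, ...]:
        return tuple(ag for ag in self.agents if not ag.is_terrorist)

    @property
    def agent_ids(self) -> list[str]:
        return [ag.agent_id for ag in self.agents]

    @property
    def worldviews(self) -> tuple[str, ...]:
        return self.agents[0].identity.worldviews

    def __len__(self) -> int:
        return len(self.agents)

    def __iter__(self):
        return iter(self.agents)

    def identity_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(b, a, B) arrays of shape (N, K) in agent then worldview order."""
        b, a, B = zip(*(ag.identity.as_arrays() for ag in self.agents))
        return np.array(b), np.array(a), np.array(B)


@dataclass(frozen=True)
class PositionGrid:
    """Regular grid of D positions on [-1, 1], endpoints included."""

    resolution: int = 400

    def __post_init__(self) -> None:
        if self.resolution < 2:
            raise ValueError("grid needs at least 2 points")

    @property
    def points(self) -> np.ndarray:
        return np.linspace(-1.0, 1.0, self.resolution)

    @property
    def spacing(self) -> float:
        return 2.0 / (self.resolution - 1)


@dataclass(frozen=True)
class AttitudeMatrix:
    """Pairwise attitudes omega[i, j] = attitude of agent i about agent j."""

    values: np.ndarray
    agent_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "agent_ids", tuple(self.agent_ids))
        n = len(self.agent_ids)
        if v.shape != (n, n):
            raise ValueError("matrix shape must match agent id count")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("self-attitudes must equal 1")
        if np.any(v < -1 - 1e-12) or np.any(v > 1 + 1e-12):
            raise ValueError("attitudes must lie in [-1, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.agent_ids), columns=list(self.agent_ids)
        )

    def to_csv(self, path, decimals: int | None = None) -> None:
        """Write as CSV with agent-id header row/column.

        ``decimals=2`` gives the compact display form; default keeps full
        precision.
        """
        frame = self.to_frame()
        if decimals is not None:
            frame = frame.round(decimals)
        frame.to_csv(path, float_format=None)


@dataclass(frozen=True)
class GroupAttitudeStats:
    """Weighted group-to-group attitude means/SDs and group weight fractions.

    ``mean.loc[G, H]`` is the attitude of group G about group H.  Cells for
    empty groups are NaN (undefined, not zero).
    """

    mean: pd.DataFrame
    sd: pd.DataFrame
    fraction: pd.Series

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(self.mean.index)

    def to_csv(self, path, decimals: int | None = None) -> None:
        mean = self.mean if decimals is None else self.mean.round(decimals)
        sd = self.sd if decimals is None else self.sd.round(decimals)
        long = pd.concat({"mean": mean, "sd": sd}, names=["stat", "group"])
        long.to_csv(path)

    def to_dict(self) -> dict:
        return {
            "groups": list(self.groups),
            "mean": self.mean.to_numpy().tolist(),
            "sd": self.sd.to_numpy().tolist(),
            "fraction": {g: float(self.fraction[g]) for g in self.groups},
        }


# ---------------------------------------------------------------------------
# Attitude kernel
# ---------------------------------------------------------------------------

def _position_attitude_arrays(b, a, B, p) -> np.ndarray:
    """Vectorized single-position attitude; inputs broadcast together.

    1 strictly inside (b, B); exactly 0 at either bound; tanh(y/2) outside,
    with y measuring signed distance past the bound in units of the margin
    on that side.  A zero-width margin gives the limit value -1 beyond it.
    """
    b, a, B, p = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (b, a, B, p))
    )
    inside = (p > b) & (p < B)
    below = p < b
    above = p > B
    margin_l = a - b
    margin_h = B - a
    with np.errstate(divide="ignore", invalid="ignore"):
        y_lo = 1.0 + (p - a) / margin_l
        y_hi = 1.0 + (a - p) / margin_h
        val_lo = np.where(margin_l > 0, np.tanh(y_lo / 2.0), -1.0)
        val_hi = np.where(margin_h > 0, np.tanh(y_hi / 2.0), -1.0)
    out = np.where(inside, 1.0, 0.0)
    out = np.where(below, val_lo, out)
    out = np.where(above, val_hi, out)
    return out


def position_attitude(segment: AcceptanceSegment, p) -> float | np.ndarray:
    """Attitude of an observer with ``segment`` about position ``p``.

    Accepts a scalar or array of positions; positions outside [-1, 1] are
    evaluated by the same formulas.
    """
    out = _position_attitude_arrays(
        segment.lower_bound, segment.ma_position, segment.upper_bound, p
    )
    if np.isscalar(p) or np.ndim(p) == 0:
        return float(out)
    return out


def _interior_mask(b, a, B, points) -> np.ndarray:
    """Grid points strictly inside (b, B): exactly the points where the
    clipped target kernel max(omega_target, 0) equals 1 (it is 0 at the
    bounds and negative outside), so the segment-attitude ratio reduces to
    a plain mean of the observer kernel over these points."""
    return (points > np.asarray(b)[..., None]) & (points < np.asarray(B)[..., None])


def segment_attitude(
    observer: AcceptanceSegment,
    target: AcceptanceSegment,
    grid: PositionGrid,
) -> float:
    """Attitude of ``observer`` about ``target``'s acceptance segment:
    the observer kernel averaged over grid positions the target accepts."""
    pts = grid.points
    inside = (pts > target.lower_bound) & (pts < target.upper_bound)
    n = int(inside.sum())
    if n == 0:
        raise UnresolvableSegmentError(
            f"segment ({target.lower_bound}, {target.upper_bound}) is "
            f"unresolvable at resolution D={grid.resolution}"
        )
    vals = position_attitude(observer, pts[inside])
    return float(np.mean(vals))


def identity_attitude(
    observer: CulturalIdentity,
    target: CulturalIdentity,
    grid: PositionGrid,
) -> float:
    """Attitude about a whole cultural identity: the mean of the K
    per-worldview segment attitudes."""
    if observer.worldviews != target.worldviews:
        raise ValueError("identities must share the same worldview set")
    total = 0.0
    for k in observer.worldviews:
        try:
            total += segment_attitude(observer.segments[k], target.segments[k], grid)
        except UnresolvableSegmentError as exc:
            raise UnresolvableSegmentError(
                f"worldview {k!r}: {exc}"
            ) from exc
    return total / len(observer.worldviews)


def group_of(identity: CulturalIdentity) -> str:
    """The agent's cultural group: the worldview with the highest
    m.a.position; ties go to the earliest worldview in the fixed order."""
    a = identity.ma_positions()
    return identity.worldviews[int(np.argmax(a))]


def _attitude_matrix_arrays(
    b: np.ndarray, a: np.ndarray, B: np.ndarray, points: np.ndarray
) -> np.ndarray:
    """Pairwise identity attitudes from (N, K) bound arrays.

    Returns an (N, N) array with the diagonal forced to exactly 1.  Raises
    UnresolvableSegmentError if any agent's segment contains no grid point.
    """
    kernel = _position_attitude_arrays(
        b[:, :, None], a[:, :, None], B[:, :, None], points
    )  # (N, K, D)
    interior = _interior_mask(b, a, B, points)  # (N, K, D)
    counts = interior.sum(axis=-1)  # (N, K)
    if np.any(counts == 0):
        i, k = np.argwhere(counts == 0)[0]
        raise UnresolvableSegmentError(
            f"agent index {i}, worldview index {k}: segment unresolvable "
            f"at resolution D={points.size}"
        )
    sums = np.einsum("ikd,jkd->ijk", kernel, interior.astype(float))
    omega = (sums / counts[None, :, :]).mean(axis=-1)
    np.fill_diagonal(omega, 1.0)
    return omega


def attitude_matrix(pop: Population, grid: PositionGrid) -> AttitudeMatrix:
    """All pairwise attitudes in ``pop``; entry (i, j) is agent i's attitude
    about agent j's cultural identity, the diagonal exactly 1."""
    b, a, B = pop.identity_arrays()
    try:
        omega = _attitude_matrix_arrays(b, a, B, grid.points)
    except UnresolvableSegmentError as exc:
        raise UnresolvableSegmentError(f"in population: {exc}") from exc
    return AttitudeMatrix(values=omega, agent_ids=tuple(pop.agent_ids))


def _grouped_stats(
    omega: np.ndarray,
    weights: np.ndarray,
    group_idx: np.ndarray,
    n_groups: int,
    include_self: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weighted group-pair means/SDs from an attitude matrix.

    Pair (i, j) carries weight w_i * w_j.  Self-pairs (value 1) belong to
    the in-group cells unless ``include_self`` is False.  Empty cells are
    NaN.  Returns (mean, sd, fraction) arrays.
    """
    mean = np.full((n_groups, n_groups), np.nan)
    sd = np.full((n_groups, n_groups), np.nan)
    fraction = np.zeros(n_groups)
    for g in range(n_groups):
        fraction[g] = weights[group_idx == g].sum()
    for g in range(n_groups):
        obs = np.flatnonzero(group_idx == g)
        if obs.size == 0:
            continue
        for h in range(n_groups):
            tgt = np.flatnonzero(group_idx == h)
            if tgt.size == 0:
                continue
            w = np.outer(weights[obs], weights[tgt])
            vals = omega[np.ix_(obs, tgt)]
            if not include_self and g == h:
                same = obs[:, None] == tgt[None, :]
                w = np.where(same, 0.0, w)
                if w.sum() == 0:
                    continue
            wsum = w.sum()
            m = float((w * vals).sum() / wsum)
            mean[g, h] = m
            sd[g, h] = math.sqrt(float((w * (vals - m) ** 2).sum() / wsum))
    return mean, sd, fraction


def group_stats(
    pop: Population,
    matrix: AttitudeMatrix,
    include_self: bool = True,
) -> GroupAttitudeStats:
    """Group-to-group weighted attitude statistics.

    Terrorist agents are excluded as observers and targets.  Self-pairs
    (attitude exactly 1) count toward in-group cells by default, since
    self-attitude is part of the model; ``include_self=False`` exposes the
    exclude-self alternative for sensitivity analysis.  Fractions are the
    summed non-terrorist weights per group.
    """
    if tuple(matrix.agent_ids) != tuple(pop.agent_ids):
        raise ValueError("matrix was not computed from this population")
    worldviews = pop.worldviews
    keep = [i for i, ag in enumerate(pop.agents) if not ag.is_terrorist]
    agents = [pop.agents[i] for i in keep]
    omega = matrix.values[np.ix_(keep, keep)]
    weights = np.array([ag.weight for ag in agents])
    group_idx = np.array(
        [worldviews.index(group_of(ag.identity)) for ag in agents]
    )
    mean, sd, fraction = _grouped_stats(
        omega, weights, group_idx, len(worldviews), include_self=include_self
    )
    labels = list(worldviews)
    return GroupAttitudeStats(
        mean=pd.DataFrame(mean, index=labels, columns=labels),
        sd=pd.DataFrame(sd, index=labels, columns=labels),
        fraction=pd.Series(fraction, index=labels),
    )
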