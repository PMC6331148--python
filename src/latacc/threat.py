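"""Threat reaction dynamics: margin contraction after a terrorist message.

A terrorist agent ``q`` broadcasts an extreme cultural identity (a very
narrow, very positive segment on its preferred worldview, very negative
segments elsewhere).  Each population agent ``i`` computes the terrorist's
attitude about itself, ``omega_qi``.  A non-negative attitude means the
agent is not threatened and does nothing.  A negative one triggers a
contraction, at intensity ``mu = alpha * tanh(omega_qi / 2)``, of the bound
of the agent's segment on the targeted worldview that lies closest to the
terrorist's most acceptable position, pulling the margin width toward the
floor ``epsilon`` (an exact fixed point of the update).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .identity import (
    AcceptanceSegment,
    Agent,
    AttitudeMatrix,
    CulturalIdentity,
    DEFAULT_WORLDVIEWS,
    GroupAttitudeStats,
    Population,
    PositionGrid,
    attitude_matrix,
    group_of,
    group_stats,
    identity_attitude,
)

#: Default terrorist acceptance segments: near-maximal support for the
#: targeted worldview, near-maximal rejection of the others, all margins
#: at the minimum width 0.05.
DEFAULT_TERRORIST_TARGET_SEGMENT = (0.90, 0.95, 1.00)
DEFAULT_TERRORIST_OTHER_SEGMENT = (-1.00, -0.95, -0.90)


@dataclass(frozen=True)
class ThreatParams:
    """Dynamics parameters: reaction gain ``alpha`` in (0, 1], minimum
    margin width ``epsilon``, step cap and convergence tolerance."""

    alpha: float = 0.5
    epsilon: float = 0.05
    steps: int = 50
    convergence_tol: float = 1e-6

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if not 0 < self.epsilon < 1:
            raise ValueError("epsilon must be in (0, 1)")
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        if not self.convergence_tol > 0:
            raise ValueError("convergence_tol must be positive")


@dataclass(frozen=True)
class ReactionRecord:
    """One agent's reaction at one step."""

    agent_id: str
    step: int
    terrorist_attitude: float  # omega_qi
    intensity: float  # mu, 0.0 when the agent does not react
    bound_before: float
    bound_after: float
    reacted: bool


@dataclass(frozen=True)
class TrajectoryState:
    step: int
    population: Population
    matrix: AttitudeMatrix
    stats: GroupAttitudeStats


@dataclass(frozen=True)
class Trajectory:
    states: tuple[TrajectoryState, ...]
    records: tuple[ReactionRecord, ...]
    converged: bool
    target_worldview: str

    @property
    def initial(self) -> TrajectoryState:
        return self.states[0]

    @property
    def final(self) -> TrajectoryState:
        return self.states[-1]

    @property
    def steps_run(self) -> int:
        return self.states[-1].step


@dataclass(frozen=True)
class EvolutionSummary:
    """Classification of per-agent attitude evolutions toward the targeted
    group, with weighted and unweighted aggregates."""

    per_agent_delta: dict[str, float]
    increase_ids: tuple[str, ...]
    pct_increase: float
    pct_decrease_or_unchanged: float
    count_increase: int
    count_decrease_or_unchanged: int
    pct_increase_unweighted: float

    def to_dict(self) -> dict:
        return {
            "per_agent_delta": dict(self.per_agent_delta),
            "increase_ids": list(self.increase_ids),
            "pct_increase": self.pct_increase,
            "pct_decrease_or_unchanged": self.pct_decrease_or_unchanged,
            "count_increase": self.count_increase,
            "count_decrease_or_unchanged": self.count_decrease_or_unchanged,
            "pct_increase_unweighted": self.pct_increase_unweighted,
        }


def segment_overlap(s1: AcceptanceSegment, s2: AcceptanceSegment) -> float:
    """Overlap ``o = min(B1, B2) - max(b1, b2)`` between two acceptance
    segments on one worldview: positive values measure the length of the
    shared acceptable interval, negative values the gap between them."""
    return min(s1.upper_bound, s2.upper_bound) - max(
        s1.lower_bound, s2.lower_bound
    )


def make_terrorist(
    target_worldview: str = "M",
    target_segment: tuple[float, float, float] = DEFAULT_TERRORIST_TARGET_SEGMENT,
    other_segment: tuple[float, float, float] = DEFAULT_TERRORIST_OTHER_SEGMENT,
    worldviews: tuple[str, ...] = DEFAULT_WORLDVIEWS,
    agent_id: str = "terrorist",
    weight: float = 1.0,
) -> Agent:
    """Build the terrorist agent whose identity the threat messages convey."""
    if target_worldview not in worldviews:
        raise ValueError(f"unknown worldview {target_worldview!r}")
    segments = {
        k: AcceptanceSegment(*(target_segment if k == target_worldview else other_segment))
        for k in worldviews
    }
    ident = CulturalIdentity(segments=segments, worldviews=worldviews)
    if group_of(ident) != target_worldview:
        raise ValueError(
            "terrorist segments must give the targeted worldview the "
            "highest m.a.position"
        )
    return Agent(agent_id=agent_id, identity=ident, weight=weight, type_tag="terrorist")


def reaction_intensity(omega_qi: float, params: ThreatParams) -> float | None:
    """Intensity ``mu`` of the margin modification, or None when the
    terrorist's attitude about the agent is non-negative (no reaction).

    For negative attitudes mu = alpha * tanh(omega_qi / 2), strictly
    negative and bounded below by alpha * tanh(-1/2).
    """
    if not -1 - 1e-12 <= omega_qi <= 1 + 1e-12:
        raise ValueError("attitude must lie in [-1, 1]")
    if omega_qi >= 0:
        return None
    return params.alpha * math.tanh(omega_qi / 2.0)


def contract_bound(
    beta: float, a: float, mu: float, eps: float, side: int
) -> float:
    """One application of the bound update
    ``beta' = beta + mu * (beta - a - eps * sign(beta - a))``.

    ``side`` (+1 for the upper bound, -1 for the lower) resolves sign(0)
    when the bound coincides with the m.a.position, so a degenerate margin
    grows back toward eps.  In width terms the map is
    w' = (1 + mu) * w - mu * eps, whose fixed point is w = eps.
    """
    d = beta - a
    s = float(side) if d == 0 else math.copysign(1.0, d)
    return beta + mu * (d - eps * s)


def _choose_bound(segment: AcceptanceSegment, a_q: float) -> int:
    """Which bound of ``segment`` is closest to the terrorist position
    ``a_q``: +1 for the upper bound, -1 for the lower; ties go upper."""
    if abs(segment.upper_bound - a_q) <= abs(segment.lower_bound - a_q):
        return +1
    return -1


def apply_threat_step(
    agent: Agent,
    terrorist: Agent,
    params: ThreatParams,
    grid: PositionGrid,
    step: int = 0,
) -> tuple[Agent, ReactionRecord]:
    """One reaction of ``agent`` to the terrorist's broadcast identity.

    Only the segment on the terrorist's preferred worldview can change, and
    only its bound nearest the terrorist's m.a.position.  Returns the agent
    unchanged (same object) when the terrorist's attitude about it is
    non-negative.
    """
    if agent.is_terrorist:
        raise ValueError("threat updates apply to non-terrorist agents")
    target_wv = group_of(terrorist.identity)
    omega_qi = identity_attitude(terrorist.identity, agent.identity, grid)
    seg = agent.identity.segments[target_wv]
    a_q = terrorist.identity.segments[target_wv].ma_position
    side = _choose_bound(seg, a_q)
    beta = seg.upper_bound if side > 0 else seg.lower_bound
    mu = reaction_intensity(omega_qi, params)
    if mu is None:
        record = ReactionRecord(
            agent_id=agent.agent_id,
            step=step,
            terrorist_attitude=omega_qi,
            intensity=0.0,
            bound_before=beta,
            bound_after=beta,
            reacted=False,
        )
        return agent, record
    new_beta = contract_bound(beta, seg.ma_position, mu, params.epsilon, side)
    new_beta = min(1.0, max(-1.0, new_beta))
    if side > 0:
        new_seg = AcceptanceSegment(seg.lower_bound, seg.ma_position, new_beta)
    else:
        new_seg = AcceptanceSegment(new_beta, seg.ma_position, seg.upper_bound)
    segments = dict(agent.identity.segments)
    segments[target_wv] = new_seg
    new_identity = CulturalIdentity(
        segments=segments, worldviews=agent.identity.worldviews
    )
    new_agent = replace(agent, identity=new_identity)
    record = ReactionRecord(
        agent_id=agent.agent_id,
        step=step,
        terrorist_attitude=omega_qi,
        intensity=mu,
        bound_before=beta,
        bound_after=new_beta,
        reacted=True,
    )
    return new_agent, record


def run_scenario(
    pop: Population,
    terrorist: Agent,
    params: ThreatParams,
    grid: PositionGrid,
    record_all: bool = True,
) -> Trajectory:
    """Expose ``pop`` to repeated threat messages.

    All agents react synchronously to the same broadcast each step (the
    terrorist's identity is constant, and each agent's update depends only
    on its own current identity).  The attitude matrix and group statistics
    are recorded at t=0 and after every step (``record_all=False`` keeps
    only the initial and final states); iteration stops after
    ``params.steps`` messages or once the largest bound movement drops
    below ``params.convergence_tol``.
    """
    if any(ag.agent_id == terrorist.agent_id for ag in pop.agents):
        raise ValueError("terrorist must not be part of the population")
    target_wv = group_of(terrorist.identity)

    def snapshot(p: Population, step: int) -> TrajectoryState:
        m = attitude_matrix(p, grid)
        return TrajectoryState(
            step=step, population=p, matrix=m, stats=group_stats(p, m)
        )

    states = [snapshot(pop, 0)]
    records: list[ReactionRecord] = []
    current = pop
    converged = False
    for t in range(1, params.steps + 1):
        new_agents = []
        max_delta = 0.0
        for ag in current.agents:
            if ag.is_terrorist:
                new_agents.append(ag)
                continue
            new_ag, rec = apply_threat_step(ag, terrorist, params, grid, step=t)
            records.append(rec)
            max_delta = max(max_delta, abs(rec.bound_after - rec.bound_before))
            new_agents.append(new_ag)
        current = Population(agents=tuple(new_agents))
        if record_all:
            states.append(snapshot(current, t))
        if max_delta < params.convergence_tol:
            converged = True
            break
    if not record_all:
        states.append(snapshot(current, t))
    return Trajectory(
        states=tuple(states),
        records=tuple(records),
        converged=converged,
        target_worldview=target_wv,
    )


def _mean_attitude_toward_group(
    state: TrajectoryState, observer_idx: int, target_ids: list[str]
) -> float:
    ids = list(state.matrix.agent_ids)
    weights = {ag.agent_id: ag.weight for ag in state.population.agents}
    num = 0.0
    den = 0.0
    for tid in target_ids:
        j = ids.index(tid)
        num += weights[tid] * state.matrix.values[observer_idx, j]
        den += weights[tid]
    return num / den


def classify_evolutions(
    traj: Trajectory, tol: float = 1e-9
) -> EvolutionSummary:
    """Classify each non-terrorist agent's change of attitude toward the
    targeted group between the first and last recorded states.

    The per-agent attitude is the weighted mean attitude toward the
    non-terrorist agents of the targeted (default M) group, self included
    for group members.  Delta > tol counts as an increase, anything else as
    decrease-or-unchanged.  Percentages are agent-weight weighted; an
    unweighted (per-agent count) percentage is reported alongside.
    """
    if len(traj.states) < 2:
        raise ValueError("trajectory must contain at least two states")
    first, last = traj.initial, traj.final
    target_wv = traj.target_worldview
    observers = [
        (i, ag)
        for i, ag in enumerate(first.population.agents)
        if not ag.is_terrorist
    ]
    target_ids = [
        ag.agent_id
        for ag in first.population.agents
        if not ag.is_terrorist and group_of(ag.identity) == target_wv
    ]
    if not target_ids:
        raise ValueError(
            f"no non-terrorist agents in targeted group {target_wv!r}; "
            "evolution classification undefined"
        )
    deltas: dict[str, float] = {}
    increase_ids = []
    w_inc = 0.0
    w_tot = 0.0
    for i, ag in observers:
        before = _mean_attitude_toward_group(first, i, target_ids)
        after = _mean_attitude_toward_group(last, i, target_ids)
        delta = float(after - before)
        deltas[ag.agent_id] = delta
        w_tot += ag.weight
        if delta > tol:
            increase_ids.append(ag.agent_id)
            w_inc += ag.weight
    pct_inc = 100.0 * w_inc / w_tot
    n_inc = len(increase_ids)
    n_obs = len(observers)
    return EvolutionSummary(
        per_agent_delta=deltas,
        increase_ids=tuple(increase_ids),
        pct_increase=pct_inc,
        pct_decrease_or_unchanged=100.0 - pct_inc,
        count_increase=n_inc,
        count_decrease_or_unchanged=n_obs - n_inc,
        pct_increase_unweighted=100.0 * n_inc / n_obs,
    )


def write_reaction_records(records, path) -> None:
    """Per-step reaction log as CSV."""
    import pandas as pd

    frame = pd.DataFrame(
        [
            {
                "step": r.step,
                "agent_id": r.agent_id,
                "terrorist_attitude": r.terrorist_attitude,
                "intensity": r.intensity,
                "bound_before": r.bound_before,
                "bound_after": r.bound_after,
                "reacted": r.reacted,
            }
            for r in records
        ]
    )
    frame.to_csv(path, index=False)


def write_trajectory_stats(traj: Trajectory, path) -> None:
    """Per-step group statistics as long-form CSV."""
    import pandas as pd

    rows = []
    for state in traj.states:
        groups = state.stats.groups
        for g in groups:
            for h in groups:
                rows.append(
                    {
                        "step": state.step,
                        "observer_group": g,
                        "target_group": h,
                        "mean": state.stats.mean.loc[g, h],
                        "sd": state.stats.sd.loc[g, h],
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)
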