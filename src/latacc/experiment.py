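"""End-to-end experiment pipeline and reproducibility plumbing.

``run_experiment`` chains the stages: obtain a calibration target (survey
file, stats file, or synthetic survey spec), calibrate a set of virtual
populations with PSO, expose each to the threat scenario, classify the
per-agent attitude evolutions toward the targeted group, and aggregate.
All randomness descends from one master seed through named substreams, so
each stage can be re-run independently with identical results.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .identity import (
    AcceptanceSegment,
    Agent,
    CulturalIdentity,
    DEFAULT_WORLDVIEWS,
    Population,
    PositionGrid,
    group_of,
)
from .popio import read_population, read_stats, write_population, write_stats
from .synthesis import (
    CalibrationTarget,
    PSOConfig,
    SynthSurveySpec,
    default_templates,
    pso_calibrate,
    read_survey,
    sample_prototype,
    survey_stats,
    synth_survey,
    write_survey,
)
from .threat import (
    EvolutionSummary,
    ThreatParams,
    Trajectory,
    classify_evolutions,
    make_terrorist,
    run_scenario,
    write_reaction_records,
    write_trajectory_stats,
)

logger = logging.getLogger(__name__)


def substream_seed(master_seed: int, name: str) -> int:
    """Derive a named, reproducible 31-bit child seed from the master seed."""
    key = zlib.crc32(name.encode("utf-8"))
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(key,))
    return int(ss.generate_state(1)[0] % (2**31))


def substream(master_seed: int, name: str) -> np.random.Generator:
    """Named RNG substream; logged so seed lineage is auditable."""
    seed = substream_seed(master_seed, name)
    logger.info("rng substream %r <- master %d: child seed %d", name, master_seed, seed)
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class ExperimentConfig:
    """Full experiment definition.

    Exactly one target source is used: ``survey_file`` (S1-format table),
    ``stats_file`` (group-statistics JSON), or ``synthetic_survey`` (a
    SynthSurveySpec mapping).  Alternatively ``population_files`` skips
    calibration and runs the scenario on the given population JSONs.
    """

    seed: int
    out_dir: str = "experiment_out"
    grid_resolution: int = 400
    survey_file: str | None = None
    stats_file: str | None = None
    synthetic_survey: dict | None = None
    population_files: tuple[str, ...] | None = None
    pso: dict = field(default_factory=dict)
    threat: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.grid_resolution < 2:
            raise ValueError("grid resolution must be >= 2")
        sources = [
            s
            for s in (
                self.survey_file,
                self.stats_file,
                self.synthetic_survey,
                self.population_files,
            )
            if s
        ]
        if len(sources) != 1:
            raise ValueError(
                "exactly one of survey_file, stats_file, synthetic_survey, "
                "population_files must be given"
            )

    @classmethod
    def from_dict(cls, doc: dict, seed: int | None = None) -> "ExperimentConfig":
        doc = dict(doc)
        if seed is not None:
            doc["seed"] = seed
        if "population_files" in doc and doc["population_files"] is not None:
            doc["population_files"] = tuple(doc["population_files"])
        allowed = {
            "seed",
            "out_dir",
            "grid_resolution",
            "survey_file",
            "stats_file",
            "synthetic_survey",
            "population_files",
            "pso",
            "threat",
        }
        unknown = set(doc) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)


def threat_params_from_config(threat: dict) -> ThreatParams:
    kwargs = {
        k: threat[k]
        for k in ("alpha", "epsilon", "steps", "convergence_tol")
        if k in threat
    }
    return ThreatParams(**kwargs)


def terrorist_from_config(
    threat: dict, worldviews: tuple[str, ...] = DEFAULT_WORLDVIEWS
) -> Agent:
    target_wv = threat.get("target_worldview", "M")
    spec = threat.get("terrorist")
    if spec is None:
        return make_terrorist(target_worldview=target_wv, worldviews=worldviews)
    segments = {
        k: AcceptanceSegment(float(spec[k]["b"]), float(spec[k]["a"]), float(spec[k]["B"]))
        for k in worldviews
    }
    ident = CulturalIdentity(segments=segments, worldviews=worldviews)
    if group_of(ident) != target_wv:
        raise ValueError(
            "terrorist segments must give the targeted worldview the highest "
            "m.a.position"
        )
    return Agent(agent_id="terrorist", identity=ident, weight=1.0, type_tag="terrorist")


@dataclass(frozen=True)
class ExperimentReport:
    """Aggregated experiment outcome.

    Percentages pool every non-terrorist agent over all populations; the
    weighted figure uses agent weights (each population's weights sum to 1
    and populations count equally), and an unweighted per-agent-count
    figure is reported alongside, since either aggregation basis is
    defensible.
    """

    seed: int
    n_populations: int
    per_population: dict[str, dict]
    per_population_direction: dict[str, str]
    pooled_pct_increase: float
    pooled_pct_decrease_or_unchanged: float
    pooled_pct_increase_unweighted: float
    calibration_errors: dict[str, list[float]]

    def to_json(self) -> str:
        doc = {
            "seed": self.seed,
            "n_populations": self.n_populations,
            "per_population": self.per_population,
            "per_population_direction": self.per_population_direction,
            "pooled_pct_increase": self.pooled_pct_increase,
            "pooled_pct_decrease_or_unchanged": self.pooled_pct_decrease_or_unchanged,
            "pooled_pct_increase_unweighted": self.pooled_pct_increase_unweighted,
            "calibration_errors": self.calibration_errors,
        }
        return json.dumps(doc, indent=2, sort_keys=True)


def _population_direction(traj: Trajectory, tol: float = 1e-9) -> str:
    """Direction of the population's weighted mean attitude toward the
    targeted group's non-terrorist agents between first and last state."""
    first, last = traj.initial, traj.final
    target_wv = traj.target_worldview
    agents = first.population.agents
    target_ids = [
        ag.agent_id
        for ag in agents
        if not ag.is_terrorist and group_of(ag.identity) == target_wv
    ]
    ids = list(first.matrix.agent_ids)

    def pooled(state) -> float:
        w_t = {ag.agent_id: ag.weight for ag in state.population.agents}
        num = den = 0.0
        for i, ag in enumerate(state.population.agents):
            if ag.is_terrorist:
                continue
            for tid in target_ids:
                j = ids.index(tid)
                num += ag.weight * w_t[tid] * state.matrix.values[i, j]
                den += ag.weight * w_t[tid]
        return num / den

    delta = pooled(last) - pooled(first)
    if delta > tol:
        return "increase"
    if delta < -tol:
        return "decrease"
    return "unchanged"


def resolve_target(config: ExperimentConfig) -> CalibrationTarget:
    if config.survey_file:
        return survey_stats(read_survey(config.survey_file))
    if config.stats_file:
        return read_stats(config.stats_file)
    spec = SynthSurveySpec.from_dict(config.synthetic_survey or {})
    records = synth_survey(spec, seed=substream_seed(config.seed, "survey"))
    return survey_stats(records)


def run_experiment(config: ExperimentConfig) -> ExperimentReport:
    """Execute the full pipeline and write report artifacts to
    ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = PositionGrid(config.grid_resolution)
    params = threat_params_from_config(config.threat)

    if config.population_files:
        stage = "load-populations"
        try:
            populations = [
                (read_population(p), None) for p in config.population_files
            ]
        except Exception as exc:
            raise RuntimeError(f"[{stage}] {exc}") from exc
    else:
        stage = "calibrate"
        try:
            target = resolve_target(config)
            pso_cfg = PSOConfig(
                seed=substream_seed(config.seed, "calibration"),
                **config.pso,
            )
            result = pso_calibrate(target, pso_cfg, grid)
            populations = list(result.populations)
            write_stats(target, out / "calibration_target.json")
            np.savetxt(
                out / "calibration_trace.csv",
                np.column_stack(
                    [np.arange(len(result.history)), result.history]
                ),
                delimiter=",",
                header="iteration,best_absolute_error",
                comments="",
            )
        except Exception as exc:
            raise RuntimeError(f"[{stage}] {exc}") from exc

    worldviews = populations[0][0].worldviews
    terrorist = terrorist_from_config(config.threat, worldviews)

    per_pop: dict[str, dict] = {}
    directions: dict[str, str] = {}
    calib_errors: dict[str, list[float]] = {}
    w_inc_total = 0.0
    w_total = 0.0
    n_inc_total = 0
    n_total = 0
    for idx, (pop, err) in enumerate(populations):
        pop_id = f"pop{idx:03d}"
        stage = f"scenario:{pop_id}"
        try:
            traj = run_scenario(pop, terrorist, params, grid)
            summary = classify_evolutions(traj)
        except Exception as exc:
            raise RuntimeError(f"[{stage}] {exc}") from exc
        per_pop[pop_id] = summary.to_dict()
        directions[pop_id] = _population_direction(traj)
        if err is not None:
            calib_errors[pop_id] = [err.absolute, err.relative_avg, err.relative_max]
        write_population(pop, out / f"{pop_id}.json")
        write_reaction_records(traj.records, out / f"{pop_id}_reactions.csv")
        write_trajectory_stats(traj, out / f"{pop_id}_group_stats.csv")
        observers = [ag for ag in pop.agents if not ag.is_terrorist]
        w_total += sum(ag.weight for ag in observers)
        w_inc_total += sum(
            ag.weight for ag in observers if ag.agent_id in summary.increase_ids
        )
        n_total += len(observers)
        n_inc_total += summary.count_increase

    pct_inc = 100.0 * w_inc_total / w_total
    report = ExperimentReport(
        seed=config.seed,
        n_populations=len(populations),
        per_population=per_pop,
        per_population_direction=directions,
        pooled_pct_increase=pct_inc,
        pooled_pct_decrease_or_unchanged=100.0 - pct_inc,
        pooled_pct_increase_unweighted=100.0 * n_inc_total / n_total,
        calibration_errors=calib_errors,
    )
    (out / "report.json").write_text(report.to_json() + "\n")
    return report


# ---------------------------------------------------------------------------
# Fixture bundle
# ---------------------------------------------------------------------------

#: The two worked-example agents: same acceptance segment [-0.85, -0.15] on
#: the M worldview but different m.a.positions, hence different upper
#: margins and different attitudes about the position p = 0.2
#: (-0.24 for the wide-margin agent, -0.46 for the narrow-margin one).
FIG1_SEGMENT_WIDE = AcceptanceSegment(-0.85, -0.85, -0.15)
FIG1_SEGMENT_NARROW = AcceptanceSegment(-0.85, -0.50, -0.15)
FIG1_POSITION = 0.2


def _fig1_population() -> Population:
    """Two-agent population carrying the worked-example M segments; the
    other worldviews get neutral placeholder segments (one positive
    m.a.position keeps them valid population agents)."""
    filler = {
        "C": AcceptanceSegment(0.1, 0.5, 0.9),
        "A": AcceptanceSegment(-0.5, -0.1, 0.3),
    }
    agents = []
    for name, seg in (("orange", FIG1_SEGMENT_WIDE), ("green", FIG1_SEGMENT_NARROW)):
        ident = CulturalIdentity(
            segments={"M": seg, **filler}, worldviews=DEFAULT_WORLDVIEWS
        )
        agents.append(Agent(agent_id=name, identity=ident, weight=0.5, type_tag="inclusive"))
    return Population(agents=tuple(agents))


def increase_condition_pair() -> Population:
    """Hand-built two-agent population satisfying the conditions under
    which a non-M observer's attitude toward an M agent rises after the
    threat: the non-M agent has a positive-but-lower M m.a.position and an
    upper margin already at the minimum width (so it cannot contract),
    both share a persistent band of acceptable M positions through their
    lower margins, and the M agent has a large upper margin that contracts
    strongly."""
    non_m = CulturalIdentity(
        segments={
            "M": AcceptanceSegment(-0.60, 0.30, 0.35),  # margin_h = epsilon
            "C": AcceptanceSegment(-0.80, -0.30, 0.10),
            "A": AcceptanceSegment(0.00, 0.60, 0.90),
        }
    )
    m_agent = CulturalIdentity(
        segments={
            "M": AcceptanceSegment(-0.40, 0.50, 0.95),  # large margin_h
            "C": AcceptanceSegment(-0.80, -0.50, -0.20),
            "A": AcceptanceSegment(-0.60, -0.20, 0.20),
        }
    )
    return Population(
        agents=(
            Agent("observer_nonM", non_m, 0.5, "inclusive"),
            Agent("agent_M", m_agent, 0.5, "inclusive"),
        )
    )


def generate_fixtures(seed: int, out_dir) -> dict[str, Path]:
    """Write the reusable fixture bundle; deterministic given the seed.

    Contents: the two worked-example agents, a template-sampled six-agent
    prototype population, a synthetic n=1000 survey, and the hand-built
    increase-condition pair.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["fig1_pair"] = out / "fig1_pair.json"
    write_population(_fig1_population(), paths["fig1_pair"])

    rng = substream(seed, "fixtures")
    fractions = {"M": 0.036, "C": 0.606, "A": 0.358}
    agents = []
    for t in default_templates():
        ident = sample_prototype(t, rng)
        agents.append(
            Agent(
                agent_id=f"{t.group}_{t.type_tag}",
                identity=ident,
                weight=fractions[t.group] * 0.5,
                type_tag=t.type_tag,
            )
        )
    paths["prototype_population"] = out / "prototype_population.json"
    write_population(Population(agents=tuple(agents)), paths["prototype_population"])

    records = synth_survey(SynthSurveySpec(), seed=substream_seed(seed, "survey"))
    paths["synthetic_survey"] = out / "synthetic_survey.txt"
    write_survey(records, paths["synthetic_survey"])

    paths["increase_pair"] = out / "increase_pair.json"
    write_population(increase_condition_pair(), paths["increase_pair"])
    return paths
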