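"""Survey-calibrated virtual population synthesis.

A six-agent virtual population (one *inclusive* and one *exclusive*
prototype per cultural group) is encoded as a 57-vector: 54 acceptance
segment values (6 prototypes x 3 worldviews x (b, a, B)) plus the three
per-group inclusive weight shares.  Particle Swarm Optimization searches
this space, with a constraint-repair operator applied at every evaluation,
to minimize the sum of absolute differences between the population's
group-to-group attitude means/SDs and the survey-derived targets (18 terms:
9 ordered group pairs x {mean, sd}).

The survey side reads the S1-format attitude table (participant id, region,
age, gender, three 5-point attitude items, religion, free-text religion,
start/end timestamps) or generates a synthetic table with the same record
structure and group-conditional 5-point attitude distributions, so the
pipeline runs without any external data file.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .identity import (
    AcceptanceSegment,
    Agent,
    CulturalIdentity,
    DEFAULT_WORLDVIEWS,
    GroupAttitudeStats,
    Population,
    PositionGrid,
    _attitude_matrix_arrays,
    _grouped_stats,
    attitude_matrix,
    group_of,
    group_stats,
)

logger = logging.getLogger(__name__)

#: The calibration target is simply a complete set of group-attitude
#: statistics (means, SDs, group fractions).
CalibrationTarget = GroupAttitudeStats

#: Minimum margin width enforced on synthesized identities; matches the
#: threat dynamics' smallest possible margin.
EPSILON_DEFAULT = 0.05

#: Columns of the S1-format survey table, in file order.
S1_COLUMNS = (
    "participant_id",
    "region",
    "age",
    "gender",
    "attitude_C",
    "attitude_M",
    "attitude_A",
    "religion",
    "religion_other",
    "start_time",
    "end_time",
)

#: Attitude item column per target group label.
ATTITUDE_COLUMNS = {"M": "attitude_M", "C": "attitude_C", "A": "attitude_A"}

#: Religion label -> cultural group.  Labels not listed here (lower-cased,
#: stripped) are unmappable and excluded from the statistics with a logged
#: count.
RELIGION_GROUPS = {
    "muslim": "M",
    "musulman": "M",
    "musulmane": "M",
    "islam": "M",
    "christian": "C",
    "chretien": "C",
    "chrétien": "C",
    "catholic": "C",
    "catholique": "C",
    "protestant": "C",
    "protestante": "C",
    "orthodox": "C",
    "orthodoxe": "C",
    "areligious": "A",
    "atheist": "A",
    "athee": "A",
    "athée": "A",
    "agnostic": "A",
    "agnostique": "A",
    "none": "A",
    "no religion": "A",
    "sans religion": "A",
    "aucune": "A",
}


# ---------------------------------------------------------------------------
# Survey records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurveyRecord:
    participant_id: str
    region: str
    age: int
    gender: str
    attitude_C: int
    attitude_M: int
    attitude_A: int
    religion: str
    religion_other: str = ""
    start_time: str = ""
    end_time: str = ""

    def __post_init__(self) -> None:
        for col in ("attitude_C", "attitude_M", "attitude_A"):
            v = getattr(self, col)
            if v not in (1, 2, 3, 4, 5):
                raise ValueError(f"{col} must be an integer 1-5, got {v!r}")
        if not 18 <= self.age <= 89:
            raise ValueError(f"age out of surveyed range 18-89: {self.age}")

    @property
    def group(self) -> str | None:
        """Cultural group the respondent belongs to, or None if the
        religion label is unmappable."""
        return RELIGION_GROUPS.get(self.religion.strip().lower())

    def attitude_toward(self, group: str) -> int:
        return getattr(self, ATTITUDE_COLUMNS[group])


def _detect_delimiter(line: str) -> str:
    counts = {d: line.count(d) for d in ("\t", ";", ",")}
    best = max(counts, key=counts.get)
    if counts[best] == 0:
        raise ValueError("could not detect a tab/comma/semicolon delimiter")
    return best


def read_survey(path) -> list[SurveyRecord]:
    """Read an S1-format delimited survey table.

    The delimiter (tab, comma, or semicolon) and an optional header row are
    auto-detected.  Malformed rows are skipped with a logged count; more
    than 10% malformed rows is a hard error.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text(encoding="utf-8").splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty survey file")
    delim = _detect_delimiter(lines[0])
    first = [f.strip() for f in lines[0].split(delim)]
    has_header = len(first) >= 3 and not first[2].isdigit()  # age column
    rows = lines[1:] if has_header else lines
    records: list[SurveyRecord] = []
    bad = 0
    for ln in rows:
        fields = [f.strip() for f in ln.split(delim)]
        if len(fields) < 9:
            bad += 1
            logger.warning("skipping short row: %r", ln[:80])
            continue
        fields += [""] * (len(S1_COLUMNS) - len(fields))
        try:
            records.append(
                SurveyRecord(
                    participant_id=fields[0],
                    region=fields[1],
                    age=int(fields[2]),
                    gender=fields[3],
                    attitude_C=int(fields[4]),
                    attitude_M=int(fields[5]),
                    attitude_A=int(fields[6]),
                    religion=fields[7],
                    religion_other=fields[8],
                    start_time=fields[9],
                    end_time=fields[10],
                )
            )
        except ValueError as exc:
            bad += 1
            logger.warning("skipping malformed row (%s): %r", exc, ln[:80])
    total = len(rows)
    if bad:
        logger.info("survey %s: skipped %d of %d rows", path, bad, total)
    if total and bad > 0.1 * total:
        raise ValueError(
            f"{path}: {bad}/{total} rows malformed (>10%); refusing to proceed"
        )
    return records


def normalize_response(r: int) -> float:
    """Map a 5-point response linearly onto [-1, 1]: 1 -> -1, 3 -> 0, 5 -> 1."""
    return (r - 3) / 2.0


def survey_stats(
    records: list[SurveyRecord],
    worldviews: tuple[str, ...] = DEFAULT_WORLDVIEWS,
) -> CalibrationTarget:
    """Group-conditional attitude statistics from survey records.

    Responses are normalized to [-1, 1]; for each ordered (respondent
    group, target group) pair the mean and population SD are computed.
    Respondents with unmappable religion labels are excluded and counted;
    groups with no respondents yield NaN cells.
    """
    grouped: dict[str, list[SurveyRecord]] = {g: [] for g in worldviews}
    unmapped = 0
    for rec in records:
        g = rec.group
        if g is None or g not in grouped:
            unmapped += 1
            continue
        grouped[g].append(rec)
    if unmapped:
        logger.info("survey_stats: excluded %d unmappable respondents", unmapped)
    total = sum(len(v) for v in grouped.values())
    if total == 0:
        raise ValueError("no mappable survey respondents")
    n = len(worldviews)
    mean = np.full((n, n), np.nan)
    sd = np.full((n, n), np.nan)
    fraction = np.zeros(n)
    for gi, g in enumerate(worldviews):
        recs = grouped[g]
        fraction[gi] = len(recs) / total
        if not recs:
            logger.warning("survey_stats: group %s empty; cells undefined", g)
            continue
        for hi, h in enumerate(worldviews):
            vals = np.array([normalize_response(r.attitude_toward(h)) for r in recs])
            mean[gi, hi] = vals.mean()
            sd[gi, hi] = vals.std(ddof=0)
    labels = list(worldviews)
    return GroupAttitudeStats(
        mean=pd.DataFrame(mean, index=labels, columns=labels),
        sd=pd.DataFrame(sd, index=labels, columns=labels),
        fraction=pd.Series(fraction, index=labels),
    )


# ---------------------------------------------------------------------------
# Synthetic survey generator
# ---------------------------------------------------------------------------

_REGIONS = (
    "Ile-de-France",
    "Auvergne-Rhone-Alpes",
    "Nouvelle-Aquitaine",
    "Occitanie",
    "Hauts-de-France",
    "Grand Est",
    "Provence-Alpes-Cote d'Azur",
    "Pays de la Loire",
    "Normandie",
    "Bretagne",
    "Bourgogne-Franche-Comte",
    "Centre-Val de Loire",
    "Corse",
)

_GROUP_RELIGION = {"M": "Muslim", "C": "Christian", "A": "No religion"}


@dataclass(frozen=True)
class SynthSurveySpec:
    """Specification of a synthetic S1-format survey.

    ``mean5``/``sd5`` give the group-conditional attitude distribution on
    the raw 1-5 scale: ``mean5[G][H]`` is respondent group G's mean
    response about group H.
    """

    n: int = 1000
    fractions: dict[str, float] = field(
        default_factory=lambda: {"M": 0.036, "C": 0.606, "A": 0.358}
    )
    mean5: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "M": {"M": 4.4, "C": 3.4, "A": 3.0},
            "C": {"M": 2.6, "C": 4.0, "A": 3.2},
            "A": {"M": 2.9, "C": 3.2, "A": 4.1},
        }
    )
    sd5: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "M": {"M": 0.8, "C": 1.0, "A": 1.0},
            "C": {"M": 1.1, "C": 0.9, "A": 1.0},
            "A": {"M": 1.1, "C": 1.0, "A": 0.9},
        }
    )

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be positive")
        tot = sum(self.fractions.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(f"group fractions must sum to 1, got {tot}")
        for g, row in self.sd5.items():
            for h, s in row.items():
                if s < 0:
                    raise ValueError(f"sd5[{g}][{h}] must be >= 0")

    @classmethod
    def from_dict(cls, doc: dict) -> "SynthSurveySpec":
        kwargs = {}
        for key in ("n", "fractions", "mean5", "sd5"):
            if key in doc:
                kwargs[key] = doc[key]
        return cls(**kwargs)


def _largest_remainder_counts(n: int, fractions: dict[str, float]) -> dict[str, int]:
    groups = list(fractions)
    raw = np.array([n * fractions[g] for g in groups])
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    for i in order[:remainder]:
        counts[i] += 1
    return dict(zip(groups, counts.tolist()))


def synth_survey(spec: SynthSurveySpec, seed: int) -> list[SurveyRecord]:
    """Generate a reproducible synthetic survey.

    Group sizes follow the spec fractions exactly (largest-remainder
    apportionment), so the empirical group fractions are deterministic;
    attitudes are Gaussian draws with the group-conditional (mean, sd) on
    the 1-5 scale, rounded and clipped to {1..5}.
    """
    rng = np.random.default_rng(seed)
    counts = _largest_remainder_counts(spec.n, spec.fractions)
    group_seq = [g for g in counts for _ in range(counts[g])]
    group_seq = [group_seq[i] for i in rng.permutation(spec.n)]
    records = []
    for i, g in enumerate(group_seq):
        atts = {}
        for h in ("C", "M", "A"):
            raw = rng.normal(spec.mean5[g][h], spec.sd5[g][h])
            atts[h] = int(min(5, max(1, round(raw))))
        start_min = 8 * 60 + int(rng.integers(0, 600))
        duration = int(rng.integers(6, 25))
        records.append(
            SurveyRecord(
                participant_id=f"P{i + 1:04d}",
                region=_REGIONS[int(rng.integers(0, len(_REGIONS)))],
                age=int(rng.integers(18, 90)),
                gender="female" if rng.random() < 0.52 else "male",
                attitude_C=atts["C"],
                attitude_M=atts["M"],
                attitude_A=atts["A"],
                religion=_GROUP_RELIGION[g],
                religion_other="",
                start_time=f"2014-06-01 {start_min // 60:02d}:{start_min % 60:02d}",
                end_time=(
                    f"2014-06-01 {(start_min + duration) // 60:02d}:"
                    f"{(start_min + duration) % 60:02d}"
                ),
            )
        )
    return records


def write_survey(records: list[SurveyRecord], path, delimiter: str = "\t") -> None:
    lines = [delimiter.join(S1_COLUMNS)]
    for r in records:
        lines.append(
            delimiter.join(
                str(getattr(r, col)) for col in S1_COLUMNS
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Prototype templates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PrototypeTemplate:
    """Sampling template for one prototype identity.

    *Exclusive* prototypes hold their own-group segment inside [0, 1] with
    total width at most 0.8, and the other worldviews' segments mostly
    (>= 60%) below zero with non-positive m.a.positions.  *Inclusive*
    prototypes have a positive own-group m.a.position, all segment widths
    at least 0.7, and at least 60% of every segment above -0.2; the other
    worldviews' m.a.positions sit near zero.
    """

    group: str
    type_tag: str  # "inclusive" | "exclusive"
    worldviews: tuple[str, ...] = DEFAULT_WORLDVIEWS
    eps: float = EPSILON_DEFAULT
    own_a_range: tuple[float, float] = (0.3, 0.9)
    other_a_range: tuple[float, float] = (-0.8, -0.05)

    def __post_init__(self) -> None:
        if self.type_tag not in ("inclusive", "exclusive"):
            raise ValueError("type_tag must be inclusive or exclusive")
        if self.group not in self.worldviews:
            raise ValueError(f"unknown group {self.group!r}")

    def satisfies(self, identity: CulturalIdentity) -> bool:
        """Structural constraint check for a sampled identity."""
        if group_of(identity) != self.group:
            return False
        for k in self.worldviews:
            seg = identity.segments[k]
            if seg.margin_l < self.eps - 1e-12 or seg.margin_h < self.eps - 1e-12:
                return False
            if self.type_tag == "exclusive":
                if k == self.group:
                    if seg.lower_bound < 0 or seg.width > 0.8 or seg.ma_position <= 0:
                        return False
                else:
                    if seg.ma_position > 0:
                        return False
                    below = min(0.0, seg.upper_bound) - seg.lower_bound
                    if seg.width > 0 and below / seg.width < 0.6 - 1e-12:
                        return False
            else:
                if seg.width < 0.7 - 1e-12:
                    return False
                above = seg.upper_bound - max(seg.lower_bound, -0.2)
                if above / seg.width < 0.6 - 1e-12:
                    return False
                if k == self.group and seg.ma_position <= 0:
                    return False
        return True


def default_templates(
    worldviews: tuple[str, ...] = DEFAULT_WORLDVIEWS,
    eps: float = EPSILON_DEFAULT,
) -> list[PrototypeTemplate]:
    """Six templates in canonical slot order: per group, inclusive then
    exclusive."""
    out = []
    for g in worldviews:
        out.append(
            PrototypeTemplate(
                group=g,
                type_tag="inclusive",
                worldviews=worldviews,
                eps=eps,
                own_a_range=(0.35, 0.65),
                other_a_range=(-0.15, 0.3),
            )
        )
        out.append(
            PrototypeTemplate(
                group=g,
                type_tag="exclusive",
                worldviews=worldviews,
                eps=eps,
                own_a_range=(0.3, 0.9),
                other_a_range=(-0.8, -0.05),
            )
        )
    return out


def _sample_exclusive(t: PrototypeTemplate, rng: np.random.Generator) -> CulturalIdentity:
    segments = {}
    for k in t.worldviews:
        if k == t.group:
            a = rng.uniform(*t.own_a_range)
            ml = rng.uniform(t.eps, min(0.4, a))
            mh = rng.uniform(t.eps, min(0.4, 1.0 - a))
        else:
            a = rng.uniform(*t.other_a_range)
            ml = rng.uniform(t.eps, min(0.5, 1.0 + a))
            # keep >= 60% of the segment below zero
            mh_cap = min(0.5, max(t.eps, (2.0 / 3.0) * (-a) + (2.0 / 3.0) * ml - 1e-6))
            mh = rng.uniform(t.eps, max(t.eps + 1e-9, mh_cap))
        segments[k] = AcceptanceSegment(a - ml, a, min(1.0, a + mh))
    return CulturalIdentity(segments=segments, worldviews=t.worldviews)


def _sample_inclusive(t: PrototypeTemplate, rng: np.random.Generator) -> CulturalIdentity:
    segments = {}
    a_own = rng.uniform(*t.own_a_range)
    for k in t.worldviews:
        if k == t.group:
            a = a_own
            ml = rng.uniform(0.35, min(0.65, a + 0.3))
            mh = rng.uniform(0.35, 1.0 - a)
        else:
            hi = min(t.other_a_range[1], a_own - 0.05)
            a = rng.uniform(t.other_a_range[0], hi)
            b = rng.uniform(-0.3, a - t.eps)
            B = rng.uniform(max(a + t.eps, b + 0.7), 1.0)
            ml, mh = a - b, B - a
        segments[k] = AcceptanceSegment(a - ml, a, a + mh)
    return CulturalIdentity(segments=segments, worldviews=t.worldviews)


def sample_prototype(
    template: PrototypeTemplate,
    rng: np.random.Generator,
    max_tries: int = 200,
) -> CulturalIdentity:
    """Sample one prototype identity satisfying the template constraints."""
    sampler = _sample_exclusive if template.type_tag == "exclusive" else _sample_inclusive
    for _ in range(max_tries):
        ident = sampler(template, rng)
        if template.satisfies(ident):
            return ident
    raise RuntimeError(
        f"could not sample a {template.type_tag} {template.group} prototype "
        f"satisfying the template constraints in {max_tries} tries"
    )


# ---------------------------------------------------------------------------
# 57-vector encoding / repair
# ---------------------------------------------------------------------------

N_VECTOR = 57
_SHARE_CLIP = (0.01, 0.99)
_TIE_EPS = 1e-6


def _slot_order(worldviews: tuple[str, ...]) -> list[tuple[str, str]]:
    return [(g, tt) for g in worldviews for tt in ("inclusive", "exclusive")]


def encode(pop: Population) -> np.ndarray:
    """Encode a six-prototype population as a 57-vector.

    Layout: per group in worldview order, the inclusive then the exclusive
    prototype; per prototype, (b, a, B) for each worldview; then the three
    per-group inclusive weight shares.
    """
    worldviews = pop.worldviews
    by_slot: dict[tuple[str, str], Agent] = {}
    for ag in pop.non_terrorists:
        key = (group_of(ag.identity), ag.type_tag)
        if key in by_slot:
            raise ValueError(f"duplicate prototype slot {key}")
        by_slot[key] = ag
    slots = _slot_order(worldviews)
    if set(by_slot) != set(slots):
        raise ValueError(
            "population must contain exactly one inclusive and one exclusive "
            f"prototype per group; got {sorted(by_slot)}"
        )
    vec = np.empty(N_VECTOR)
    pos = 0
    for key in slots:
        ag = by_slot[key]
        for k in worldviews:
            vec[pos:pos + 3] = ag.identity.segments[k].as_tuple()
            pos += 3
    for gi, g in enumerate(worldviews):
        w_inc = by_slot[(g, "inclusive")].weight
        w_exc = by_slot[(g, "exclusive")].weight
        vec[54 + gi] = w_inc / (w_inc + w_exc)
    return vec


def repair_constraints(
    vec: np.ndarray,
    worldviews: tuple[str, ...] = DEFAULT_WORLDVIEWS,
    eps: float = EPSILON_DEFAULT,
) -> np.ndarray:
    """Project an arbitrary 57-vector onto the feasible set.

    Clips to [-1, 1]; sorts each (b, a, B) triple; clamps m.a.positions so
    margins of width eps fit inside [-1, 1]; restores each prototype's
    group membership (own-group m.a.position strictly maximal, by minimal
    shift with a 1e-6 tie-break offset); widens margins to at least eps;
    clips weight shares to [0.01, 0.99].  Idempotent.
    """
    v = np.asarray(vec, dtype=float).copy()
    if v.shape != (N_VECTOR,):
        raise ValueError(f"expected a {N_VECTOR}-vector, got shape {v.shape}")
    np.clip(v[:54], -1.0, 1.0, out=v[:54])
    np.clip(v[54:], *_SHARE_CLIP, out=v[54:])
    K = len(worldviews)
    trips = v[:54].reshape(6, K, 3)
    trips.sort(axis=-1)  # b <= a <= B per worldview
    b, a, B = trips[..., 0], trips[..., 1], trips[..., 2]
    np.clip(a, -1.0 + eps, 1.0 - eps, out=a)
    for slot in range(6):
        own = slot // 2
        others = [k for k in range(K) if k != own]
        m = a[slot, others].max()
        floor_own = max(m + _TIE_EPS, _TIE_EPS)  # also keep a positive m.a.position
        if a[slot, own] < floor_own:
            a_own = min(floor_own, 1.0 - eps)
            a[slot, own] = a_own
            for k in others:
                if a[slot, k] > a_own - _TIE_EPS:
                    a[slot, k] = a_own - _TIE_EPS
    np.minimum(b, a - eps, out=b)
    np.maximum(b, -1.0, out=b)
    np.maximum(B, a + eps, out=B)
    np.minimum(B, 1.0, out=B)
    return v


def decode(
    vec: np.ndarray,
    fractions: pd.Series | dict[str, float],
    worldviews: tuple[str, ...] = DEFAULT_WORLDVIEWS,
    eps: float = EPSILON_DEFAULT,
) -> Population:
    """Decode a 57-vector into a six-prototype population.

    The vector is repaired first (a no-op for feasible vectors).  Agent
    weight = group fraction x type share; group fractions come from the
    calibration target, not the vector.
    """
    v = repair_constraints(vec, worldviews=worldviews, eps=eps)
    fr = {g: float(fractions[g]) for g in worldviews}
    if abs(sum(fr.values()) - 1.0) > 1e-9:
        raise ValueError("group fractions must sum to 1")
    if any(f <= 0 for f in fr.values()):
        raise ValueError("group fractions must be positive")
    K = len(worldviews)
    trips = v[:54].reshape(6, K, 3)
    shares = v[54:]
    agents = []
    for slot, (g, tt) in enumerate(_slot_order(worldviews)):
        segments = {
            k: AcceptanceSegment(*trips[slot, ki]) for ki, k in enumerate(worldviews)
        }
        ident = CulturalIdentity(segments=segments, worldviews=worldviews)
        share = shares[slot // 2] if tt == "inclusive" else 1.0 - shares[slot // 2]
        agents.append(
            Agent(
                agent_id=f"{g}_{tt}",
                identity=ident,
                weight=fr[g] * share,
                type_tag=tt,
            )
        )
    return Population(agents=tuple(agents))


# ---------------------------------------------------------------------------
# Calibration error
# ---------------------------------------------------------------------------

class ErrorTriple(NamedTuple):
    """Calibration error: raw sum plus relative average/max over the 18
    (9 group pairs x {mean, sd}) terms."""

    absolute: float
    relative_avg: float
    relative_max: float


#: Floor for the relative-error denominator on the normalized scale;
#: prevents blow-up for near-zero target statistics.
RELATIVE_FLOOR = 0.05


def _error_terms(
    sim_mean: np.ndarray,
    sim_sd: np.ndarray,
    tgt_mean: np.ndarray,
    tgt_sd: np.ndarray,
    floor: float = RELATIVE_FLOOR,
) -> ErrorTriple:
    diffs = []
    rels = []
    skipped = 0
    for sim, tgt in ((sim_mean, tgt_mean), (sim_sd, tgt_sd)):
        for s, t in zip(np.ravel(sim), np.ravel(tgt)):
            if math.isnan(t):
                skipped += 1
                continue
            d = abs(s - t)
            diffs.append(d)
            rels.append(d / max(abs(t), floor))
    if skipped:
        logger.info("population_error: skipped %d undefined target cells", skipped)
    if not diffs:
        raise ValueError("no defined target cells")
    return ErrorTriple(
        absolute=float(np.sum(diffs)),
        relative_avg=float(np.mean(rels)),
        relative_max=float(np.max(rels)),
    )


def population_error(
    pop: Population,
    target: CalibrationTarget,
    grid: PositionGrid,
    floor: float = RELATIVE_FLOOR,
) -> ErrorTriple:
    """Discrepancy between a population's group-attitude statistics and a
    calibration target."""
    matrix = attitude_matrix(pop, grid)
    stats = group_stats(pop, matrix)
    labels = list(target.groups)
    sim_mean = stats.mean.loc[labels, labels].to_numpy()
    sim_sd = stats.sd.loc[labels, labels].to_numpy()
    return _error_terms(
        sim_mean, sim_sd, target.mean.to_numpy(), target.sd.to_numpy(), floor
    )


def _vector_error(
    vec: np.ndarray,
    fractions: np.ndarray,
    tgt_mean: np.ndarray,
    tgt_sd: np.ndarray,
    points: np.ndarray,
    n_groups: int,
    floor: float = RELATIVE_FLOOR,
) -> ErrorTriple:
    """Fast calibration error for a repaired 57-vector (array path, no
    object construction)."""
    trips = vec[:54].reshape(6, n_groups, 3)
    b, a, B = trips[..., 0], trips[..., 1], trips[..., 2]
    shares = vec[54:]
    w = np.empty(6)
    w[0::2] = fractions * shares
    w[1::2] = fractions * (1.0 - shares)
    gidx = np.repeat(np.arange(n_groups), 2)
    omega = _attitude_matrix_arrays(b, a, B, points)
    mean, sd, _ = _grouped_stats(omega, w, gidx, n_groups)
    return _error_terms(mean, sd, tgt_mean, tgt_sd, floor)


# ---------------------------------------------------------------------------
# Particle Swarm Optimization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PSOConfig:
    """Global-best PSO settings; constriction-style defaults."""

    seed: int
    swarm_size: int = 40
    iterations: int = 500
    inertia: float = 0.72
    cognitive_coeff: float = 1.49
    social_coeff: float = 1.49
    keep_top: int = 120
    velocity_clamp: float = 0.25
    prescreen: int = 0  # >swarm_size enables error-screened warm start

    def __post_init__(self) -> None:
        for name in ("swarm_size", "iterations", "inertia",
                     "cognitive_coeff", "social_coeff", "keep_top",
                     "velocity_clamp"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class CalibrationResult:
    """Ranked calibrated populations with their errors and the global-best
    absolute-error trace (one entry per iteration, starting at init)."""

    populations: tuple[tuple[Population, ErrorTriple], ...]
    history: tuple[float, ...]

    @property
    def best(self) -> tuple[Population, ErrorTriple]:
        return self.populations[0]


def _initial_positions(
    n: int,
    templates: list[PrototypeTemplate],
    rng: np.random.Generator,
    worldviews: tuple[str, ...],
) -> np.ndarray:
    X = np.empty((n, N_VECTOR))
    for p in range(n):
        pos = 0
        for t in templates:
            ident = sample_prototype(t, rng)
            for k in worldviews:
                X[p, pos:pos + 3] = ident.segments[k].as_tuple()
                pos += 3
        X[p, 54:] = rng.uniform(0.1, 0.9, size=len(worldviews))
    return X


def pso_calibrate(
    target: CalibrationTarget,
    config: PSOConfig,
    grid: PositionGrid,
    templates: list[PrototypeTemplate] | None = None,
    eps: float = EPSILON_DEFAULT,
) -> CalibrationResult:
    """Calibrate six-prototype populations to a survey target with
    global-best PSO.

    Particles are 57-vectors initialized by template sampling (optionally
    error-prescreened), repaired at every evaluation, and scored by the
    absolute error (18-term sum).  Deterministic given ``config.seed``.
    Returns the ``keep_top`` distinct personal-best populations ranked by
    absolute error.
    """
    worldviews = tuple(target.groups)
    n_groups = len(worldviews)
    if templates is None:
        templates = default_templates(worldviews, eps=eps)
    if any(np.isnan(target.fraction.to_numpy())) or any(
        target.fraction.to_numpy() <= 0
    ):
        raise ValueError("calibration target requires positive group fractions")
    fractions = target.fraction.to_numpy(dtype=float)
    tgt_mean = target.mean.to_numpy(dtype=float)
    tgt_sd = target.sd.to_numpy(dtype=float)
    points = grid.points
    rng = np.random.default_rng(config.seed)

    def evaluate(x: np.ndarray) -> tuple[np.ndarray, ErrorTriple]:
        xr = repair_constraints(x, worldviews=worldviews, eps=eps)
        return xr, _vector_error(xr, fractions, tgt_mean, tgt_sd, points, n_groups)

    n_init = max(config.swarm_size, config.prescreen)
    X0 = _initial_positions(n_init, templates, rng, worldviews)
    evals = [evaluate(x) for x in X0]
    if n_init > config.swarm_size:
        order = np.argsort([e.absolute for _, e in evals], kind="stable")
        evals = [evals[i] for i in order[: config.swarm_size]]
    X = np.array([x for x, _ in evals])
    errs = [e for _, e in evals]

    P = X.copy()
    p_errs = list(errs)
    g_idx = int(np.argmin([e.absolute for e in p_errs]))
    G = P[g_idx].copy()
    g_err = p_errs[g_idx]
    history = [g_err.absolute]
    V = np.zeros_like(X)
    vmax = config.velocity_clamp

    for _ in range(config.iterations):
        r1 = rng.random(X.shape)
        r2 = rng.random(X.shape)
        V = (
            config.inertia * V
            + config.cognitive_coeff * r1 * (P - X)
            + config.social_coeff * r2 * (G - X)
        )
        np.clip(V, -vmax, vmax, out=V)
        X = X + V
        for p in range(config.swarm_size):
            xr, e = evaluate(X[p])
            X[p] = xr
            if e.absolute < p_errs[p].absolute:
                P[p] = xr
                p_errs[p] = e
                if e.absolute < g_err.absolute:
                    G = xr.copy()
                    g_err = e
        history.append(g_err.absolute)

    order = np.argsort([e.absolute for e in p_errs], kind="stable")
    seen: set[bytes] = set()
    ranked: list[tuple[Population, ErrorTriple]] = []
    for i in order:
        key = np.round(P[i], 9).tobytes()
        if key in seen:
            continue
        seen.add(key)
        pop = decode(P[i], target.fraction, worldviews=worldviews, eps=eps)
        ranked.append((pop, p_errs[i]))
        if len(ranked) >= config.keep_top:
            break
    return CalibrationResult(populations=tuple(ranked), history=tuple(history))
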