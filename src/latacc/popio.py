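"""Population and statistics file formats.

Populations are stored as JSON::

    {"worldviews": ["M", "C", "A"],
     "agents": [{"id": "...", "weight": 0.3, "type": "inclusive",
                 "identity": {"M": {"b": -0.1, "a": 0.4, "B": 0.9}, ...}}]}

Group-attitude statistics round-trip through a JSON document with explicit
group labels so files remain self-describing.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .identity import (
    AcceptanceSegment,
    Agent,
    CulturalIdentity,
    DEFAULT_WORLDVIEWS,
    GroupAttitudeStats,
    Population,
)


def population_to_dict(pop: Population) -> dict:
    return {
        "worldviews": list(pop.worldviews),
        "agents": [
            {
                "id": ag.agent_id,
                "weight": ag.weight,
                "type": ag.type_tag,
                "identity": {
                    k: {
                        "b": seg.lower_bound,
                        "a": seg.ma_position,
                        "B": seg.upper_bound,
                    }
                    for k, seg in (
                        (k, ag.identity.segments[k]) for k in pop.worldviews
                    )
                },
            }
            for ag in pop.agents
        ],
    }


def population_from_dict(doc: dict) -> Population:
    if "agents" not in doc or not isinstance(doc["agents"], list):
        raise ValueError("population document needs an 'agents' list")
    worldviews = tuple(doc.get("worldviews", DEFAULT_WORLDVIEWS))
    agents = []
    for entry in doc["agents"]:
        try:
            ident = CulturalIdentity(
                segments={
                    k: AcceptanceSegment(
                        lower_bound=float(entry["identity"][k]["b"]),
                        ma_position=float(entry["identity"][k]["a"]),
                        upper_bound=float(entry["identity"][k]["B"]),
                    )
                    for k in worldviews
                },
                worldviews=worldviews,
            )
            agents.append(
                Agent(
                    agent_id=str(entry["id"]),
                    identity=ident,
                    weight=float(entry["weight"]),
                    type_tag=str(entry.get("type", "inclusive")),
                )
            )
        except (KeyError, TypeError) as exc:
            raise ValueError(f"malformed agent entry {entry!r}: {exc}") from exc
    return Population(agents=tuple(agents))


def write_population(pop: Population, path) -> None:
    Path(path).write_text(
        json.dumps(population_to_dict(pop), indent=2, sort_keys=False) + "\n"
    )


def read_population(path) -> Population:
    return population_from_dict(json.loads(Path(path).read_text()))


def stats_to_dict(stats: GroupAttitudeStats) -> dict:
    return stats.to_dict()


def stats_from_dict(doc: dict) -> GroupAttitudeStats:
    groups = list(doc["groups"])
    mean = pd.DataFrame(np.asarray(doc["mean"], dtype=float), index=groups, columns=groups)
    sd = pd.DataFrame(np.asarray(doc["sd"], dtype=float), index=groups, columns=groups)
    fraction = pd.Series({g: float(doc["fraction"][g]) for g in groups})
    return GroupAttitudeStats(mean=mean, sd=sd, fraction=fraction)


def write_stats(stats: GroupAttitudeStats, path) -> None:
    Path(path).write_text(json.dumps(stats_to_dict(stats), indent=2) + "\n")


def read_stats(path) -> GroupAttitudeStats:
    return stats_from_dict(json.loads(Path(path).read_text()))
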