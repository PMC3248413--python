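"""File I/O: CSV readers with validation, network export, run manifests.

All tabular interchange is plain UTF-8 CSV with mandatory headers.
Networks are exported as edge lists (CSV), GraphML (via networkx) or DOT
text with the line width of each link scaled linearly by its estimated
probability.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping

import networkx as nx
import pandas as pd

from .abduction_engine import TrophicNetwork
from .background_knowledge import (
    POINT_COLUMNS,
    TRAIT_COLUMNS,
    SpeciesTaxon,
)
from .probability_ensemble import PermutationEnsemble
from .ratio_observations import COUNT_COLUMNS, TREATMENTS

EDGE_COLUMNS = ["predator_id", "prey_id", "probability", "frequency", "n_permutations"]

_TRUTHY = {"true", "1", "yes", "t"}
_FALSY = {"false", "0", "no", "f"}


def _read_csv(path: str | Path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != columns:
        raise ValueError(
            f"{path}: expected header {','.join(columns)}, got {','.join(df.columns)}"
        )
    return df


def _to_count(value: str, path: Path, line: int, column: str = "count") -> int:
    try:
        n = int(value)
    except ValueError as exc:
        raise ValueError(f"{path}:{line}: {column} {value!r} is not an integer") from exc
    if n < 0:
        raise ValueError(f"{path}:{line}: {column} must be non-negative, got {n}")
    return n


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read the species/site/treatment count table, validating each row."""
    path = Path(path)
    df = _read_csv(path, COUNT_COLUMNS)
    counts = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        if row.treatment not in TREATMENTS:
            raise ValueError(
                f"{path}:{line}: treatment must be one of {TREATMENTS}, "
                f"got {row.treatment!r}"
            )
        counts.append(_to_count(row.count, path, line))
    df = df.copy()
    df["count"] = counts
    return df


def read_traits(path: str | Path) -> dict[str, SpeciesTaxon]:
    """Read the trait table into a species_id -> SpeciesTaxon mapping."""
    path = Path(path)
    df = _read_csv(path, TRAIT_COLUMNS)
    traits: dict[str, SpeciesTaxon] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        flag = row.is_predator.strip().lower()
        if flag in _TRUTHY:
            is_pred = True
        elif flag in _FALSY:
            is_pred = False
        else:
            raise ValueError(f"{path}:{line}: is_predator {row.is_predator!r} not boolean")
        size = _to_count(row.size_class, path, line, "size_class")
        try:
            taxon = SpeciesTaxon(row.species_id, row.name, is_pred, size)
        except ValueError as exc:
            raise ValueError(f"{path}:{line}: {exc}") from exc
        if row.species_id in traits:
            raise ValueError(f"{path}:{line}: duplicate species {row.species_id!r}")
        traits[row.species_id] = taxon
    return traits


def read_points(path: str | Path) -> pd.DataFrame:
    """Read the per-sample-point count table."""
    path = Path(path)
    df = _read_csv(path, POINT_COLUMNS)
    df = df.copy()
    df["count"] = [
        _to_count(v, path, i + 2) for i, v in enumerate(df["count"])
    ]
    return df


def check_species_known(counts: pd.DataFrame, traits: Mapping[str, SpeciesTaxon]) -> None:
    """Error naming any species present in counts but absent from traits."""
    unknown = sorted(set(counts["species_id"]) - set(traits))
    if unknown:
        raise ValueError(f"species in counts but missing from traits: {unknown}")


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, index=False)


def write_traits(traits: Mapping[str, SpeciesTaxon], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "species_id": t.species_id,
                "name": t.name,
                "is_predator": t.is_predator,
                "size_class": t.size_class,
            }
            for t in sorted(traits.values(), key=lambda t: t.species_id)
        ],
        columns=TRAIT_COLUMNS,
    ).to_csv(path, index=False)


def write_points(points: pd.DataFrame, path: str | Path) -> None:
    points.to_csv(path, index=False)


def network_frame(network: TrophicNetwork) -> pd.DataFrame:
    """Single-network edge list with per-direction support counts."""
    return pd.DataFrame(
        [
            {
                "predator_id": pred,
                "prey_id": prey,
                "n_support_up": hyp.n_support_up,
                "n_support_down": hyp.n_support_down,
            }
            for (pred, prey), hyp in sorted(network.links.items())
        ],
        columns=["predator_id", "prey_id", "n_support_up", "n_support_down"],
    )


def uncovered_frame(network: TrophicNetwork) -> pd.DataFrame:
    return pd.DataFrame(
        sorted((o.species_id, o.site_id, o.direction) for o in network.uncovered),
        columns=["species_id", "site_id", "direction"],
    )


def ensemble_frame(ensemble: PermutationEnsemble) -> pd.DataFrame:
    """Probabilistic edge list, probabilities printed with 4 decimals."""
    rows = [
        {
            "predator_id": pred,
            "prey_id": prey,
            "probability": round(count / ensemble.n_permutations, 4),
            "frequency": count,
            "n_permutations": ensemble.n_permutations,
        }
        for (pred, prey), count in sorted(ensemble.link_frequency.items())
    ]
    return pd.DataFrame(rows, columns=EDGE_COLUMNS)


def read_network_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = _read_csv(path, EDGE_COLUMNS)
    df = df.copy()
    df["probability"] = df["probability"].astype(float)
    df["frequency"] = df["frequency"].astype(int)
    df["n_permutations"] = df["n_permutations"].astype(int)
    return df


def _edges_to_digraph(
    edges: pd.DataFrame, traits: Mapping[str, SpeciesTaxon] | None
) -> nx.DiGraph:
    g = nx.DiGraph()
    for row in edges.itertuples(index=False):
        g.add_edge(
            row.predator_id,
            row.prey_id,
            probability=float(row.probability),
            frequency=int(row.frequency),
        )
    if traits:
        for node in g.nodes:
            if node in traits:
                g.nodes[node]["size_class"] = traits[node].size_class
                g.nodes[node]["is_predator"] = traits[node].is_predator
    return g


def _dot_text(edges: pd.DataFrame, traits: Mapping[str, SpeciesTaxon] | None) -> str:
    lines = ["digraph foodweb {", "  rankdir=BT;"]
    nodes = sorted(set(edges["predator_id"]) | set(edges["prey_id"]))
    for node in nodes:
        attrs = ""
        if traits and node in traits:
            attrs = f' [label="{node}\\nsize {traits[node].size_class}"]'
        lines.append(f'  "{node}"{attrs};')
    for row in edges.itertuples(index=False):
        p = float(row.probability)
        lines.append(
            f'  "{row.predator_id}" -> "{row.prey_id}" '
            f'[penwidth={4.0 * p:.3f}, label="{p:.2f}"];'
        )
    lines.append("}")
    return "\n".join(lines) + "\n"


def export_network(
    ensemble: PermutationEnsemble,
    path: str | Path,
    fmt: str = "csv",
    traits: Mapping[str, SpeciesTaxon] | None = None,
) -> None:
    """Write the probabilistic network as ``csv``, ``graphml`` or ``dot``.

    CSV round-trips exactly through :func:`read_network_csv`; GraphML and
    DOT carry the probability as edge weight (DOT penwidth is 4x the
    probability, so a certain link draws at width 4).
    """
    export_edges(ensemble_frame(ensemble), path, fmt, traits)


def export_edges(
    edges: pd.DataFrame,
    path: str | Path,
    fmt: str = "csv",
    traits: Mapping[str, SpeciesTaxon] | None = None,
) -> None:
    path = Path(path)
    if fmt == "csv":
        edges.to_csv(path, index=False, float_format="%.4f")
    elif fmt == "graphml":
        nx.write_graphml(_edges_to_digraph(edges, traits), path)
    elif fmt == "dot":
        path.write_text(_dot_text(edges, traits), encoding="utf-8")
    else:
        raise ValueError(f"unknown export format {fmt!r} (csv, graphml, dot)")


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Everything needed to re-execute a run bit-identically."""

    seed: int
    config: dict
    inputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    outputs: list[str] = field(default_factory=list)
    created: str = ""

    def __post_init__(self) -> None:
        if not self.created:
            self.created = datetime.now(timezone.utc).isoformat()

    def add_input(self, path: str | Path) -> None:
        self.inputs[str(path)] = file_digest(path)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n", encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text(encoding="utf-8")))
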