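"""File formats and run configuration.

Everything is plain text: panels and registries as UTF-8 CSV with a
header row, contiguity graphs as an adjacency-list file with lines
``area_id: neighbour neighbour ...``. Output files carry a comment
header line with the package version (suppressible for byte-identical
reruns). The run configuration is a single JSON document.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .graphs import SpatialGraph
from .model import PanelData

__all__ = [
    "read_graph",
    "write_graph",
    "read_panel",
    "write_panel",
    "read_registry",
    "write_registry",
    "write_table",
    "read_table",
    "RunConfig",
]

_PANEL_COLUMNS = [
    "area_id", "province_id", "age_group", "year", "py", "cases",
    "deprivation_decile", "facility_decile", "urban",
]


def write_graph(graph: SpatialGraph, path) -> None:
    idx = graph.index
    neighbours = {v: [] for v in graph.node_ids}
    for a, b in sorted(graph.edges, key=lambda e: (idx[e[0]], idx[e[1]])):
        neighbours[a].append(b)
        neighbours[b].append(a)
    with open(path, "w", encoding="utf-8") as fh:
        for v in graph.node_ids:
            fh.write(f"{v}: {' '.join(str(w) for w in sorted(neighbours[v]))}\n")


def read_graph(path) -> SpatialGraph:
    """Parse an adjacency-list file. Asymmetric entries ("a: b" without
    "b: a") are symmetrised with a warning; malformed lines error with
    their line number."""
    nodes, directed_edges = [], set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if ":" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'id: neighbour ...'")
            head, _, tail = line.partition(":")
            node = head.strip()
            if not node:
                raise ValueError(f"{path}:{lineno}: empty node id")
            nodes.append(node)
            for nb in tail.split():
                directed_edges.add((node, nb))
    known = set(nodes)
    for a, b in directed_edges:
        if b not in known:
            raise ValueError(f"edge {a}-{b} references unknown node {b!r}")
    asym = {(a, b) for a, b in directed_edges if (b, a) not in directed_edges}
    if asym:
        warnings.warn(f"{len(asym)} asymmetric adjacency entries symmetrised")
    edges = {tuple(sorted(e, key=str)) for e in directed_edges}
    return SpatialGraph(tuple(nodes), frozenset(edges))


def _open_out(path, version_header: bool):
    fh = open(path, "w", encoding="utf-8", newline="")
    if version_header:
        fh.write(f"# iccmap {__version__}\n")
    return fh


def write_panel(panel: PanelData, path, version_header: bool = True) -> None:
    n, a, t = panel.shape
    ai, gi, ti = np.unravel_index(np.arange(panel.n_cells), panel.shape)
    cov = panel.covariates
    frame = pd.DataFrame(
        {
            "area_id": np.asarray(panel.areas, object)[ai],
            "province_id": cov["province_id"].to_numpy()[ai],
            "age_group": np.asarray(panel.age_groups, object)[gi],
            "year": np.asarray(panel.years)[ti],
            "py": panel.E.ravel(),
            "cases": panel.y.ravel(),
            "deprivation_decile": cov["deprivation_decile"].to_numpy()[ai],
            "facility_decile": cov["facility_decile"].to_numpy()[ai],
            "urban": cov["urban"].to_numpy()[ai],
        }
    )
    with _open_out(path, version_header) as fh:
        frame.to_csv(fh, index=False)


def read_panel(path, graph: SpatialGraph | None = None) -> PanelData:
    """Read a panel CSV; with a graph given, every area must be a graph
    node (referential integrity)."""
    frame = pd.read_csv(path, comment="#")
    missing = set(_PANEL_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"panel file missing columns: {sorted(missing)}")
    areas = list(dict.fromkeys(frame["area_id"]))
    ages = list(dict.fromkeys(frame["age_group"]))
    years = sorted(frame["year"].unique())
    if graph is not None:
        unknown = set(areas) - set(graph.node_ids)
        if unknown:
            raise ValueError(f"panel references areas absent from the graph: {sorted(unknown)[:5]}")
        areas = [v for v in graph.node_ids if v in set(areas)]
    shape = (len(areas), len(ages), len(years))
    if len(frame) != int(np.prod(shape)):
        raise ValueError("panel is not a complete area x age x year grid")
    a_idx = {v: i for i, v in enumerate(areas)}
    g_idx = {v: i for i, v in enumerate(ages)}
    t_idx = {v: i for i, v in enumerate(years)}
    y = np.zeros(shape)
    e = np.zeros(shape)
    for row in frame.itertuples(index=False):
        pos = (a_idx[row.area_id], g_idx[row.age_group], t_idx[row.year])
        y[pos] = row.cases
        e[pos] = row.py
    cov = (
        frame.drop_duplicates("area_id")
        .set_index("area_id")[
            ["deprivation_decile", "facility_decile", "urban", "province_id"]
        ]
        .loc[areas]
    )
    if not np.allclose(y, np.round(y)):
        y_arr = y
    else:
        y_arr = y.astype(int)
    return PanelData(
        y=y_arr, E=e, areas=tuple(areas), age_groups=tuple(ages),
        years=tuple(years), covariates=cov,
    )


def write_registry(registry: pd.DataFrame, path, version_header: bool = True) -> None:
    with _open_out(path, version_header) as fh:
        registry.to_csv(fh, index=False)


def read_registry(path) -> pd.DataFrame:
    frame = pd.read_csv(path, comment="#")
    required = {"area_id", "linked"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"registry file missing columns: {sorted(missing)}")
    for col in ("linked", "private", "geocode_valid", "excluded_region"):
        if col in frame.columns:
            frame[col] = frame[col].astype(bool)
    return frame


def write_table(frame: pd.DataFrame, path, version_header: bool = True) -> None:
    """Generic results table writer with the version comment header."""
    with _open_out(path, version_header) as fh:
        frame.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


@dataclass
class RunConfig:
    """Pipeline configuration loaded from a single JSON document.

    Sections: ``paths`` (graph/panel/registry/standard/output dir),
    ``model`` (random-effect flags and covariates), ``prior``
    (``sd.U``/``sd.alpha``, ``phi.U``/``phi.alpha``), ``sampler``
    (hyper draws, latent draws per hyper), ``correction`` (method and
    replicate count) and the master ``seed``.
    """

    paths: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)
    prior: dict = field(default_factory=dict)
    sampler: dict = field(default_factory=dict)
    correction: dict = field(default_factory=dict)
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_json(cls, path, check_paths: bool = True) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        cfg = cls(
            paths=doc.get("paths", {}),
            model=doc.get("model", {}),
            prior=doc.get("prior", {}),
            sampler=doc.get("sampler", {}),
            correction=doc.get("correction", {}),
            seed=int(doc.get("seed", 0)),
            log_level=doc.get("log_level", "INFO"),
        )
        if cfg.seed < 0:
            raise ValueError("seed must be a non-negative integer")
        if check_paths:
            for key, p in cfg.paths.items():
                if key != "output_dir" and not Path(p).exists():
                    raise FileNotFoundError(f"configured path {key} does not exist: {p}")
        return cfg

    def model_spec(self):
        from .model import ModelSpec

        m = self.model
        return ModelSpec(
            include_age=m.get("age", True),
            include_time=m.get("time", True),
            include_space=m.get("space", True),
            include_interaction=m.get("interaction", True),
            covariates=tuple(m.get("covariates", ())),
        )

    def prior_config(self):
        from .priors import PcPrecisionSpec, PriorConfig

        sd = self.prior.get("sd", {})
        phi = self.prior.get("phi", {})
        return PriorConfig(
            sd=PcPrecisionSpec(U=sd.get("U", 1.0), alpha=sd.get("alpha", 0.01)),
            phi_U=phi.get("U", 0.5),
            phi_alpha=phi.get("alpha", 2.0 / 3.0),
            fixed_effect_sd=self.prior.get("fixed_effect_sd", 10.0),
        )

    def run_config(self):
        from .inference import RunConfig as SamplerConfig

        s = self.sampler
        return SamplerConfig(
            n_hyper_draws=s.get("n_hyper_draws", 64),
            n_latent_per_hyper=s.get("n_latent_per_hyper", 16),
            seed=self.seed,
            hyper_sampler=s.get("hyper_sampler", "gaussian"),
        )
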