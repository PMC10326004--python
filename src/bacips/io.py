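"""Readers, writers and run manifests binding the pipeline stages.

File dialects
-------------
* Telemetry CSV: ``bird_id,date,x,y[,status]`` with ISO-8601 dates; status
  is ``alive`` (default) or ``dead``.
* Nest CSV: ``nest_id,bird_id,age_class,x,y,date_found,date_last_active,
  date_fate,fate``; fate labels are normalized case-insensitively
  (``HATCHED`` -> success, ``depredated`` -> failure, ...).
* Fire perimeters: GeoJSON FeatureCollection of Polygon/MultiPolygon
  features with ``name`` and ``start_date`` properties, coordinates in
  planar meters.
* Chains CSV: long format ``chain,iteration,parameter,value``.

Every pipeline run emits a JSON manifest recording the command, config
snapshot, seed, SHA-256 digests of the inputs, output paths, the R-hat
table and timestamps — enough to reproduce the run bit-identically.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .grouping import FireEvent, Location, normalize_fate
from .mcmc import ChainSet, SamplerConfig

__all__ = [
    "read_fire_geojson",
    "write_fire_geojson",
    "read_telemetry_csv",
    "write_telemetry_csv",
    "read_nest_csv",
    "write_nest_csv",
    "read_birds_csv",
    "read_chains_csv",
    "write_chains_csv",
    "write_summary",
    "RunManifest",
    "file_digest",
]

_TELEMETRY_COLS = ["bird_id", "date", "x", "y"]
_NEST_COLS = [
    "nest_id", "bird_id", "age_class", "x", "y",
    "date_found", "date_last_active", "date_fate", "fate",
]


def _parse_date(value, where: str) -> dt.date:
    try:
        return dt.date.fromisoformat(str(value).strip())
    except ValueError:
        raise ValueError(f"{where}: unparseable date {value!r}") from None


def read_fire_geojson(path) -> list[FireEvent]:
    """Parse fire perimeters from a GeoJSON FeatureCollection."""
    path = Path(path)
    data = json.loads(path.read_text())
    if data.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    fires = []
    for k, feat in enumerate(data.get("features", [])):
        props = feat.get("properties") or {}
        name = props.get("name", f"feature {k}")
        if "start_date" not in props:
            raise ValueError(f"{path}: feature {name!r} is missing a start_date property")
        geom = shape(feat["geometry"])
        if geom.geom_type not in ("Polygon", "MultiPolygon"):
            raise ValueError(
                f"{path}: feature {name!r} must be Polygon/MultiPolygon, got {geom.geom_type}"
            )
        fires.append(
            FireEvent(
                name=str(name),
                start_date=_parse_date(props["start_date"], f"{path}: feature {name!r}"),
                perimeter=geom,
            )
        )
    if not fires:
        raise ValueError(f"{path}: no fire features found")
    return fires


def write_fire_geojson(fires: Sequence[FireEvent], path) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": mapping(f.perimeter),
            "properties": {"name": f.name, "start_date": f.start_date.isoformat()},
        }
        for f in fires
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )


def read_telemetry_csv(path) -> list[Location]:
    """Parse telemetry relocations; optional ``status`` column (alive/dead)."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"bird_id": str})
    missing = [c for c in _TELEMETRY_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    has_status = "status" in df.columns
    locations = []
    for k, row in enumerate(df.itertuples(index=False), start=2):
        where = f"{path}, line {k}"
        try:
            locations.append(
                Location(
                    bird_id=str(row.bird_id),
                    date=_parse_date(row.date, where),
                    x=float(row.x),
                    y=float(row.y),
                    status=str(row.status).strip().lower() if has_status else "alive",
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{where}, column bird_id={row.bird_id!r}: {exc}") from exc
    return locations


def write_telemetry_csv(locations, path) -> None:
    if isinstance(locations, pd.DataFrame):
        locations.to_csv(path, index=False)
        return
    pd.DataFrame(
        [(l.bird_id, l.date.isoformat(), l.x, l.y, l.status) for l in locations],
        columns=_TELEMETRY_COLS + ["status"],
    ).to_csv(path, index=False)


def read_nest_csv(path) -> pd.DataFrame:
    """Parse raw nest monitoring rows; fate labels normalized, dates ISO."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"nest_id": str, "bird_id": str})
    missing = [c for c in _NEST_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    out = df.copy()
    for k, row in enumerate(df.itertuples(index=False), start=2):
        where = f"{path}, line {k}"
        try:
            fate = normalize_fate(row.fate)
        except ValueError as exc:
            raise ValueError(f"{where}, column fate: {exc}") from None
        found = _parse_date(row.date_found, f"{where}, column date_found")
        last = _parse_date(row.date_last_active, f"{where}, column date_last_active")
        fated = _parse_date(row.date_fate, f"{where}, column date_fate")
        if not found <= last <= fated:
            raise ValueError(
                f"{where}: non-monotone dates for nest {row.nest_id!r} "
                "(need found <= last_active <= fate)"
            )
        out.loc[k - 2, ["date_found", "date_last_active", "date_fate", "fate"]] = [
            found.isoformat(), last.isoformat(), fated.isoformat(), fate,
        ]
    return out


def write_nest_csv(nests: pd.DataFrame, path) -> None:
    nests.to_csv(path, index=False)


def read_birds_csv(path) -> dict[str, str]:
    """Capture table -> mapping bird_id -> age class at capture."""
    df = pd.read_csv(path, dtype={"bird_id": str})
    if "bird_id" not in df.columns or "age_at_capture" not in df.columns:
        raise ValueError(f"{path}: need columns bird_id, age_at_capture")
    ages = {}
    for row in df.itertuples(index=False):
        age = str(row.age_at_capture).strip().lower()
        if age not in ("yearling", "adult"):
            raise ValueError(f"{path}: unknown age class {row.age_at_capture!r}")
        ages[str(row.bird_id)] = age
    return ages


def write_chains_csv(chains: ChainSet, path) -> None:
    chains.to_long_dataframe().to_csv(path, index=False)


def read_chains_csv(path, config: SamplerConfig | None = None) -> ChainSet:
    df = pd.read_csv(path)
    names = list(dict.fromkeys(df["parameter"]))
    n_chains = df["chain"].nunique()
    n_iter = df["iteration"].nunique()
    draws = np.empty((n_chains, n_iter, len(names)))
    pos = {n: j for j, n in enumerate(names)}
    pivot = df.pivot_table(
        index=["chain", "iteration"], columns="parameter", values="value", sort=False
    )
    for name in names:
        draws[:, :, pos[name]] = pivot[name].to_numpy().reshape(n_chains, n_iter)
    cfg = config or SamplerConfig(
        n_chains=n_chains, n_iterations=2 * n_iter, burn_in=n_iter, thin=1
    )
    return ChainSet(draws=draws, param_names=names, config=cfg)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (dt.date, dt.datetime)):
            return obj.isoformat()
        return super().default(obj)


def write_summary(results: dict, path) -> None:
    """Write a results/summary JSON (full double precision; presentation
    rounding happens only at report time)."""
    Path(path).write_text(json.dumps(results, indent=2, cls=_NumpyEncoder, sort_keys=True))


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record emitted once per pipeline run."""

    command: str
    config: dict
    seed: int
    inputs: dict = field(default_factory=dict)  # path -> sha256
    outputs: list = field(default_factory=list)
    rhat: dict = field(default_factory=dict)
    started: str = ""
    finished: str = ""

    @classmethod
    def start(cls, command: str, config: dict, seed: int, inputs: Sequence = ()) -> "RunManifest":
        return cls(
            command=command,
            config=config,
            seed=seed,
            inputs={str(p): file_digest(p) for p in inputs},
            started=dt.datetime.now().isoformat(timespec="seconds"),
        )

    def finish(self, outputs: Sequence, rhat: dict | None = None) -> "RunManifest":
        self.outputs = [str(p) for p in outputs]
        self.rhat = {k: float(v) for k, v in (rhat or {}).items()}
        self.finished = dt.datetime.now().isoformat(timespec="seconds")
        return self

    def write(self, path) -> None:
        write_summary(asdict(self), path)
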