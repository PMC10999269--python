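"""Readers and writers for the tabular formats and study bundles.

All tables are TSV (UTF-8, '.' decimal); CSV is accepted on read via a
flag.  Ages are calibrated years BP throughout I/O; the model integrates
forward in model years with t = age_max - age_bp.

Formats
-------
record TSV
    First column ``taxon``; remaining columns are sample ids; cells are
    replicate counts.  A companion age table (``sample_id``, ``age_bp``
    and optionally ``n_replicates``) dates the samples.  A table without
    ``n_replicates`` is read as presence/absence (R = 1).
driver TSV
    Columns ``time_bp`` and ``value``.
trajectory TSV
    Long format: ``time``, ``site``, ``species``, ``abundance``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .model import TrajectorySet
from .observe import ObservationParams, SedaRecord
from .params import DriverSeries, MetacommunityParams

__all__ = [
    "SchemaError",
    "StudyBundle",
    "read_record",
    "write_record",
    "read_drivers",
    "write_drivers",
    "read_trajectory",
    "write_trajectory",
    "read_obs_params",
    "write_obs_params",
    "read_bundle",
    "write_bundle",
]


class SchemaError(ValueError):
    """A file violated the documented table dialect."""


def _read_table(path, sep: str):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    try:
        return pd.read_csv(path, sep=sep, float_precision="round_trip")
    except Exception as err:  # pragma: no cover - pandas error text varies
        raise SchemaError(f"{path}: could not parse table ({err})") from err


def read_record(path, age_table_path, *, sep: str = "\t") -> SedaRecord:
    """Read a taxon x sample replicate-count table plus its age table."""
    det = _read_table(path, sep)
    if det.columns[0] != "taxon":
        raise SchemaError(f"{path}: first column must be named 'taxon'")
    det = det.set_index("taxon")
    det.index.name = None
    if det.index.has_duplicates:
        dup = det.index[det.index.duplicated()][0]
        raise SchemaError(f"{path}: duplicate taxon name {dup!r}")

    ages = _read_table(age_table_path, sep)
    for col in ("sample_id", "age_bp"):
        if col not in ages.columns:
            raise SchemaError(f"{age_table_path}: missing column {col!r}")
    ages = ages.set_index("sample_id")
    if "n_replicates" in ages.columns:
        r_vals = ages["n_replicates"].unique()
        if r_vals.size != 1:
            raise SchemaError(
                f"{age_table_path}: n_replicates must be constant per lake"
            )
        n_replicates = int(r_vals[0])
    else:
        n_replicates = 1  # presence/absence dialect

    missing = [c for c in det.columns if c not in ages.index]
    if missing:
        raise SchemaError(
            f"{age_table_path}: no age for sample(s) {missing[:3]}"
        )
    age_series = ages.loc[list(det.columns), "age_bp"].astype(float)

    vals = det.to_numpy()
    if not np.issubdtype(vals.dtype, np.number):
        raise SchemaError(f"{path}: non-numeric detection counts")
    if np.any(vals != np.round(vals)):
        raise SchemaError(f"{path}: detection counts must be integers")
    vals = vals.astype(int)
    if vals.size and (vals.min() < 0 or vals.max() > n_replicates):
        i, j = np.unravel_index(
            np.argmax((vals < 0) | (vals > n_replicates)), vals.shape
        )
        raise SchemaError(
            f"{path}: count {vals[i, j]} for taxon {det.index[i]!r}, sample "
            f"{det.columns[j]!r} outside [0, {n_replicates}]"
        )
    return SedaRecord(
        lake=Path(path).stem,
        ages=age_series,
        detections=pd.DataFrame(vals, index=det.index, columns=det.columns),
        n_replicates=n_replicates,
    )


def write_record(record: SedaRecord, path, age_table_path) -> None:
    det = record.detections.copy()
    det.insert(0, "taxon", det.index)
    det.to_csv(path, sep="\t", index=False)
    ages = pd.DataFrame(
        {
            "sample_id": record.ages.index,
            "age_bp": record.ages.to_numpy(),
            "n_replicates": record.n_replicates,
        }
    )
    ages.to_csv(age_table_path, sep="\t", index=False, float_format="%.17g")


def read_drivers(path, *, sep: str = "\t", site: str | None = None) -> DriverSeries:
    """Read a two-column (time_bp, value) driver table."""
    tab = _read_table(path, sep)
    for col in ("time_bp", "value"):
        if col not in tab.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    t = tab["time_bp"].to_numpy(dtype=float)
    if np.unique(t).size != t.size:
        raise SchemaError(f"{path}: duplicate time_bp values")
    try:
        return DriverSeries(
            t, tab["value"].to_numpy(dtype=float),
            site=site or Path(path).stem,
        )
    except ValueError as err:
        raise SchemaError(f"{path}: {err}") from err


def write_drivers(series: DriverSeries, path) -> None:
    pd.DataFrame({"time_bp": series.times, "value": series.values}).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def write_trajectory(traj: TrajectorySet, path) -> None:
    S, L, T = traj.abundance.shape
    frame = pd.DataFrame(
        {
            "time": np.repeat(traj.times, S * L),
            "site": np.tile(np.repeat(np.arange(L), S), T),
            "species": np.tile(np.arange(S), L * T),
            "abundance": np.transpose(traj.abundance, (2, 1, 0)).ravel(),
        }
    )
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_trajectory(path, *, sep: str = "\t") -> TrajectorySet:
    tab = _read_table(path, sep)
    for col in ("time", "site", "species", "abundance"):
        if col not in tab.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    times = np.unique(tab["time"].to_numpy(dtype=float))
    S = int(tab["species"].max()) + 1
    L = int(tab["site"].max()) + 1
    abundance = np.zeros((S, L, times.size))
    t_ix = {t: j for j, t in enumerate(times)}
    for row in tab.itertuples(index=False):
        abundance[int(row.species), int(row.site), t_ix[float(row.time)]] = (
            row.abundance
        )
    return TrajectorySet(times=times, abundance=abundance)


def write_obs_params(obs: ObservationParams, path) -> None:
    payload = {
        "c": obs.c,
        "beta": obs.beta.tolist(),
        "fp": obs.fp,
        "n_replicates": obs.n_replicates,
        "seed": obs.seed,
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_obs_params(path) -> ObservationParams:
    d = yaml.safe_load(Path(path).read_text())
    return ObservationParams(
        c=d["c"],
        beta=np.asarray(d.get("beta", 1.0), dtype=float),
        fp=d.get("fp", 0.0),
        n_replicates=d.get("n_replicates", 8),
        seed=d.get("seed", 0),
    )


@dataclass
class StudyBundle:
    """One study's records, drivers and (for synthetic data) ground truth.

    Provenance carries the scenario name, seed, package version, the model
    time span and the initial state, so a synthetic bundle can be re-fitted
    without access to the generator.
    """

    records: list
    drivers: list
    params: MetacommunityParams | None = None
    obs: ObservationParams | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("a bundle needs at least one record")
        if len(self.drivers) < 1:
            raise ValueError("a bundle needs driver series")
        if self.params is not None and "seed" not in self.provenance:
            raise ValueError("synthetic bundles must record their seed")

    @property
    def t_span(self) -> tuple[float, float]:
        return tuple(self.provenance.get("t_span", (0.0, 0.0)))

    @property
    def age_max(self) -> float:
        return float(
            self.provenance.get("age_max", self.t_span[1] - self.t_span[0])
        )

    @property
    def initial_state(self) -> np.ndarray | None:
        init = self.provenance.get("initial_abundance")
        return None if init is None else np.asarray(init, dtype=float)

    def model_drivers(self) -> list:
        """Driver series converted from years BP to forward model time."""
        return [d.to_model_time(self.age_max) for d in self.drivers]


def write_bundle(bundle: StudyBundle, out_dir) -> None:
    out = Path(out_dir)
    (out / "records").mkdir(parents=True, exist_ok=True)
    (out / "drivers").mkdir(exist_ok=True)
    for rec in bundle.records:
        write_record(
            rec,
            out / "records" / f"{rec.lake}.tsv",
            out / "records" / f"{rec.lake}.ages.tsv",
        )
    for k, drv in enumerate(bundle.drivers):
        write_drivers(drv, out / "drivers" / f"site{k}.tsv")
    if bundle.params is not None:
        bundle.params.to_yaml(out / "params.yaml")
    if bundle.obs is not None:
        write_obs_params(bundle.obs, out / "obs.yaml")
    manifest = dict(bundle.provenance)
    manifest["lakes"] = [r.lake for r in bundle.records]
    manifest["site_index"] = {
        r.lake: r.site_index for r in bundle.records if r.site_index is not None
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_bundle(in_dir) -> StudyBundle:
    src = Path(in_dir)
    manifest_path = src / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no such bundle manifest: {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    records = []
    for lake in manifest["lakes"]:
        rec = read_record(
            src / "records" / f"{lake}.tsv",
            src / "records" / f"{lake}.ages.tsv",
        )
        rec.site_index = manifest.get("site_index", {}).get(lake)
        records.append(rec)
    driver_paths = sorted(
        (src / "drivers").glob("site*.tsv"),
        key=lambda p: int(p.stem.removeprefix("site")),
    )
    drivers = [read_drivers(p) for p in driver_paths]
    params = None
    if (src / "params.yaml").exists():
        params = MetacommunityParams.from_yaml(src / "params.yaml")
    obs = None
    if (src / "obs.yaml").exists():
        obs = read_obs_params(src / "obs.yaml")
    return StudyBundle(
        records=records,
        drivers=drivers,
        params=params,
        obs=obs,
        provenance=manifest,
    )
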