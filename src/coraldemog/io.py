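"""Readers/writers for the package's tabular and config formats.

CSV dialect: comma-separated, UTF-8, mandatory header row, '.' decimal —
fixed so that round-trip tests can be bit-exact.  Schema violations are
reported with row/column context via :class:`SchemaError`.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .matrices import GROWTH_FORMS, N_STAGES, LifeTableSample, TransitionMatrix
from .projection import CoverProxyConfig, SizeDistribution, cover_from_distribution
from .scenarios import ImpactScenario

__all__ = [
    "SchemaError",
    "RunManifest",
    "read_life_tables",
    "write_life_tables",
    "matrix_to_json",
    "matrix_from_json",
    "read_size_distributions",
    "write_size_distributions",
    "write_trajectory",
    "read_scenario_yaml",
    "write_scenario_yaml",
    "write_manifest",
    "read_manifest",
]


class SchemaError(ValueError):
    """A file violates its documented schema; message carries row/column."""


def read_life_tables(path: "str | Path") -> dict[str, list[LifeTableSample]]:
    """Life-table CSV -> pools per growth form.

    Columns: growth_form, stage (1-5), sigma, duration, source_label; one
    row per stage per sample, samples identified by (growth_form,
    source_label).
    """
    df = pd.read_csv(path)
    required = {"growth_form", "stage", "sigma", "duration", "source_label"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
    pools: dict[str, list[LifeTableSample]] = {}
    for (gf, label), grp in df.groupby(["growth_form", "source_label"], sort=True):
        if gf not in GROWTH_FORMS:
            row = int(grp.index[0]) + 2
            raise SchemaError(
                f"{path} row {row}, column 'growth_form': unknown value {gf!r}"
            )
        if sorted(grp["stage"]) != list(range(1, N_STAGES + 1)):
            raise SchemaError(
                f"{path}: sample {label!r} ({gf}) must have stages 1..5 exactly"
            )
        grp = grp.sort_values("stage")
        for col, lo, hi in (("sigma", 0.0, 1.0),):
            bad = grp[(grp[col] < lo) | (grp[col] > hi)]
            if len(bad):
                row = int(bad.index[0]) + 2
                raise SchemaError(
                    f"{path} row {row}, column '{col}': value outside [{lo}, {hi}]"
                )
        try:
            sample = LifeTableSample(
                growth_form=str(gf),
                sigma=grp["sigma"].to_numpy(),
                duration=grp["duration"].to_numpy(),
                source_label=str(label),
            )
        except ValueError as e:
            raise SchemaError(f"{path}: sample {label!r}: {e}") from e
        pools.setdefault(str(gf), []).append(sample)
    return pools


def write_life_tables(
    pools: Mapping[str, Sequence[LifeTableSample]], path: "str | Path"
) -> None:
    rows = []
    for gf in sorted(pools):
        for lt in pools[gf]:
            for s in range(N_STAGES):
                rows.append(
                    {
                        "growth_form": gf,
                        "stage": s + 1,
                        "sigma": lt.sigma[s],
                        "duration": int(lt.duration[s]),
                        "source_label": lt.source_label,
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def matrix_to_json(
    tm: TransitionMatrix,
    path: "str | Path",
    provenance: Mapping[str, Any] | None = None,
) -> None:
    """Matrix JSON: row-major 5x5 array, fertility, lambda, provenance."""
    payload = {
        "growth_form": tm.growth_form,
        "A": tm.A.tolist(),
        "fertility": list(tm.fertility),
        "lambda": tm.lambda_,
        "provenance": dict(provenance or {}),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def matrix_from_json(path: "str | Path") -> TransitionMatrix:
    payload = json.loads(Path(path).read_text())
    try:
        return TransitionMatrix(
            A=np.asarray(payload["A"], dtype=float),
            growth_form=payload.get("growth_form", "branching_encrusting"),
        )
    except (KeyError, ValueError) as e:
        raise SchemaError(f"{path}: {e}") from e


_SD_COLUMNS = ["habitat", "depth_zone", "year"] + [
    f"class_{c}" for c in range(1, N_STAGES + 1)
]


def read_size_distributions(path: "str | Path") -> list[SizeDistribution]:
    df = pd.read_csv(path)
    missing = set(_SD_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
    out = []
    for idx, row in df.iterrows():
        counts = row[[f"class_{c}" for c in range(1, N_STAGES + 1)]].to_numpy(float)
        neg = np.flatnonzero(counts < 0)
        if neg.size:
            raise SchemaError(
                f"{path} row {int(idx) + 2}, column 'class_{int(neg[0]) + 1}': "
                f"negative count {counts[neg[0]]}"
            )
        year = row["year"]
        out.append(
            SizeDistribution(
                n=counts,
                habitat=str(row["habitat"]),
                depth_zone=str(row["depth_zone"]),
                year=None if pd.isna(year) else int(year),
            )
        )
    return out


def write_size_distributions(
    dists: Sequence[SizeDistribution], path: "str | Path"
) -> None:
    rows = []
    for d in dists:
        row: dict[str, Any] = {
            "habitat": d.habitat,
            "depth_zone": d.depth_zone,
            "year": d.year,
        }
        row.update({f"class_{c + 1}": d.n[c] for c in range(N_STAGES)})
        rows.append(row)
    pd.DataFrame(rows, columns=_SD_COLUMNS).to_csv(path, index=False)


def write_trajectory(
    traj: Sequence[SizeDistribution],
    path: "str | Path",
    cover_cfg: CoverProxyConfig | None = None,
) -> None:
    """Trajectory CSV: year, per-class counts and the cover proxy."""
    cfg = cover_cfg or CoverProxyConfig()
    rows = []
    for t, d in enumerate(traj):
        row: dict[str, Any] = {"year": d.year if d.year is not None else t}
        row.update({f"class_{c + 1}": d.n[c] for c in range(N_STAGES)})
        row["cover_cm2"] = cover_from_distribution(d, cfg)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_scenario_yaml(path: "str | Path") -> ImpactScenario:
    """Scenario YAML -> ImpactScenario, bounds-checked before any compute."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {
        "recruitment_loss_rate",
        "episodic_mortality",
        "event_interval",
        "affected_classes",
        "horizon",
    }
    unknown = set(raw) - known
    if unknown:
        raise SchemaError(f"{path}: unknown key(s) {sorted(unknown)}")
    if "affected_classes" in raw:
        raw["affected_classes"] = frozenset(int(c) for c in raw["affected_classes"])
    try:
        return ImpactScenario(**raw)
    except (TypeError, ValueError) as e:
        raise SchemaError(f"{path}: {e}") from e


def write_scenario_yaml(scenario: ImpactScenario, path: "str | Path") -> None:
    payload = {
        "recruitment_loss_rate": scenario.recruitment_loss_rate,
        "episodic_mortality": scenario.episodic_mortality,
        "event_interval": scenario.event_interval,
        "affected_classes": sorted(scenario.affected_classes),
        "horizon": scenario.horizon,
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


@dataclass(frozen=True)
class RunManifest:
    """Provenance of one pipeline run: command, config, seeds, inputs."""

    command: str
    config: Mapping[str, Any]
    rng_seeds: Mapping[str, int]
    input_digests: Mapping[str, str]
    package_version: str
    timestamp: str


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(
    out_dir: "str | Path",
    command: str,
    config: Mapping[str, Any],
    rng_seeds: Mapping[str, int],
    inputs: Sequence["str | Path"] = (),
) -> RunManifest:
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        command=command,
        config=dict(config),
        rng_seeds=dict(rng_seeds),
        input_digests={str(p): _digest(Path(p)) for p in inputs},
        package_version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    (out_dir / "manifest.json").write_text(json.dumps(asdict(manifest), indent=2))
    return manifest


def read_manifest(out_dir: "str | Path") -> RunManifest:
    payload = json.loads((Path(out_dir) / "manifest.json").read_text())
    return RunManifest(**payload)
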