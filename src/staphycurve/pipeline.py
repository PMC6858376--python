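"""One reproducible run: simulate -> screen -> metrics -> report.

All randomness flows from a single root seed that is split per stage, so a
run is fully regenerable from its manifest (seed + config hash + package
version).  Every artifact is a plain CSV/JSON file readable by the other
modules.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analysis import build_report, cohort_frame
from .core import Cohort, Group, Provenance
from .eligibility import DOME_THRESHOLD_UM, screen_cohort
from .errors import ConfigError, StaphyCurveError
from .io import write_cohort
from .metrics import compute_metrics
from .synthetic import (
    GeometryRanges,
    GroupDistribution,
    default_group_distributions,
    generate_group_geometry,
    sample_cohort_metrics,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: Path = Path("staphycurve_run")
    mode: str = "metrics"  # "metrics" | "geometry"
    seed: int = 0
    n_geometry: int = 50
    dome_threshold_um: float = DOME_THRESHOLD_UM
    equal_var: bool = True
    correlation_method: str = "pearson"
    x_unit_scale: float = 1.0
    groups: dict[Group, GroupDistribution] = field(
        default_factory=default_group_distributions
    )
    geometry_ranges: GeometryRanges = field(default_factory=GeometryRanges)

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if self.mode not in ("metrics", "geometry"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.dome_threshold_um <= 0:
            raise ConfigError("dome threshold must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        groups = payload.pop("groups", None)
        cfg = cls(**payload)
        if groups:
            cfg.groups = {
                Group(g): GroupDistribution(**params) for g, params in groups.items()
            }
        return cfg

    def digest(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            if isinstance(o, (Path, Group)):
                return str(o)
            return repr(o)

        payload = json.dumps(dataclasses.asdict(self), default=default, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


def _stage_seed(root: int, stage: str) -> int:
    h = hashlib.sha256(f"{root}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def compute_cohort_metrics(
    cohort: Cohort, x_unit_scale: float = 1.0
) -> pd.DataFrame:
    """Per-eye metrics table: computed from profiles where present,
    otherwise carried over from the records."""
    rows = []
    for rec in cohort.records:
        if rec.profile_h is not None and rec.profile_v is not None:
            m = compute_metrics(rec.profile_h, rec.profile_v, x_unit_scale)
        elif rec.metrics is not None:
            m = rec.metrics
        else:
            raise StaphyCurveError(
                f"eye {rec.patient_id}/{rec.eye.value} has neither profiles nor metrics"
            )
        row = {"patient_id": rec.patient_id, "eye": rec.eye.value}
        row.update(m.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate -> screen -> metrics -> report; return the manifest."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "staphycurve",
        "version": __version__,
        "seed": config.seed,
        "mode": config.mode,
        "config_sha256": config.digest(),
        "outputs": {},
        "status": "incomplete",
    }
    manifest_path = out / "manifest.json"
    try:
        sim_seed = _stage_seed(config.seed, "simulate")
        if config.mode == "metrics":
            cohort = sample_cohort_metrics(config.groups, seed=sim_seed)
        else:
            cohort = Cohort(
                records=[
                    r
                    for g, dist in config.groups.items()
                    for r in generate_group_geometry(
                        n=min(config.n_geometry, dist.n),
                        ranges=config.geometry_ranges,
                        seed=_stage_seed(config.seed, f"simulate:{g.value}"),
                        group=g,
                        dist=dist,
                    ).records
                ],
                provenance=Provenance.SYNTHETIC_GEOMETRY,
                seed=sim_seed,
            )
        cohort_path = out / "cohort.csv"
        write_cohort(cohort, cohort_path)
        manifest["outputs"]["cohort"] = cohort_path.name
        logger.info("simulated %d eyes (%s mode)", len(cohort), config.mode)

        screening = screen_cohort(cohort, dome_threshold_um=config.dome_threshold_um)
        screening_rows = [
            {
                "patient_id": pid,
                "eye": eye,
                "eligible": outcome.eligible,
                "reasons": ";".join(r.value for r in outcome.reasons),
            }
            for (pid, eye), outcome in screening.outcomes.items()
        ]
        screening_path = out / "screening.csv"
        pd.DataFrame(screening_rows).to_csv(screening_path, index=False)
        manifest["outputs"]["screening"] = screening_path.name
        eligible = screening.eligible
        logger.info("%d of %d eyes eligible", len(eligible), len(cohort))

        metrics_path = out / "metrics.csv"
        metrics = compute_cohort_metrics(eligible, config.x_unit_scale)
        metrics.to_csv(metrics_path, index=False)
        manifest["outputs"]["metrics"] = metrics_path.name

        report_path = out / "report.json"
        if len(eligible) > 0:
            report = build_report(
                eligible,
                metrics=metrics,
                equal_var=config.equal_var,
                correlation_method=config.correlation_method,
            )
            report_path.write_text(json.dumps(report.to_json_dict(), indent=1))
            frame = cohort_frame(eligible, metrics)
        else:
            report_path.write_text(json.dumps({}))
            frame = pd.DataFrame()
        manifest["outputs"]["report"] = report_path.name
        eyes_path = out / "eyes.csv"
        frame.to_csv(eyes_path, index=False)
        manifest["outputs"]["eyes"] = eyes_path.name
        manifest["status"] = "complete"
    finally:
        manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
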