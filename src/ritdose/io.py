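"""Readers, writers, run configuration and report provenance.

CSV schemas (RFC-4180, UTF-8, '.' decimal separator):

* binding:          ``cells,bound_fraction``
* competition:      ``conc_nM,counts``
* internalization:  ``time_h,internalized,membrane,medium_protein,medium_free``
* raw biodist:      ``animal_id,tissue,day,counts,weight_g,body_weight_g,offset_h``
* biodist table:    ``antibody,tissue,day,mean_pid_g,sd_pid_g,n``
* tumor growth:     ``animal_id,arm,day,width_mm,height_mm,depth_mm,body_weight_g``
* apoptosis:        ``arm,field_id,tunel_positive,total_cells``

Reports are JSON with a provenance block (package version, config hash, seed,
inputs); no timestamps are embedded, so identical runs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .binding import CellBindingCurve, CompetitionCurve, InternalizationTimecourse
from .biodist import SAMPLE_COLUMNS, TissueSample
from .outcomes import ApoptosisFieldCounts, GrowthRecord, TumorMeasurement, tumor_volume

__all__ = [
    "RunConfig",
    "read_binding_csv",
    "read_competition_csv",
    "read_internalization_csv",
    "read_samples_csv",
    "read_growth_csv",
    "read_apoptosis_csv",
    "provenance_block",
    "write_report",
]


def _require_columns(df: pd.DataFrame, required: Sequence[str], path, kind: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(
            f"{kind} CSV {path}: missing required column(s) {missing}; "
            f"expected header {','.join(required)}"
        )
    if df.empty:
        raise ValueError(f"{kind} CSV {path}: no data rows")


@dataclass
class RunConfig:
    """Pipeline run configuration; round-trips through YAML unchanged."""

    nuclide_overrides: list = field(default_factory=list)
    reference_body_weight_g: float = 20.0
    anchor_zero_at_origin: bool = True
    disappearance_threshold_mm3: float = 1.0
    regrowth_factor: float = 2.0
    observation_end_day: float = 28.0
    allowed_cr_exceptions: int = 1
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"config {path}: unknown key(s) {sorted(unknown)}")
        return cls(**data)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def read_binding_csv(path) -> CellBindingCurve:
    df = pd.read_csv(path)
    _require_columns(df, ["cells", "bound_fraction"], path, "binding")
    return CellBindingCurve(
        cells_per_tube=df["cells"].to_numpy(float),
        bound_fraction=df["bound_fraction"].to_numpy(float),
        label=str(Path(path).stem),
    )


def read_competition_csv(path, labeled_conc_nM: float) -> CompetitionCurve:
    df = pd.read_csv(path)
    _require_columns(df, ["conc_nM", "counts"], path, "competition")
    return CompetitionCurve(
        competitor_conc_nM=df["conc_nM"].to_numpy(float),
        bound_signal=df["counts"].to_numpy(float),
        labeled_conc_nM=labeled_conc_nM,
        label=str(Path(path).stem),
    )


def read_internalization_csv(path) -> InternalizationTimecourse:
    df = pd.read_csv(path)
    cols = ["time_h", "internalized", "membrane", "medium_protein", "medium_free"]
    _require_columns(df, cols, path, "internalization")
    df = df.sort_values("time_h")
    return InternalizationTimecourse(
        times_h=df["time_h"].to_numpy(float),
        counts=df[cols[1:]].to_numpy(float),
        label=str(Path(path).stem),
    )


def read_samples_csv(path) -> list[TissueSample]:
    df = pd.read_csv(path)
    _require_columns(df, SAMPLE_COLUMNS, path, "raw biodistribution")
    return [
        TissueSample(
            animal_id=str(r.animal_id),
            tissue=str(r.tissue),
            day=float(r.day),
            counts=float(r.counts),
            weight_g=float(r.weight_g),
            body_weight_g=float(r.body_weight_g),
            counting_time_offset_h=float(r.offset_h),
        )
        for r in df.itertuples()
    ]


def write_samples_csv(samples: Sequence[TissueSample], path) -> None:
    rows = [
        {
            "animal_id": s.animal_id,
            "tissue": s.tissue,
            "day": s.day,
            "counts": s.counts,
            "weight_g": s.weight_g,
            "body_weight_g": s.body_weight_g,
            "offset_h": s.counting_time_offset_h,
        }
        for s in samples
    ]
    pd.DataFrame(rows, columns=SAMPLE_COLUMNS).to_csv(path, index=False)


def read_growth_csv(path) -> list[GrowthRecord]:
    """Read caliper measurements and assemble per-animal growth records."""
    df = pd.read_csv(path)
    cols = ["animal_id", "arm", "day", "width_mm", "height_mm", "depth_mm"]
    _require_columns(df, cols, path, "tumor growth")
    records = []
    for (animal, arm), sub in df.groupby(["animal_id", "arm"], sort=True):
        sub = sub.sort_values("day")
        vols = [
            tumor_volume(
                TumorMeasurement(str(animal), float(r.day), float(r.width_mm),
                                 float(r.height_mm), float(r.depth_mm))
            )
            for r in sub.itertuples()
        ]
        bw = sub["body_weight_g"].to_numpy(float) if "body_weight_g" in sub.columns else None
        records.append(
            GrowthRecord(
                animal_id=str(animal), arm=str(arm),
                days=sub["day"].to_numpy(float),
                volumes_mm3=np.asarray(vols), body_weights_g=bw,
            )
        )
    return records


def write_growth_csv(records: Sequence[GrowthRecord], path) -> None:
    """Write growth records as caliper rows (volume encoded as a cube: v = whd/2)."""
    rows = []
    for rec in records:
        for i, (d, v) in enumerate(zip(rec.days, rec.volumes_mm3)):
            edge = (2.0 * v) ** (1.0 / 3.0)  # equivalent cube with whd/2 = v
            rows.append(
                {
                    "animal_id": rec.animal_id, "arm": rec.arm, "day": d,
                    "width_mm": edge, "height_mm": edge, "depth_mm": edge,
                    "body_weight_g": (
                        rec.body_weights_g[i] if rec.body_weights_g is not None else ""
                    ),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_apoptosis_csv(path) -> list[ApoptosisFieldCounts]:
    df = pd.read_csv(path)
    _require_columns(df, ["arm", "field_id", "tunel_positive", "total_cells"], path, "apoptosis")
    return [
        ApoptosisFieldCounts(
            arm=str(arm),
            tunel_positive=sub["tunel_positive"].to_numpy(float),
            total_cells=sub["total_cells"].to_numpy(float),
        )
        for arm, sub in df.groupby("arm", sort=True)
    ]


def provenance_block(config: Optional[RunConfig] = None, seed: Optional[int] = None,
                     inputs: Optional[Sequence[str]] = None) -> dict:
    """Machine-readable provenance attached to every report."""
    block = {"package": "ritdose", "version": _pkg_version}
    if config is not None:
        block["config_hash"] = config.hash()
    if seed is not None:
        block["seed"] = int(seed)
    if inputs:
        block["inputs"] = [str(p) for p in inputs]
    return block


def write_report(report: dict, path: str | Path) -> None:
    """Serialize a report as deterministic, diff-able JSON."""
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
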