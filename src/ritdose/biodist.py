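"""Biodistribution processing: %ID/g tables and derived ratios.

Raw gamma-counter samples are converted to percent injected dose per gram
(%ID/g), decay-corrected to injection time and normalized to a 20-g mouse,
then aggregated into a tissue × day table (mean ± SD, n) mirroring the layout
of published biodistribution tables. Published tables for the two anti-c-kit
antibodies ([111In]12A8 and [111In]67A2 in SY-xenograft mice, 5 mice per time
point at days 1, 2, 4, 7 and 10) ship as packaged CSV fixtures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .physics import Nuclide, decay_factor, get_nuclide

__all__ = [
    "TissueSample",
    "BiodistributionTable",
    "percent_id_per_gram",
    "build_table",
    "tumor_to_blood_ratio",
    "load_packaged_table",
    "REFERENCE_BODY_WEIGHT_G",
    "TABLE_COLUMNS",
    "SAMPLE_COLUMNS",
]

#: Body weight every %ID/g value is normalized to, in grams.
REFERENCE_BODY_WEIGHT_G = 20.0

TABLE_COLUMNS = ["antibody", "tissue", "day", "mean_pid_g", "sd_pid_g", "n"]
SAMPLE_COLUMNS = ["animal_id", "tissue", "day", "counts", "weight_g", "body_weight_g", "offset_h"]

_PACKAGED = {"12A8": "table1_12A8.csv", "67A2": "table2_67A2.csv"}


@dataclass(frozen=True)
class TissueSample:
    """One gamma-counted tissue from one animal at one time point."""

    animal_id: str
    tissue: str
    day: float
    counts: float
    weight_g: float
    body_weight_g: float
    counting_time_offset_h: float = 0.0

    def __post_init__(self) -> None:
        if self.day < 0:
            raise ValueError("day must be >= 0 (day 0 = injection)")
        if self.counts < 0:
            raise ValueError("counts must be >= 0")
        if not self.weight_g > 0:
            raise ValueError("tissue weight must be > 0 g")
        if not self.body_weight_g > 0:
            raise ValueError("body weight must be > 0 g")
        if self.counting_time_offset_h < 0:
            raise ValueError("counting time offset must be >= 0 h")

    @property
    def body_weight_plausible(self) -> bool:
        """True when body weight falls in the typical mouse range 10–40 g."""
        return 10.0 <= self.body_weight_g <= 40.0


def percent_id_per_gram(
    sample: TissueSample,
    injected_standard_cpm: float,
    nuclide: Nuclide,
    reference_bw_g: float = REFERENCE_BODY_WEIGHT_G,
) -> float:
    """Decay-corrected, body-weight-normalized %ID/g for one sample.

    raw %ID/g = 100 × counts / (standard × tissue weight); decay correction
    divides by the physical decay factor over the counting delay; body-weight
    normalization multiplies by body_weight / reference (heavier animals are
    adjusted upward onto the 20-g reference).
    """
    if not injected_standard_cpm > 0:
        raise ValueError("injected standard must be > 0 cpm")
    raw = 100.0 * sample.counts / (injected_standard_cpm * sample.weight_g)
    corrected = raw / decay_factor(nuclide, sample.counting_time_offset_h)
    return corrected * sample.body_weight_g / reference_bw_g


@dataclass(frozen=True)
class BiodistributionTable:
    """Tissue × day grid of %ID/g summaries (mean, SD with n−1 denominator, n).

    ``data`` is a tidy frame with columns ``tissue, day, mean_pid_g, sd_pid_g, n``.
    """

    antibody: str
    nuclide: Nuclide
    data: pd.DataFrame
    injected_activity_kBq: Optional[float] = None
    protein_dose_ug: Optional[float] = None

    def __post_init__(self) -> None:
        df = self.data.reset_index(drop=True)
        missing = {"tissue", "day", "mean_pid_g", "sd_pid_g", "n"} - set(df.columns)
        if missing:
            raise ValueError(f"table missing columns: {sorted(missing)}")
        if (df["mean_pid_g"] < 0).any() or (df["sd_pid_g"] < 0).any():
            raise ValueError("mean and SD %ID/g must be >= 0")
        if (df["n"] < 1).any():
            raise ValueError("n must be >= 1 in every cell")
        if df.duplicated(["tissue", "day"]).any():
            raise ValueError("duplicate (tissue, day) cells")
        df = df.sort_values(["tissue", "day"], kind="stable").reset_index(drop=True)
        object.__setattr__(self, "data", df)

    @property
    def days(self) -> np.ndarray:
        return np.sort(self.data["day"].unique())

    @property
    def tissues(self) -> list[str]:
        return list(dict.fromkeys(self.data["tissue"]))

    def cell(self, tissue: str, day: float) -> tuple[float, float, int]:
        """(mean, SD, n) for one tissue at one day."""
        row = self.data[(self.data["tissue"] == tissue) & (self.data["day"] == day)]
        if row.empty:
            raise KeyError(f"no cell for tissue {tissue!r} at day {day}")
        r = row.iloc[0]
        return float(r["mean_pid_g"]), float(r["sd_pid_g"]), int(r["n"])

    def tissue_curve(self, tissue: str) -> tuple[np.ndarray, np.ndarray]:
        """(days, mean %ID/g) for one tissue, in increasing day order."""
        sub = self.data[self.data["tissue"] == tissue].sort_values("day")
        if sub.empty:
            raise KeyError(f"tissue {tissue!r} not in table (has {self.tissues})")
        return sub["day"].to_numpy(float), sub["mean_pid_g"].to_numpy(float)

    def to_csv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.insert(0, "antibody", self.antibody)
        out[TABLE_COLUMNS].to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls,
        path,
        nuclide: Nuclide | str = "In-111",
        antibody: Optional[str] = None,
        **meta,
    ) -> "BiodistributionTable":
        df = pd.read_csv(path)
        missing = set(TABLE_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(
                f"biodistribution CSV {path} missing required columns {sorted(missing)}; "
                f"expected header {','.join(TABLE_COLUMNS)}"
            )
        if antibody is None:
            labels = df["antibody"].unique()
            if len(labels) != 1:
                raise ValueError(f"CSV mixes antibody labels {list(labels)}; pass antibody=")
            antibody = str(labels[0])
        if isinstance(nuclide, str):
            nuclide = get_nuclide(nuclide)
        return cls(antibody=antibody, nuclide=nuclide, data=df.drop(columns=["antibody"]), **meta)


def build_table(
    samples: Sequence[TissueSample],
    injected_standard_cpm: float,
    nuclide: Nuclide,
    antibody: str = "",
    reference_bw_g: float = REFERENCE_BODY_WEIGHT_G,
    **meta,
) -> BiodistributionTable:
    """Aggregate raw samples into a BiodistributionTable.

    Each animal is normalized individually (decay and body weight), then cells
    are summarized as mean ± sample SD (n−1; SD 0 when n = 1).
    """
    if not samples:
        raise ValueError("no samples")
    rows = [
        {
            "tissue": s.tissue,
            "day": s.day,
            "pid_g": percent_id_per_gram(s, injected_standard_cpm, nuclide, reference_bw_g),
        }
        for s in samples
    ]
    df = pd.DataFrame(rows)
    grouped = (
        df.groupby(["tissue", "day"], as_index=False)["pid_g"]
        .agg(mean_pid_g="mean", sd_pid_g=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0, n="size")
    )
    return BiodistributionTable(antibody=antibody, nuclide=nuclide, data=grouped, **meta)


def tumor_to_blood_ratio(
    table: BiodistributionTable, day: float, tumor: str = "Tumor", blood: str = "Blood"
) -> float:
    """Mean tumor %ID/g divided by mean blood %ID/g at one day.

    The body-weight normalization cancels in the ratio.
    """
    t_mean, _, _ = table.cell(tumor, day)
    b_mean, _, _ = table.cell(blood, day)
    if b_mean == 0:
        raise ZeroDivisionError(f"blood mean is 0 at day {day}; ratio undefined")
    return t_mean / b_mean


def load_packaged_table(antibody: str) -> BiodistributionTable:
    """Load a packaged published biodistribution table ("12A8" or "67A2").

    Values are the printed decay-corrected %ID/g means ± SD (n = 5 mice per
    day) normalized to a 20-g mouse; 37 kBq of the 111In-labeled antibody and
    a 20 µg protein dose per mouse.
    """
    try:
        fname = _PACKAGED[antibody]
    except KeyError:
        raise KeyError(f"no packaged table for {antibody!r}; available: {sorted(_PACKAGED)}") from None
    with resources.as_file(resources.files("ritdose.data") / fname) as p:
        return BiodistributionTable.from_csv(
            p, nuclide="In-111", injected_activity_kBq=37.0, protein_dose_ug=20.0
        )
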