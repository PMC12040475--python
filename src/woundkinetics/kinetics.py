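"""Healing-distance kinetics.

Converts raw longitudinal wound measurements (widths in mm, or elliptic
areas in mm^2) into healing-distance records, the response of the mixed
model.  The healing distance at time t is

    d(t) = reference - size(t),

where the reference is the size at t = 0 when the trajectory is largest
there, and otherwise the maximum observed size (wounds can enlarge during
the early inflammatory phase before closure begins).  Distances are
clipped below at 0 so that 0 <= d(t) <= reference always holds.

Epithelial closure is well described as linear in time, so downstream the
per-group slope of d(t) on t is the healing rate in mm/day.

Measurements are typically performed in duplicate; replicates default to
entering the model as repeated measures (``mode="keep"``) and can be
averaged per time point for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import EllipseRelation, width_from_area

__all__ = [
    "SPECIES",
    "SETTINGS",
    "WoundObservation",
    "SchemaError",
    "reference_size",
    "healing_distances",
    "natural_wound_to_widths",
    "merge_replicates",
    "observations_to_healing_records",
    "read_observations",
    "write_observations",
    "read_healing_records",
    "write_healing_records",
]

SPECIES = frozenset(
    {"vervet", "sykes", "baboon", "chimpanzee", "human", "rat", "mouse", "other"}
)
SETTINGS = frozenset({"experimental", "natural"})
KINDS = frozenset({"width", "area"})

#: factors that convert declared input units to internal mm / mm^2
_UNIT_FACTORS = {"mm": 1.0, "cm": 10.0, "mm2": 1.0, "cm2": 100.0}
_UNIT_KIND = {"mm": "width", "cm": "width", "mm2": "area", "cm2": "area"}

OBS_COLUMNS = [
    "individual_id", "species", "setting", "time_days", "kind", "value", "replicate",
]
RECORD_COLUMNS = [
    "individual_id", "species", "setting", "time_days", "healing_distance_mm", "replicate",
]


class SchemaError(ValueError):
    """Raised when an observations table violates the input schema."""


@dataclass(frozen=True)
class WoundObservation:
    """One raw measurement of one wound at one time point."""

    individual_id: str
    species: str
    setting: str
    time_days: float
    kind: str  # "width" (mm) or "area" (mm^2)
    value: float
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        if self.setting not in SETTINGS:
            raise ValueError(f"unknown setting {self.setting!r}")
        if self.kind not in KINDS:
            raise ValueError(f"kind must be 'width' or 'area', got {self.kind!r}")
        if self.value < 0:
            raise ValueError(f"measurement value must be >= 0, got {self.value}")
        if self.time_days < 0:
            raise ValueError(f"time must be >= 0 days, got {self.time_days}")
        if self.replicate < 1:
            raise ValueError(f"replicate index must be >= 1, got {self.replicate}")


def observations_frame(obs) -> pd.DataFrame:
    """Assemble WoundObservation instances into the tidy observations table."""
    return pd.DataFrame(
        [
            {
                "individual_id": o.individual_id,
                "species": o.species,
                "setting": o.setting,
                "time_days": o.time_days,
                "kind": o.kind,
                "value": o.value,
                "replicate": o.replicate,
            }
            for o in obs
        ],
        columns=OBS_COLUMNS,
    )


def _validate_observations(df: pd.DataFrame) -> None:
    missing = [c for c in OBS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"observations table missing columns: {missing}")
    if len(df) == 0:
        raise SchemaError("observations table is empty")
    bad: list[str] = []
    for idx, row in df.iterrows():
        problems = []
        # table-level species is an open label set (custom simulation groups
        # are legitimate); the strict enum lives on WoundObservation
        if not isinstance(row["species"], str) or not row["species"]:
            problems.append(f"species={row['species']!r}")
        if row["setting"] not in SETTINGS:
            problems.append(f"setting={row['setting']!r}")
        if row["kind"] not in KINDS:
            problems.append(f"kind={row['kind']!r}")
        if not np.isfinite(row["value"]) or row["value"] < 0:
            problems.append(f"value={row['value']!r}")
        if not np.isfinite(row["time_days"]) or row["time_days"] < 0:
            problems.append(f"time_days={row['time_days']!r}")
        if problems:
            bad.append(f"row {idx}: " + ", ".join(problems))
    if bad:
        raise SchemaError("invalid observations:\n" + "\n".join(bad[:20]))


def reference_size(sizes, times=None) -> float:
    """Reference wound size of one trajectory (one wound, one replicate).

    The reference is the size at t = 0 when that is the maximum; when the
    wound enlarged first (inflammatory phase) the maximum observed size is
    used instead.  Either way this is the maximum of the trajectory.
    """
    sizes = np.asarray(sizes, dtype=float)
    if sizes.size == 0:
        raise ValueError("empty trajectory has no reference size")
    if times is not None:
        times = np.asarray(times, dtype=float)
        if times.shape != sizes.shape:
            raise ValueError("times and sizes must have matching shapes")
    return float(np.max(sizes))


def healing_distances(trajectory: pd.DataFrame) -> pd.DataFrame:
    """Healing-distance records for a width trajectory table.

    ``trajectory`` must carry the observation columns with ``kind`` all
    "width"; the reference rule is applied per (individual, replicate) and
    distances are clipped below at 0.  The t=0 distance is 0 only for
    trajectories whose maximum occurs at t=0; under the max-reference rule
    an inflamed wound has a positive distance at baseline.
    """
    if len(trajectory) == 0:
        raise ValueError("empty trajectory")
    kinds = set(trajectory["kind"].unique())
    if kinds != {"width"}:
        raise ValueError(
            f"healing distances require width observations only, got kinds {sorted(kinds)}; "
            "convert areas with natural_wound_to_widths first"
        )
    out = []
    for (ind, rep), grp in trajectory.groupby(["individual_id", "replicate"], sort=False):
        grp = grp.sort_values("time_days")
        ref = reference_size(grp["value"].to_numpy())
        dist = np.clip(ref - grp["value"].to_numpy(), 0.0, None)
        out.append(
            pd.DataFrame(
                {
                    "individual_id": ind,
                    "species": grp["species"].to_numpy(),
                    "setting": grp["setting"].to_numpy(),
                    "time_days": grp["time_days"].to_numpy(),
                    "healing_distance_mm": dist,
                    "replicate": rep,
                }
            )
        )
    records = pd.concat(out, ignore_index=True)
    # hard invariant: 0 <= distance <= reference for every record
    assert (records["healing_distance_mm"] >= 0).all()
    return records


def natural_wound_to_widths(
    area_trajectory: pd.DataFrame, rel: EllipseRelation, form: str = "derived"
) -> pd.DataFrame:
    """Convert an elliptic-area trajectory to a width trajectory.

    Applies the positive-root quadratic inversion pointwise and re-indexes
    time so that each wound's first photographed day serves as t = 0
    (natural wounds are first seen some days after injury; the day of
    injury is not needed because only the variation of width over time
    enters the healing rate).
    """
    if len(area_trajectory) == 0:
        raise ValueError("empty trajectory")
    kinds = set(area_trajectory["kind"].unique())
    if kinds != {"area"}:
        raise ValueError(f"expected area observations only, got kinds {sorted(kinds)}")
    if (area_trajectory["value"] < 0).any():
        raise ValueError("negative wound area")
    df = area_trajectory.copy()
    df["value"] = width_from_area(df["value"].to_numpy(), rel, form=form)
    df["kind"] = "width"
    df["time_days"] = df.groupby("individual_id")["time_days"].transform(
        lambda t: t - t.min()
    )
    return df


def merge_replicates(records: pd.DataFrame, mode: str = "keep") -> pd.DataFrame:
    """Handle duplicate measurements.

    mode="keep" (default) passes replicates through unchanged; they enter
    the mixed model as repeated measures.  mode="average" collapses to the
    per-(individual, time) mean with replicate index 1.
    """
    if mode == "keep":
        return records
    if mode != "average":
        raise ValueError(f"mode must be 'keep' or 'average', got {mode!r}")
    grouped = (
        records.groupby(
            ["individual_id", "species", "setting", "time_days"], sort=False, as_index=False
        )["healing_distance_mm"]
        .mean()
    )
    grouped["replicate"] = 1
    return grouped[RECORD_COLUMNS]


def observations_to_healing_records(
    obs: pd.DataFrame,
    rel: EllipseRelation | None = None,
    replicates: str = "keep",
    form: str = "derived",
) -> pd.DataFrame:
    """Full kinetics pipeline: observations table -> healing records.

    Area observations require an :class:`EllipseRelation`; width and area
    wounds may coexist in one table (they are converted separately and the
    records concatenated).
    """
    _validate_observations(obs)
    pieces = []
    widths = obs[obs["kind"] == "width"]
    areas = obs[obs["kind"] == "area"]
    if len(areas):
        if rel is None:
            raise ValueError(
                "area observations present but no width-length relation supplied"
            )
        pieces.append(natural_wound_to_widths(areas, rel, form=form))
    if len(widths):
        pieces.append(widths)
    combined = pd.concat(pieces, ignore_index=True)
    records = healing_distances(combined)
    return merge_replicates(records, mode=replicates)


# ---------------------------------------------------------------------------
# CSV I/O (tidy schemas; units are declared explicitly, never guessed)

def read_observations(path: str | Path) -> pd.DataFrame:
    """Read observations.csv, converting declared units to mm / mm^2.

    Columns: individual_id, species, setting, time_days, kind, value,
    unit {mm, cm, mm2, cm2}, replicate.  The unit must agree with the kind
    (linear units for widths, square units for areas).
    """
    df = pd.read_csv(path, dtype={"individual_id": str})
    required = OBS_COLUMNS + ["unit"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    bad_units = sorted(set(df["unit"]) - set(_UNIT_FACTORS))
    if bad_units:
        raise SchemaError(f"{path}: unknown units {bad_units}")
    mismatch = df[df.apply(lambda r: _UNIT_KIND[r["unit"]] != r["kind"], axis=1)]
    if len(mismatch):
        raise SchemaError(
            f"{path}: unit/kind mismatch at rows {list(mismatch.index[:10])}"
        )
    df["value"] = df["value"] * df["unit"].map(_UNIT_FACTORS)
    df = df.drop(columns=["unit"])
    _validate_observations(df)
    return df


def write_observations(df: pd.DataFrame, path: str | Path) -> None:
    """Write the observations schema with explicit mm/mm^2 units."""
    out = df.copy()
    out["unit"] = np.where(out["kind"] == "width", "mm", "mm2")
    cols = OBS_COLUMNS[:6] + ["unit", "replicate"]
    extra = [c for c in out.columns if c not in cols]
    out[cols + extra].to_csv(path, index=False)


def read_healing_records(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"individual_id": str})
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    return df


def write_healing_records(df: pd.DataFrame, path: str | Path) -> None:
    cols = RECORD_COLUMNS + [c for c in df.columns if c not in RECORD_COLUMNS]
    df[cols].to_csv(path, index=False)
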