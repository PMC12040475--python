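"""Synthetic longitudinal wound-trajectory generator.

Emulates the statistical structure the comparative analysis assumes: each
individual heals linearly at its own rate (population rate plus a random
slope deviation), observation times follow species-specific schedules,
every observation carries biological noise, and each observation is read
out in duplicate with independent measurement noise.  Experimental wounds
are circular widths (a 40 mm full-thickness circular excision at t = 0);
natural wounds are elliptic and reported as surface areas linked to widths
by the day-1 width-length relation.  An optional inflammation bump
enlarges the wound before a peak day so the max-reference rule downstream
gets exercised.

All randomness flows from a single integer seed; identical configurations
produce byte-identical CSV output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import EllipseRelation, ellipse_area, length_from_width
from .kinetics import write_observations

__all__ = [
    "SpeciesSimProfile",
    "SimulationConfig",
    "simulate_dataset",
    "make_study_emulation",
    "PRESETS",
]

#: day-1 width-length relation of wild-baboon natural wounds (slope, intercept mm)
NATURAL_WL_RELATION = EllipseRelation(a=0.121, b=3.963)


@dataclass(frozen=True)
class InflammationBump:
    """Multiplicative early enlargement: size * (1 + peak_fraction * tri(t)).

    ``tri`` rises linearly from 0 at t=0 to 1 at ``peak_day`` and falls
    back to 0 by 2*peak_day — a minimal triangular mechanism whose only
    purpose is to make the maximum wound size occur after baseline.
    """

    peak_fraction: float = 0.15
    peak_day: float = 2.0

    def factor(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        tri = np.clip(1.0 - np.abs(t - self.peak_day) / self.peak_day, 0.0, None)
        return 1.0 + self.peak_fraction * tri


@dataclass(frozen=True)
class SpeciesSimProfile:
    """Generating parameters for one species/group.

    true_rate is the population healing rate in mm/day; re_cov the 2x2
    covariance of per-individual (intercept, slope) deviations on the raw
    day scale; resid_sd the biological (within-individual) noise SD in mm;
    schedule the (min, max) day gap between successive observations.
    """

    label: str
    true_rate: float
    n_individuals: int
    re_cov: tuple = ((0.25, 0.0), (0.0, 0.0025))  # SDs 0.5 mm, 0.05 mm/d
    resid_sd: float = 1.0
    intercept: float = 0.0
    schedule: tuple = (2, 3)
    horizon: float = 21.0
    wound_mode: str = "circular_width"  # or "elliptic_area"
    initial_size: float = 40.0  # mm width (circular) / mm width on day 1 (elliptic)
    setting: str = "experimental"
    inflammation_bump: InflammationBump | None = None

    def __post_init__(self) -> None:
        if self.true_rate < 0:
            raise ValueError("true_rate must be >= 0")
        if self.resid_sd < 0:
            raise ValueError("resid_sd must be >= 0")
        cov = np.asarray(self.re_cov, dtype=float)
        if cov.shape != (2, 2):
            raise ValueError("re_cov must be 2x2")
        eig = np.linalg.eigvalsh(cov)
        if eig[0] < -1e-10:
            raise ValueError("re_cov must be positive semi-definite")
        if self.wound_mode not in ("circular_width", "elliptic_area"):
            raise ValueError(f"unknown wound_mode {self.wound_mode!r}")
        if not (1 <= self.schedule[0] <= self.schedule[1]):
            raise ValueError("schedule must satisfy 1 <= min <= max")


@dataclass(frozen=True)
class SimulationConfig:
    """Whole-dataset generating configuration; the seed is mandatory."""

    profiles: tuple
    seed: int
    n_replicate_measurements: int = 2
    replicate_sd: float = 0.3
    w_l_relation: EllipseRelation = NATURAL_WL_RELATION

    def to_yaml(self, path: str | Path | None = None) -> str:
        d = {
            "seed": self.seed,
            "n_replicate_measurements": self.n_replicate_measurements,
            "replicate_sd": self.replicate_sd,
            "w_l_relation": self.w_l_relation.to_dict(),
            "profiles": [
                {
                    **{k: v for k, v in asdict(p).items() if k != "inflammation_bump"},
                    "re_cov": np.asarray(p.re_cov).tolist(),
                    "schedule": list(p.schedule),
                    "inflammation_bump": (
                        asdict(p.inflammation_bump) if p.inflammation_bump else None
                    ),
                }
                for p in self.profiles
            ],
        }
        text = yaml.safe_dump(d, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text


def _sample_times(rng: np.random.Generator, schedule, horizon) -> np.ndarray:
    """First observation at t=0, then uniform integer gaps until the horizon."""
    lo, hi = schedule
    times = [0.0]
    while times[-1] < horizon:
        times.append(times[-1] + rng.integers(lo, hi + 1))
    if times[-1] > horizon:
        times.pop()
    return np.asarray(times, dtype=float)


def simulate_dataset(config: SimulationConfig):
    """Generate (observations, ground_truth) tables from the config.

    For each individual: draw (u0, u1) ~ N(0, re_cov); the underlying
    width is max(0, initial - intercept_dev - (rate + u1) * t), optionally
    inflated by the inflammation bump; biological noise is added once per
    time point and each replicate reading adds independent measurement
    noise.  Elliptic-mode trajectories are converted width -> (length,
    area) through the forward ellipse model and emitted as areas; once the
    underlying width falls below the relation intercept b (where the
    implied length would be negative) emission stops for that wound.
    """
    rng = np.random.default_rng(config.seed)
    obs_rows = []
    truth_rows = []
    rel = config.w_l_relation
    for profile in config.profiles:
        cov = np.asarray(profile.re_cov, dtype=float)
        try:
            chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:  # singular PSD (e.g. exact zeros)
            w, V = np.linalg.eigh(cov)
            chol = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
        for i in range(profile.n_individuals):
            ind = f"{profile.label}_{i + 1:03d}"
            u0, u1 = chol @ rng.standard_normal(2)
            slope = profile.true_rate + u1
            times = _sample_times(rng, profile.schedule, profile.horizon)
            width_true = np.clip(
                profile.initial_size - (profile.intercept + u0) - slope * times, 0.0, None
            )
            if profile.inflammation_bump is not None:
                width_true = width_true * profile.inflammation_bump.factor(times)
            bio = rng.normal(0.0, profile.resid_sd, size=len(times))
            width_obs = np.clip(width_true + bio, 0.0, None)
            for t, w in zip(times, width_obs):
                reps = np.clip(
                    w + rng.normal(0.0, config.replicate_sd,
                                   size=config.n_replicate_measurements),
                    0.0, None,
                )
                for r, wr in enumerate(reps, start=1):
                    if profile.wound_mode == "circular_width":
                        obs_rows.append(
                            (ind, profile.label, profile.setting, t, "width", wr, r)
                        )
                    else:
                        if wr < rel.b:
                            continue  # beyond the validity of the W-L relation
                        L = length_from_width(wr, rel)
                        S = ellipse_area(length=L, width=wr)
                        obs_rows.append(
                            (ind, profile.label, profile.setting, t, "area", S, r)
                        )
            truth_rows.append(
                {
                    "individual_id": ind,
                    "species": profile.label,
                    "true_rate": profile.true_rate,
                    "realized_slope": slope,
                    "u0": u0,
                    "u1": u1,
                }
            )
    obs = pd.DataFrame(
        obs_rows,
        columns=["individual_id", "species", "setting", "time_days", "kind",
                 "value", "replicate"],
    )
    truth = pd.DataFrame(truth_rows)
    return obs, truth


# ---------------------------------------------------------------------------
# presets

_MONKEY_SCHEDULE = (2, 3)
_CHIMP_SCHEDULE = (2, 7)
_RODENT_SCHEDULE = (1, 2)
_HUMAN_SCHEDULE = (3, 7)  # outpatient follow-up cadence; a package choice

_NONHUMAN_RATE = 0.6   # mm/day, headline non-human primate/rodent rate
_HUMAN_RATE = 0.25     # mm/day, headline human rate
_BABOON_NATURAL_RATE = 0.613  # mm/day, wild-baboon natural wounds


def _study_profiles() -> tuple:
    """Group sizes of the comparative study: baboon/sykes/vervet 6/5/6,
    chimpanzee 5, human 24, mouse 8, rat 4; 40 mm experimental wounds."""
    mk = dict(schedule=_MONKEY_SCHEDULE, horizon=21.0)
    return (
        SpeciesSimProfile(label="vervet", true_rate=_NONHUMAN_RATE, n_individuals=6, **mk),
        SpeciesSimProfile(label="sykes", true_rate=_NONHUMAN_RATE, n_individuals=5, **mk),
        SpeciesSimProfile(label="baboon", true_rate=_NONHUMAN_RATE, n_individuals=6, **mk),
        SpeciesSimProfile(
            label="chimpanzee", true_rate=_NONHUMAN_RATE, n_individuals=5,
            schedule=_CHIMP_SCHEDULE, horizon=21.0, setting="natural",
        ),
        SpeciesSimProfile(
            label="human", true_rate=_HUMAN_RATE, n_individuals=24,
            schedule=_HUMAN_SCHEDULE, horizon=22.0,
        ),
        SpeciesSimProfile(
            label="mouse", true_rate=_NONHUMAN_RATE, n_individuals=8,
            schedule=_RODENT_SCHEDULE, horizon=14.0,
        ),
        SpeciesSimProfile(
            label="rat", true_rate=_NONHUMAN_RATE, n_individuals=4,
            schedule=_RODENT_SCHEDULE, horizon=14.0,
        ),
    )


def _preset_study(seed: int) -> SimulationConfig:
    return SimulationConfig(profiles=_study_profiles(), seed=seed)


def _preset_null_two_groups(seed: int) -> SimulationConfig:
    """Calibration design: two identical groups, 6 individuals each, a fixed
    2-day schedule giving exactly 8 visits, one reading per visit.

    A single reading keeps the residual structure correctly specified:
    duplicate readings of the same photograph share the biological noise of
    that time point, which the repeated-measures treatment ignores, so a
    calibration run with duplicates would not isolate the test's own error
    rate."""
    prof = dict(
        true_rate=_NONHUMAN_RATE, n_individuals=6, schedule=(2, 2), horizon=14.0,
    )
    return SimulationConfig(
        profiles=(
            SpeciesSimProfile(label="group_a", **prof),
            SpeciesSimProfile(label="group_b", **prof),
        ),
        seed=seed,
        n_replicate_measurements=1,
    )


def _preset_baboon_wild(seed: int) -> SimulationConfig:
    """Wild-baboon natural wounds: elongated elliptic lacerations reported
    as areas, 5 individuals, the day-1 W-L relation (0.121, 3.963)."""
    return SimulationConfig(
        profiles=(
            SpeciesSimProfile(
                label="baboon", true_rate=_BABOON_NATURAL_RATE, n_individuals=5,
                schedule=(1, 4), horizon=14.0, wound_mode="elliptic_area",
                initial_size=18.0, setting="natural",
            ),
        ),
        seed=seed,
        w_l_relation=NATURAL_WL_RELATION,
    )


PRESETS = {
    "study": _preset_study,
    "null_two_groups": _preset_null_two_groups,
    "baboon_wild": _preset_baboon_wild,
}


def make_study_emulation(preset: str, seed: int = 0) -> SimulationConfig:
    """Return a named study-emulation configuration.

    Presets: "study" (all seven groups at their headline generating
    rates), "null_two_groups" (two identical groups for calibration runs),
    "baboon_wild" (elliptic natural wounds at 0.613 mm/day).
    """
    try:
        factory = PRESETS[preset]
    except KeyError:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    return factory(seed)


def write_dataset(config: SimulationConfig, outdir: str | Path):
    """Simulate and write observations.csv, ground_truth.csv, config.yaml."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    obs, truth = simulate_dataset(config)
    write_observations(obs, outdir / "observations.csv")
    truth.to_csv(outdir / "ground_truth.csv", index=False)
    config.to_yaml(outdir / "config.yaml")
    return obs, truth
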