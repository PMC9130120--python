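"""Synthetic two-arm trial generator with known ground truth.

Emulates an activity-tracker trial in recent retirees: ~231 subjects
randomized 1:1 with sex-stratified allocation, ~83% women, age ~
N(65.2, 1.1^2), accelerometer blocks of 7-8 measured days per timepoint.
Day-level 24-h compositions are drawn logistic-normally: each subject's
balance-coordinate mean is the configured group x timepoint mean plus a
random intercept and a random time slope, and days scatter around it with
independent ilr noise — so every generated day is strictly positive by
construction and geometric-mean aggregation is exactly arithmetic
averaging in coordinate space.

Real-data blemishes are injected at configurable rates: invalid days
(waking wear under 10 h), records with one behavior missing, and records
with near-zero MVPA (below the 0.5-min screen). The ground truth —
fixed-effect vector per coordinate, per-subject random effects, and the
pre-corruption values of every doctored record — is returned alongside
the data for parameter-recovery testing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict

import numpy as np
import pandas as pd

from .balances import ilr, ilr_inverse, movement_partition
from .composition import MINUTES_PER_DAY, closure, compositional_mean
from .preprocess import PART_COLS

__all__ = [
    "TRIAL_MEAN_TABLE",
    "TrialConfig",
    "TrialTruth",
    "TrialData",
    "generate_trial",
    "inject_effect",
    "null_interaction_config",
    "simulate_coordinate_panel",
    "write_trial",
]

#: Group x timepoint mean compositions (SED, LPA, MVPA, sleep; minutes of a
#: 1440-min day) the generator is centered on by default.
TRIAL_MEAN_TABLE: dict[tuple[str, str], tuple[float, ...]] = {
    ("control", "baseline"): (677.5, 217.3, 42.5, 502.7),
    ("control", "m3"): (661.0, 233.7, 43.9, 501.4),
    ("control", "m6"): (664.6, 235.1, 42.5, 497.8),
    ("control", "m12"): (684.9, 215.9, 39.9, 499.3),
    ("intervention", "baseline"): (670.8, 224.3, 51.5, 493.5),
    ("intervention", "m3"): (669.6, 231.5, 50.3, 488.5),
    ("intervention", "m6"): (658.9, 246.4, 43.6, 491.1),
    ("intervention", "m12"): (681.0, 210.6, 46.5, 501.9),
}


def _default_means():
    return {
        (g, tp): TRIAL_MEAN_TABLE[(g, tp)]
        for g in ("control", "intervention")
        for tp in ("baseline", "m6")
    }


@dataclass(frozen=True)
class TrialConfig:
    """All knobs of the generator; defaults emulate the trial's conditions.

    SD vectors are per balance coordinate (active/passive, LPA/MVPA,
    SED/sleep). ``subject_sd`` is the between-subject intercept SD,
    ``slope_sd`` the random time-slope SD per month, ``day_sd`` the
    day-to-day noise SD. ``injected_effect`` shifts the intervention mean
    of one coordinate by beta x months — the known group x time effect for
    recovery experiments.
    """

    n_intervention: int = 117
    n_control: int = 114
    proportion_women: float = 0.83
    age_mean: float = 65.2
    age_sd: float = 1.1
    timepoints: tuple[str, ...] = ("baseline", "m6")
    time_values: tuple[tuple[str, float], ...] = (("baseline", 0.0), ("m6", 6.0))
    mean_compositions: dict = field(default_factory=_default_means)
    subject_sd: tuple[float, ...] = (0.50, 0.37, 0.15)
    slope_sd: tuple[float, ...] = (0.030, 0.034, 0.015)
    day_sd: tuple[float, ...] = (0.45, 0.40, 0.20)
    days_min: int = 7
    days_max: int = 8
    day_length_mean: float = 1420.0
    day_length_sd: float = 10.0
    invalid_day_rate: float = 0.05
    missing_rate: float = 0.007
    sublimit_rate: float = 0.007
    sublimit_low: float = 0.05
    sublimit_high: float = 0.45
    injected_effect: tuple[int, float] | None = None
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_intervention, self.n_control) < 1:
            raise ValueError("need at least one subject per arm")
        for name in ("proportion_women", "invalid_day_rate", "missing_rate", "sublimit_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("subject_sd", "slope_sd", "day_sd"):
            if min(getattr(self, name)) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 1 <= self.days_min <= self.days_max:
            raise ValueError("invalid measured-days range")
        if not 0 < self.sublimit_low < self.sublimit_high < 0.5:
            raise ValueError("sub-limit MVPA range must sit inside (0, 0.5) min")
        for key in [(g, tp) for g in ("control", "intervention") for tp in self.timepoints]:
            if key not in self.mean_compositions:
                raise ValueError(f"mean composition missing for cell {key}")

    def time_map(self) -> dict[str, float]:
        return dict(self.time_values)

    def cell_coords(self) -> dict[tuple[str, str], np.ndarray]:
        """ilr coordinates of each group x timepoint mean, with any injected
        group x time effect folded into the intervention cells."""
        part = movement_partition()
        tmap = self.time_map()
        out = {}
        for (g, tp), mean in self.mean_compositions.items():
            z = ilr(closure(np.asarray(mean, dtype=float)), part)
            if self.injected_effect is not None and g == "intervention":
                k, beta = self.injected_effect
                z = z.copy()
                z[k - 1] += beta * tmap[tp]
            out[(g, tp)] = z
        return out

    def true_fixed_effects(self) -> dict[str, dict[str, float]]:
        """Generating fixed-effect values per coordinate, months time scale.

        Defined for two-timepoint configs (a line through two points);
        gender and age play no role in the generating model.
        """
        tmap = self.time_map()
        if len(self.timepoints) != 2:
            raise ValueError("true fixed effects are defined for two-timepoint configs")
        t0, t1 = (self.timepoints[0], self.timepoints[1])
        dt = tmap[t1] - tmap[t0]
        cells = self.cell_coords()
        out = {}
        for k in range(3):
            zc0, zc1 = cells[("control", t0)][k], cells[("control", t1)][k]
            zi0, zi1 = cells[("intervention", t0)][k], cells[("intervention", t1)][k]
            out[f"z{k + 1}"] = {
                "(Intercept)": float(zc0),
                "Gender": 0.0,
                "Age": 0.0,
                "Group": float(zi0 - zc0),
                "Time": float((zc1 - zc0) / dt),
                "Group*Time": float(((zi1 - zi0) - (zc1 - zc0)) / dt),
            }
        return out


@dataclass
class TrialTruth:
    """Ground truth of one generated trial."""

    fixed_effects: dict
    subject_effects: pd.DataFrame  # subject_id, b0_z1..b0_z3, b1_z1..b1_z3
    corrupted: pd.DataFrame  # subject_id, timepoint, kind, part, true_value
    config: TrialConfig

    def to_json(self, path) -> None:
        payload = {
            "fixed_effects": self.fixed_effects,
            "subject_effects": self.subject_effects.to_dict(orient="records"),
            "corrupted": self.corrupted.to_dict(orient="records"),
            "config": _config_dict(self.config),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=float)


def _config_dict(config: TrialConfig) -> dict:
    d = asdict(config)
    d["mean_compositions"] = {f"{g}/{tp}": list(v) for (g, tp), v in config.mean_compositions.items()}
    return d


@dataclass
class TrialData:
    days: pd.DataFrame
    subjects: pd.DataFrame
    truth: TrialTruth


def inject_effect(config: TrialConfig, coordinate_index: int, beta: float) -> TrialConfig:
    """Add a known group x time effect on one balance coordinate.

    Shifts only the intervention cells, by ``beta`` per month along the
    chosen coordinate; the other coordinates' true means are untouched.
    ``beta = 0`` leaves the generating process unchanged.
    """
    if coordinate_index not in (1, 2, 3):
        raise ValueError(f"coordinate_index must be 1, 2 or 3, got {coordinate_index}")
    if beta == 0.0:
        return replace(config, injected_effect=None)
    return replace(config, injected_effect=(coordinate_index, float(beta)))


def null_interaction_config(**overrides) -> TrialConfig:
    """Default-conditions config whose true group x time interaction is zero.

    Control cells keep their defaults; the intervention follow-up mean is
    the intervention baseline perturbed by the control group's change, so
    group and time effects remain but the interaction vanishes exactly.
    """
    part = movement_partition()
    base = TrialConfig(**overrides)
    tmap = base.time_map()
    tps = sorted(base.timepoints, key=tmap.get)
    t0 = tps[0]
    means = dict(base.mean_compositions)
    zc = {tp: ilr(closure(np.asarray(means[("control", tp)], dtype=float)), part) for tp in tps}
    zi0 = ilr(closure(np.asarray(means[("intervention", t0)], dtype=float)), part)
    for tp in tps[1:]:
        znew = zi0 + (zc[tp] - zc[t0])
        means[("intervention", tp)] = tuple(
            ilr_inverse(znew, part, MINUTES_PER_DAY).tolist()
        )
    return replace(base, mean_compositions=means)


def _make_subjects(config: TrialConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_intervention + config.n_control
    n_women = int(rng.binomial(n, config.proportion_women))
    # sex-stratified allocation: women split between the arms in proportion
    # to the arm sizes, men fill the remainder
    w_int = int(round(n_women * config.n_intervention / n))
    w_int = min(max(w_int, n_women - config.n_control), config.n_intervention)
    groups, genders = [], []
    for arm, n_arm, n_w in (
        ("intervention", config.n_intervention, w_int),
        ("control", config.n_control, n_women - w_int),
    ):
        sexes = np.array(["woman"] * n_w + ["man"] * (n_arm - n_w))
        rng.shuffle(sexes)
        groups.extend([arm] * n_arm)
        genders.extend(sexes.tolist())
    order = rng.permutation(n)
    return pd.DataFrame(
        {
            "subject_id": [f"S{i + 1:04d}" for i in range(n)],
            "group": np.array(groups)[order],
            "gender": np.array(genders)[order],
            "age": np.round(rng.normal(config.age_mean, config.age_sd, n), 1),
        }
    )


def generate_trial(config: TrialConfig | None = None) -> TrialData:
    """Generate one trial: day records, subject covariates and ground truth.

    Deterministic given the config (all randomness flows from
    ``config.seed`` through per-stage substreams, so e.g. raising the
    missingness rate does not reshuffle the day-level draws).
    """
    config = config or TrialConfig()
    config.validate()
    part = movement_partition()
    streams = np.random.SeedSequence(config.seed).spawn(6)
    rng_subj, rng_eff, rng_day, rng_invalid, rng_sub, rng_miss = (
        np.random.default_rng(s) for s in streams
    )

    subjects = _make_subjects(config, rng_subj)
    n = len(subjects)
    b0 = rng_eff.normal(0.0, config.subject_sd, size=(n, 3))
    b1 = rng_eff.normal(0.0, config.slope_sd, size=(n, 3))
    cells = config.cell_coords()
    tmap = config.time_map()

    day_rows = []
    record_index = []  # (subject_id, timepoint, first_row, n_days)
    for i, subj in subjects.iterrows():
        for tp in config.timepoints:
            z_mean = cells[(subj["group"], tp)] + b0[i] + b1[i] * tmap[tp]
            n_days = int(rng_day.integers(config.days_min, config.days_max + 1))
            eps = rng_day.normal(0.0, config.day_sd, size=(n_days, 3))
            props = ilr_inverse(z_mean + eps, part)
            day_len = rng_day.normal(config.day_length_mean, config.day_length_sd, n_days)
            minutes = props * day_len[:, None]
            nonwear = np.abs(rng_day.normal(20.0, 10.0, n_days))
            wear = day_len - minutes[:, 3] - nonwear
            record_index.append((subj["subject_id"], tp, len(day_rows), n_days))
            for d in range(n_days):
                day_rows.append(
                    {
                        "subject_id": subj["subject_id"],
                        "timepoint": tp,
                        "day_index": d + 1,
                        "sed_min": minutes[d, 0],
                        "lpa_min": minutes[d, 1],
                        "mvpa_min": minutes[d, 2],
                        "sleep_min": minutes[d, 3],
                        "waking_wear_min": wear[d],
                        "day_length_min": day_len[d],
                    }
                )
    days = pd.DataFrame(day_rows)

    # invalid days: recorded wear drops below the 10-h rule
    invalid = rng_invalid.random(len(days)) < config.invalid_day_rate
    days.loc[invalid, "waking_wear_min"] = rng_invalid.uniform(300.0, 599.0, int(invalid.sum()))

    corrupted = []
    # near-zero MVPA records: scale the record's days so the aggregated
    # MVPA lands inside the configured sub-limit window, moving the freed
    # minutes into SED
    for sid, tp, start, n_days in record_index:
        if rng_sub.random() >= config.sublimit_rate:
            continue
        rows = days.index[start : start + n_days]
        block = days.loc[rows, list(PART_COLS)].to_numpy()
        agg = compositional_mean(block, MINUTES_PER_DAY)
        target = rng_sub.uniform(config.sublimit_low, config.sublimit_high)
        f = target / agg[2]
        freed = block[:, 2] * (1.0 - f)
        days.loc[rows, "mvpa_min"] = block[:, 2] * f
        days.loc[rows, "sed_min"] = block[:, 0] + freed
        corrupted.append(
            {"subject_id": sid, "timepoint": tp, "kind": "sublimit_mvpa",
             "part": "mvpa_min", "true_value": float(agg[2])}
        )

    # missing behavior: one part unrecorded for a whole subject-timepoint
    already = {(c["subject_id"], c["timepoint"]) for c in corrupted}
    for sid, tp, start, n_days in record_index:
        if (sid, tp) in already or rng_miss.random() >= config.missing_rate:
            continue
        part_col = PART_COLS[int(rng_miss.integers(0, 4))]
        rows = days.index[start : start + n_days]
        block = days.loc[rows, list(PART_COLS)].to_numpy()
        agg = compositional_mean(block, MINUTES_PER_DAY)
        corrupted.append(
            {"subject_id": sid, "timepoint": tp, "kind": "missing",
             "part": part_col, "true_value": float(agg[list(PART_COLS).index(part_col)])}
        )
        days.loc[rows, part_col] = np.nan

    truth = TrialTruth(
        fixed_effects=config.true_fixed_effects() if len(config.timepoints) == 2 else {},
        subject_effects=pd.DataFrame(
            {
                "subject_id": subjects["subject_id"],
                **{f"b0_z{k + 1}": b0[:, k] for k in range(3)},
                **{f"b1_z{k + 1}": b1[:, k] for k in range(3)},
            }
        ),
        corrupted=pd.DataFrame(
            corrupted, columns=["subject_id", "timepoint", "kind", "part", "true_value"]
        ),
        config=config,
    )
    return TrialData(days=days, subjects=subjects, truth=truth)


def simulate_coordinate_panel(
    config: TrialConfig, coordinate_index: int, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Subject-timepoint panel of one balance coordinate, analysis-ready.

    Draws directly at the resolution the mixed model sees: the record's
    coordinate value is the subject mean plus aggregate noise with SD
    day_sd / sqrt(n_days). Because geometric-mean aggregation is arithmetic
    averaging in ilr space, this is distribution-identical to generating
    full day files (with no corrupt records) and running the preprocessing
    — and orders of magnitude faster for replicated simulations.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    k = coordinate_index - 1
    subjects = _make_subjects(config, rng)
    n = len(subjects)
    b0 = rng.normal(0.0, config.subject_sd[k], n)
    b1 = rng.normal(0.0, config.slope_sd[k], n)
    cells = config.cell_coords()
    tmap = config.time_map()
    rows = []
    for tp in config.timepoints:
        t = tmap[tp]
        mu = np.array([cells[(g, tp)][k] for g in subjects["group"]])
        n_days = rng.integers(config.days_min, config.days_max + 1, n)
        noise = rng.normal(0.0, config.day_sd[k] / np.sqrt(n_days))
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": subjects["subject_id"],
                    "group": subjects["group"],
                    "gender": subjects["gender"],
                    "age": subjects["age"],
                    "timepoint": tp,
                    "time": t,
                    "z": mu + b0 + b1 * t + noise,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def write_trial(trial: TrialData, out_dir, float_format: str = "%.6f") -> dict:
    """Write days.csv, subjects.csv and truth.json; returns the paths."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "days": out / "days.csv",
        "subjects": out / "subjects.csv",
        "truth": out / "truth.json",
    }
    trial.days.to_csv(paths["days"], index=False, float_format=float_format)
    trial.subjects.to_csv(paths["subjects"], index=False, float_format=float_format)
    trial.truth.to_json(paths["truth"])
    return {k: str(v) for k, v in paths.items()}
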