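"""Linear mixed models on balance coordinates: the trial's primary analysis.

Each balance coordinate of the subject-timepoint compositions is analysed
with its own linear mixed model

    z_it = b0 + b1*gender_i + b2*age_i + b3*group_i + b4*time_t
           + b5*(group_i x time_t) + u0_i + u1_i*time_t + e_it

with subject-specific random intercepts u0 and random time slopes u1
(unstructured 2x2 covariance) and REML estimation. The group x time
interaction is the quantity of interest: does the coordinate change
differently in the intervention arm?

:class:`BalanceLMM` is the model object (build from a subject-timepoint
dataset plus covariates); :meth:`BalanceLMM.fit` returns a
:class:`BalanceLMMResults` carrying per-coordinate estimates, Wald 95%
confidence intervals, p-values, variance components and a ``summary()``
table. Estimation is delegated to :class:`statsmodels MixedLM`; if the
unstructured random-effect covariance fails to converge the model falls
back to independent random effects and flags it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM, MixedLMParams

from .balances import MOVEMENT_COORD_NAMES, BalancePartition, ilr, movement_partition
from .composition import CompositionError
from .preprocess import PART_COLS

__all__ = [
    "CodingConfig",
    "LmmDesign",
    "CoordinateFit",
    "build_design",
    "fit_lmm",
    "summarize_fits",
    "BalanceLMM",
    "BalanceLMMResults",
]

TERMS = ("(Intercept)", "Gender", "Age", "Group", "Time", "Group*Time")


@dataclass(frozen=True)
class CodingConfig:
    """Covariate and time codings for the mixed models.

    time_coding "months" puts time on a months scale via ``time_values``
    (default baseline=0, m6=6); "binary" codes the two timepoints 0/1.
    Group and gender use reference-cell coding (control=0, woman=0 by
    default); age is centered at the sample mean so the intercept refers
    to an average-aged reference subject. ``df_method`` "normal" uses
    Wald normal inference; "t" uses a t reference with n - p residual
    degrees of freedom.
    """

    time_coding: str = "months"
    time_values: tuple[tuple[str, float], ...] = (("baseline", 0.0), ("m6", 6.0))
    group_reference: str = "control"
    gender_reference: str = "woman"
    center_age: bool = True
    df_method: str = "normal"

    def time_map(self) -> dict[str, float]:
        tv = dict(self.time_values)
        if self.time_coding == "months":
            return tv
        if self.time_coding == "binary":
            order = sorted(tv, key=tv.get)
            return {tp: float(i) for i, tp in enumerate(order)}
        raise ValueError(f"unknown time_coding {self.time_coding!r}")


@dataclass
class LmmDesign:
    """Design matrices for one coordinate's mixed model."""

    endog: np.ndarray
    exog: pd.DataFrame  # columns = TERMS
    exog_re: np.ndarray  # intercept + time, per row
    groups: np.ndarray  # subject ids, one per row
    coordinate_index: int
    coordinate_name: str
    coding: CodingConfig
    age_center: float


def build_design(
    data: pd.DataFrame,
    subjects: pd.DataFrame,
    coordinate_index: int,
    partition: BalancePartition | None = None,
    coding: CodingConfig | None = None,
) -> LmmDesign:
    """Assemble one coordinate's response and design matrices.

    ``data`` holds one row per subject-timepoint with the behavior
    columns (strictly positive); ``subjects`` holds group, gender and age.
    ``coordinate_index`` is 1-based (1..D-1).
    """
    partition = partition or movement_partition()
    coding = coding or CodingConfig()
    if not 1 <= coordinate_index <= partition.n_coords:
        raise ValueError(f"coordinate_index must be in 1..{partition.n_coords}")

    tmap = coding.time_map()
    missing_tp = set(data["timepoint"].unique()) - set(tmap)
    if missing_tp:
        raise ValueError(f"timepoints {sorted(missing_tp)} lack a time value in the coding")
    merged = data.merge(subjects, on="subject_id", validate="m:1")
    if merged[["group", "gender", "age"]].isna().any().any():
        bad = merged.loc[merged[["group", "gender", "age"]].isna().any(axis=1), "subject_id"]
        raise ValueError(f"missing covariates for subjects {sorted(set(bad))}")

    z = ilr(merged[list(PART_COLS)].to_numpy(dtype=float), partition)
    endog = z[:, coordinate_index - 1]
    time = merged["timepoint"].map(tmap).to_numpy(dtype=float)
    group = (merged["group"] != coding.group_reference).astype(float).to_numpy()
    gender = (merged["gender"] != coding.gender_reference).astype(float).to_numpy()
    age_center = float(merged["age"].mean()) if coding.center_age else 0.0
    age = merged["age"].to_numpy(dtype=float) - age_center

    exog = pd.DataFrame(
        {
            "(Intercept)": np.ones(len(merged)),
            "Gender": gender,
            "Age": age,
            "Group": group,
            "Time": time,
            "Group*Time": group * time,
        }
    )
    exog_re = np.column_stack([np.ones(len(merged)), time])
    name = (
        MOVEMENT_COORD_NAMES[coordinate_index - 1]
        if partition.n_coords == 3 and coordinate_index <= 3
        else f"Coordinate {coordinate_index}"
    )
    return LmmDesign(
        endog=endog,
        exog=exog,
        exog_re=exog_re,
        groups=merged["subject_id"].to_numpy(),
        coordinate_index=coordinate_index,
        coordinate_name=name,
        coding=coding,
        age_center=age_center,
    )


def build_design_from_panel(
    panel: pd.DataFrame,
    coordinate_index: int = 1,
    coding: CodingConfig | None = None,
    name: str | None = None,
) -> LmmDesign:
    """Design from an already-transformed panel (columns ``subject_id``,
    ``group``, ``gender``, ``age``, ``time``, ``z``) — the simulation
    harness path, bypassing the compositional columns."""
    coding = coding or CodingConfig()
    time = panel["time"].to_numpy(dtype=float)
    group = (panel["group"] != coding.group_reference).astype(float).to_numpy()
    gender = (panel["gender"] != coding.gender_reference).astype(float).to_numpy()
    age_center = float(panel["age"].mean()) if coding.center_age else 0.0
    exog = pd.DataFrame(
        {
            "(Intercept)": np.ones(len(panel)),
            "Gender": gender,
            "Age": panel["age"].to_numpy(dtype=float) - age_center,
            "Group": group,
            "Time": time,
            "Group*Time": group * time,
        }
    )
    return LmmDesign(
        endog=panel["z"].to_numpy(dtype=float),
        exog=exog,
        exog_re=np.column_stack([np.ones(len(panel)), time]),
        groups=panel["subject_id"].to_numpy(),
        coordinate_index=coordinate_index,
        coordinate_name=name or f"Coordinate {coordinate_index}",
        coding=coding,
        age_center=age_center,
    )


@dataclass
class CoordinateFit:
    """Fixed-effect table and variance components for one coordinate."""

    coordinate_name: str
    params: pd.DataFrame  # index TERMS; columns estimate, se, ci_low, ci_high, p
    cov_re: pd.DataFrame  # 2x2 random-effect covariance (intercept, time)
    resid_var: float
    converged: bool
    fallback: bool
    method: str

    @property
    def random_effect_corr(self) -> float:
        c = self.cov_re.to_numpy()
        denom = np.sqrt(c[0, 0] * c[1, 1])
        return float(c[0, 1] / denom) if denom > 0 else 0.0


def _wald_table(estimates, ses, coding: CodingConfig, n_obs: int, level=0.95) -> pd.DataFrame:
    if coding.df_method == "t":
        df = max(n_obs - len(estimates), 1)
        crit = stats.t.ppf(0.5 + level / 2, df)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = 2 * stats.t.sf(np.abs(estimates / ses), df)
    else:
        crit = stats.norm.ppf(0.5 + level / 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = 2 * stats.norm.sf(np.abs(estimates / ses))
    return pd.DataFrame(
        {
            "estimate": estimates,
            "se": ses,
            "ci_low": estimates - crit * ses,
            "ci_high": estimates + crit * ses,
            "p": p,
        },
        index=list(TERMS),
    )


def _moment_start(design: LmmDesign):
    """Method-of-moments start values: OLS fixed effects plus variance
    components solved from the per-subject residual covariance over the
    two time values. Cuts optimizer iterations considerably; returns None
    when the design is not a complete two-timepoint panel."""
    times = np.unique(design.exog_re[:, 1])
    if len(times) != 2:
        return None
    t0, t1 = times
    X = design.exog.to_numpy()
    y = design.endog
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    wide = (
        pd.DataFrame({"g": design.groups, "t": design.exog_re[:, 1], "r": y - X @ beta})
        .pivot_table(index="g", columns="t", values="r")
        .dropna()
    )
    if len(wide) < 3:
        return None
    v0, v1 = wide[t0].var(), wide[t1].var()
    c = wide[t0].cov(wide[t1])
    s00 = max(c, 1e-4)  # cov across times ~ intercept variance
    scale = max(v0 - s00, 1e-4)  # residual variance
    s11 = max((v1 - s00 - scale) / (t1 - t0) ** 2, 1e-6)  # slope variance
    cov_re = np.array([[s00, 0.0], [0.0, s11]]) / scale
    return MixedLMParams.from_components(fe_params=beta, cov_re=cov_re)


def fit_lmm(design: LmmDesign, reml: bool = True, structure: str = "auto") -> CoordinateFit:
    """REML fit of one coordinate's mixed model.

    ``structure="auto"`` tries the unstructured random-effect covariance
    and falls back to independent (diagonal-covariance) random effects
    when that fit does not converge; ``"diagonal"`` forces the fallback
    structure. A singular fit after the fallback raises with diagnostics.
    """
    if structure not in ("auto", "diagonal"):
        raise ValueError(f"structure must be 'auto' or 'diagonal', got {structure!r}")
    n_subjects = len(np.unique(design.groups))
    if n_subjects < 10:
        raise ValueError(f"need at least 10 subjects, have {n_subjects}")

    y = design.endog
    if np.ptp(y) == 0.0:
        # degenerate: constant response -> intercept only, no variance
        est = np.zeros(len(TERMS))
        est[0] = float(y[0])
        tab = _wald_table(est, np.zeros(len(TERMS)), design.coding, len(y))
        tab.loc[:, "p"] = np.nan
        cov = pd.DataFrame(np.zeros((2, 2)), index=["(Intercept)", "Time"], columns=["(Intercept)", "Time"])
        return CoordinateFit(design.coordinate_name, tab, cov, 0.0, True, False, "degenerate")

    start = _moment_start(design)

    def _run(free):
        model = MixedLM(
            y,
            design.exog.to_numpy(),
            groups=design.groups,
            exog_re=design.exog_re,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return model.fit(
                reml=reml, method="lbfgs", maxiter=500, free=free, start_params=start
            )

    fallback = False
    res = None
    if structure == "auto":
        try:
            res = _run(None)
        except np.linalg.LinAlgError:
            # singular information matrix: the unstructured covariance is
            # not identified (e.g. two-timepoint panels); use independent
            # random effects instead
            res = None
    if res is None or not res.converged:
        free = MixedLMParams.from_components(
            fe_params=np.ones(design.exog.shape[1]), cov_re=np.eye(2)
        )
        res = _run(free)
        fallback = structure == "auto"
        if not res.converged:
            raise RuntimeError(
                f"mixed model for {design.coordinate_name!r} failed to converge even with "
                f"independent random effects (n={len(y)}, subjects={n_subjects})"
            )

    est = np.asarray(res.fe_params, dtype=float)
    se = np.asarray(res.bse_fe, dtype=float)
    tab = _wald_table(est, se, design.coding, len(y))
    cov_re = pd.DataFrame(
        np.asarray(res.cov_re, dtype=float),
        index=["(Intercept)", "Time"],
        columns=["(Intercept)", "Time"],
    )
    return CoordinateFit(
        design.coordinate_name,
        tab,
        cov_re,
        float(res.scale),
        bool(res.converged),
        fallback,
        "REML" if reml else "ML",
    )


def summarize_fits(fits, round_to: int | None = 2) -> pd.DataFrame:
    """Long-format fixed-effect table: coordinate block x term x (beta, CI, p)."""
    rows = []
    for fit in fits:
        for term, rec in fit.params.iterrows():
            rows.append(
                {
                    "coordinate": fit.coordinate_name,
                    "term": term,
                    "beta": rec["estimate"],
                    "ci_low": rec["ci_low"],
                    "ci_high": rec["ci_high"],
                    "p": rec["p"],
                }
            )
    out = pd.DataFrame(rows)
    if round_to is not None:
        out[["beta", "ci_low", "ci_high", "p"]] = out[["beta", "ci_low", "ci_high", "p"]].round(
            round_to
        )
    return out


class BalanceLMM:
    """Mixed-model analysis of all balance coordinates of a trial dataset.

    Parameters
    ----------
    data : DataFrame, one row per subject-timepoint with ``subject_id``,
        ``timepoint`` and the behavior minute columns (strictly positive —
        run imputation first).
    subjects : DataFrame with ``subject_id``, ``group``, ``gender``, ``age``.
    partition : balance partition; the movement-behavior SBP by default.
    coding : covariate/time coding configuration.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        subjects: pd.DataFrame,
        partition: BalancePartition | None = None,
        coding: CodingConfig | None = None,
    ):
        self.partition = partition or movement_partition()
        self.coding = coding or CodingConfig()
        self.data = data
        self.subjects = subjects
        self.designs = [
            build_design(data, subjects, k, self.partition, self.coding)
            for k in range(1, self.partition.n_coords + 1)
        ]

    @classmethod
    def from_dataframe(cls, data, subjects, **kwargs) -> "BalanceLMM":
        return cls(data, subjects, **kwargs)

    def fit(self, reml: bool = True) -> "BalanceLMMResults":
        return BalanceLMMResults(self, [fit_lmm(d, reml=reml) for d in self.designs])


class BalanceLMMResults:
    """Per-coordinate fits with a publication-style summary table."""

    def __init__(self, model: BalanceLMM, fits: list[CoordinateFit]):
        self.model = model
        self.fits = fits

    @property
    def table(self) -> pd.DataFrame:
        """Full-precision long table (coordinate, term, beta, ci_low, ci_high, p)."""
        return summarize_fits(self.fits, round_to=None)

    def interaction(self, coordinate_index: int) -> pd.Series:
        """The group x time row for one coordinate (1-based)."""
        return self.fits[coordinate_index - 1].params.loc["Group*Time"]

    def summary(self, round_to: int = 2) -> str:
        lines = []
        for fit in self.fits:
            lines.append(fit.coordinate_name)
            lines.append(f"  estimation: {fit.method}"
                         + (", independent random effects (fallback)" if fit.fallback else ""))
            tab = fit.params.round(round_to)
            for term, rec in tab.iterrows():
                lines.append(
                    f"  {term:<12} beta={rec['estimate']:>6.2f}  "
                    f"95% CI [{rec['ci_low']:>6.2f}, {rec['ci_high']:>6.2f}]  p={rec['p']:.2f}"
                )
            c = fit.cov_re.to_numpy()
            lines.append(
                f"  random effects: var(intercept)={c[0, 0]:.4f}, var(time)={c[1, 1]:.5f}, "
                f"corr={fit.random_effect_corr:.2f}; residual var={fit.resid_var:.4f}"
            )
            lines.append("")
        return "\n".join(lines)

    def to_csv(self, path, round_to: int | None = 2) -> None:
        summarize_fits(self.fits, round_to=round_to).to_csv(path, index=False)

    def variance_components(self) -> dict:
        return {
            fit.coordinate_name: {
                "cov_re": fit.cov_re.to_numpy().tolist(),
                "resid_var": fit.resid_var,
                "converged": fit.converged,
                "fallback": fit.fallback,
                "method": fit.method,
            }
            for fit in self.fits
        }
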