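"""Penalized random-slope Gaussian mixed model for wound-closure rates.

The healing distance d of individual i in group g at time t is modelled as

    d_it = b0_g(i) + b1_g(i) * s(t) + u0_i + u1_i * s(t) + e_it,
    (u0_i, u1_i) ~ N(0, G),   e_it ~ N(0, sigma^2),

with s(t) the standardized time (sample SD pooled over all records, the R
``scale()`` convention).  The random-effects structure is maximal: every
individual carries its own intercept and slope deviation.  Duplicate
measurements enter as independent residual draws given the individual's
random effects.

Estimation is restricted maximum likelihood with the fixed effects and the
residual variance profiled out, leaving the three log-Cholesky parameters
of the relative covariance Psi = G / sigma^2.  A weakly informative
log-det penalty on Psi (Wishart-style, strength configurable) keeps the
optimizer away from singular covariance fits, in the spirit of the
blme-style covariance prior; with the penalty active the returned G is
positive definite, at a small floor when the data carry no individual
heterogeneity.

Group-specific slopes back-transformed to mm/day are the healing rates;
equality of slopes between groups is tested with a Wald chi-square on the
fixed-effect covariance.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "TimeScaling",
    "ModelSpec",
    "ConvergenceError",
    "scale_time",
    "HealingRateModel",
    "HealingRateResults",
    "fit_lmm",
    "extract_rates",
    "slope_contrast_test",
    "assign_age_classes",
]

_PSI_DIAG_FLOOR = 1e-8  # floor on the relative-covariance diagonal
_SIGMA2_FLOOR = 1e-12


class ConvergenceError(RuntimeError):
    """REML optimization failed after all restarts; carries diagnostics."""

    def __init__(self, message: str, diagnostics: list | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


@dataclass(frozen=True)
class TimeScaling:
    """Back-transformation constants for standardized time."""

    mean: float
    sd: float

    def transform(self, t):
        return (np.asarray(t, dtype=float) - self.mean) / self.sd

    def inverse(self, s):
        return np.asarray(s, dtype=float) * self.sd + self.mean

    @classmethod
    def identity(cls) -> "TimeScaling":
        return cls(mean=0.0, sd=1.0)


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one mixed-model fit.

    The random structure is always the maximal per-individual
    intercept + slope; only the fixed-effect grouping, the time scaling
    and the covariance penalty vary.
    """

    group_factor: str = "species"
    include_group_intercepts: bool = True
    time_scaling: str = "standardize"  # or "none"
    covariance_penalty_strength: float = 0.01

    def __post_init__(self) -> None:
        if self.time_scaling not in ("standardize", "none"):
            raise ValueError("time_scaling must be 'standardize' or 'none'")
        if self.covariance_penalty_strength < 0:
            raise ValueError("penalty strength must be >= 0")


def scale_time(records: pd.DataFrame, column: str = "time_days"):
    """Standardize the time column over all records.

    Returns ``(records_with_time_scaled, TimeScaling)``.  The SD is the
    sample SD (ddof=1) of the pooled time column, matching R's ``scale``.
    """
    t = records[column].to_numpy(dtype=float)
    if np.ptp(t) == 0:
        raise ValueError("all record times are equal; time cannot be scaled")
    scaling = TimeScaling(mean=float(np.mean(t)), sd=float(np.std(t, ddof=1)))
    out = records.copy()
    out["time_scaled"] = scaling.transform(t)
    return out, scaling


def _cholesky_from_theta(theta: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor of Psi from the log-Cholesky parameters."""
    return np.array([[np.exp(theta[0]), 0.0], [theta[1], np.exp(theta[2])]])


class HealingRateModel:
    """Random-slope model of healing distance on (scaled) time.

    Parameters
    ----------
    records : DataFrame
        Healing records with columns individual_id, time_days,
        healing_distance_mm, plus the grouping column.
    group : str
        Column defining the fixed-effect groups (species, setting, sex,
        age_class, site, ...).
    group_intercepts : bool
        Give each group its own intercept (default); with False a single
        common intercept is shared and only slopes vary by group.
    time_scaling : {"standardize", "none"}
    penalty_strength : float
        Strength of the log-det covariance penalty; 0 disables it.

    Examples
    --------
    >>> model = HealingRateModel(records, group="species")
    >>> res = model.fit()
    >>> res.rates  # per-species mm/day with SEs
    """

    def __init__(
        self,
        records: pd.DataFrame,
        group: str = "species",
        group_intercepts: bool = True,
        time_scaling: str = "standardize",
        penalty_strength: float = 0.01,
        response: str = "healing_distance_mm",
    ):
        if group not in records.columns:
            raise ValueError(f"grouping column {group!r} not in records")
        for col in ("individual_id", "time_days", response):
            if col not in records.columns:
                raise ValueError(f"records missing column {col!r}")
        self.spec = ModelSpec(
            group_factor=group,
            include_group_intercepts=group_intercepts,
            time_scaling=time_scaling,
            covariance_penalty_strength=penalty_strength,
        )
        self.records = records.reset_index(drop=True)
        self.response = response
        self._check_design()
        if time_scaling == "standardize":
            self.records, self.scaling = scale_time(self.records)
        else:
            self.records = self.records.copy()
            self.records["time_scaled"] = self.records["time_days"].astype(float)
            self.scaling = TimeScaling.identity()
        self.groups = sorted(self.records[group].astype(str).unique())
        self._build_design()

    @classmethod
    def from_observations(
        cls,
        obs: pd.DataFrame,
        relation=None,
        replicates: str = "keep",
        group: str = "species",
        **kwargs,
    ) -> "HealingRateModel":
        """Build the model straight from a raw observations table."""
        from .kinetics import observations_to_healing_records

        records = observations_to_healing_records(obs, rel=relation, replicates=replicates)
        return cls(records, group=group, **kwargs)

    # -- design ------------------------------------------------------------
    def _check_design(self) -> None:
        g = self.spec.group_factor
        per_group = self.records.groupby(g)["individual_id"].nunique()
        lonely = per_group[per_group < 2]
        if len(lonely):
            raise ValueError(
                "groups with a single individual cannot support a random slope: "
                + ", ".join(str(k) for k in lonely.index)
            )
        times_per_ind = self.records.groupby("individual_id")["time_days"].nunique()
        short = times_per_ind[times_per_ind < 2]
        if len(short):
            raise ValueError(
                "individuals with < 2 time points: "
                + ", ".join(str(k) for k in short.index[:10])
            )

    def _build_design(self) -> None:
        rec = self.records
        g = rec[self.spec.group_factor].astype(str).to_numpy()
        s = rec["time_scaled"].to_numpy(dtype=float)
        y = rec[self.response].to_numpy(dtype=float)
        k = len(self.groups)
        if self.spec.include_group_intercepts:
            p = 2 * k
            X = np.zeros((len(rec), p))
            names = []
            for j, grp in enumerate(self.groups):
                mask = g == grp
                X[mask, 2 * j] = 1.0
                X[mask, 2 * j + 1] = s[mask]
                names += [f"intercept[{grp}]", f"slope[{grp}]"]
            self._slope_idx = {grp: 2 * j + 1 for j, grp in enumerate(self.groups)}
        else:
            p = 1 + k
            X = np.zeros((len(rec), p))
            X[:, 0] = 1.0
            names = ["intercept"]
            for j, grp in enumerate(self.groups):
                mask = g == grp
                X[mask, 1 + j] = s[mask]
                names.append(f"slope[{grp}]")
            self._slope_idx = {grp: 1 + j for j, grp in enumerate(self.groups)}
        self.exog_names = names
        self.n_params = p
        # per-individual sufficient statistics, stacked so the REML
        # objective is pure batched 2x2 algebra; Z_i = [1, s]
        A_list, B_list, c_list = [], [], []
        XtX = np.zeros((p, p))
        Xty = np.zeros(p)
        yty = 0.0
        for ind, grp in rec.groupby("individual_id", sort=False):
            idx = grp.index.to_numpy()
            Zi = np.column_stack([np.ones(len(idx)), s[idx]])
            Xi = X[idx]
            yi = y[idx]
            A_list.append(Zi.T @ Zi)
            B_list.append(Zi.T @ Xi)
            c_list.append(Zi.T @ yi)
            XtX += Xi.T @ Xi
            Xty += Xi.T @ yi
            yty += float(yi @ yi)
        self._A = np.stack(A_list)       # (m, 2, 2)
        self._B = np.stack(B_list)       # (m, 2, p)
        self._c = np.stack(c_list)       # (m, 2)
        self._XtX, self._Xty, self._yty = XtX, Xty, yty
        self.n_individuals = len(A_list)
        self.nobs = len(rec)

    # -- REML objective ----------------------------------------------------
    def _profiled_reml(self, theta: np.ndarray):
        """Profiled REML pieces at the log-Cholesky parameters theta.

        Returns (loglik, beta, XtWX, sigma2, Psi); W = (I + Z Psi Z')^-1
        blockwise via the Woodbury identity on the 2x2 inner matrix.
        """
        L = _cholesky_from_theta(theta)
        # K_i = I + L' A_i L, inverted in closed form (2x2, PD by construction)
        K = np.eye(2) + np.einsum("ab,nbc,cd->nad", L.T, self._A, L)
        det = K[:, 0, 0] * K[:, 1, 1] - K[:, 0, 1] * K[:, 1, 0]
        if np.any(det <= 0):
            raise np.linalg.LinAlgError("non-PD inner matrix in REML objective")
        Kinv = np.empty_like(K)
        Kinv[:, 0, 0] = K[:, 1, 1]
        Kinv[:, 1, 1] = K[:, 0, 0]
        Kinv[:, 0, 1] = -K[:, 0, 1]
        Kinv[:, 1, 0] = -K[:, 1, 0]
        Kinv /= det[:, None, None]
        logdet = float(np.sum(np.log(det)))
        LB = np.einsum("ab,nbp->nap", L.T, self._B)   # (m, 2, p)
        Lc = np.einsum("ab,nb->na", L.T, self._c)     # (m, 2)
        MLB = np.einsum("nab,nbp->nap", Kinv, LB)
        MLc = np.einsum("nab,nb->na", Kinv, Lc)
        XtWX = self._XtX - np.einsum("nap,naq->pq", LB, MLB)
        XtWy = self._Xty - np.einsum("nap,na->p", LB, MLc)
        ytWy = self._yty - float(np.einsum("na,na->", Lc, MLc))
        beta = np.linalg.solve(XtWX, XtWy)
        rss = max(ytWy - float(beta @ XtWy), 0.0)
        dof = self.nobs - self.n_params
        sigma2 = max(rss / dof, _SIGMA2_FLOOR)
        sign, ld_x = np.linalg.slogdet(XtWX)
        loglik = -0.5 * (logdet + dof * (1.0 + np.log(2.0 * np.pi * sigma2)) + ld_x)
        return loglik, beta, XtWX, sigma2, L @ L.T

    def _penalty(self, theta: np.ndarray) -> float:
        lam = self.spec.covariance_penalty_strength
        if lam == 0:
            return 0.0
        logdet_psi = 2.0 * (theta[0] + theta[2])
        tr_psi = np.exp(2.0 * theta[0]) + theta[1] ** 2 + np.exp(2.0 * theta[2])
        return lam * (logdet_psi - tr_psi)

    def _objective(self, theta: np.ndarray) -> float:
        try:
            loglik, *_ = self._profiled_reml(theta)
        except np.linalg.LinAlgError:
            return 1e12
        return -(loglik + self._penalty(theta))

    def fit(self, restarts: int = 3, maxiter: int = 200) -> "HealingRateResults":
        """Maximize the penalized profiled REML objective.

        Up to ``restarts`` deterministic starting points are tried
        (L-BFGS-B, log-Cholesky bounds keeping the relative covariance
        diagonal above 1e-8); the best converged solution wins.  If no
        start converges a :class:`ConvergenceError` carries the optimizer
        diagnostics.
        """
        lo = 0.5 * np.log(_PSI_DIAG_FLOOR)
        bounds = [(lo, 8.0), (-50.0, 50.0), (lo, 8.0)]
        starts = [
            np.array([np.log(0.3), 0.0, np.log(0.3)]),
            np.array([np.log(1.0), 0.0, np.log(1.0)]),
            np.array([np.log(0.02), 0.0, np.log(0.02)]),
        ][: max(restarts, 1)]
        best = None
        diagnostics = []
        for x0 in starts:
            res = optimize.minimize(
                self._objective, x0, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": maxiter},
            )
            diagnostics.append(
                {"x0": x0.tolist(), "success": bool(res.success),
                 "message": str(res.message), "fun": float(res.fun)}
            )
            if res.success and (best is None or res.fun < best.fun):
                best = res
        if best is None:
            # fall back on the lowest objective even without formal success
            funs = [d["fun"] for d in diagnostics]
            raise ConvergenceError(
                f"REML optimization did not converge in {len(starts)} starts "
                f"(best objective {min(funs):.4g})",
                diagnostics,
            )
        theta = best.x
        loglik, beta, XtWX, sigma2, Psi = self._profiled_reml(theta)
        penalized = loglik + self._penalty(theta)
        G = sigma2 * Psi
        cov_beta = sigma2 * np.linalg.inv(XtWX)
        eig = np.linalg.eigvalsh(G)
        singular = bool(eig[0] < 1e-6 * max(np.trace(G), _SIGMA2_FLOOR))
        return HealingRateResults(
            model=self,
            fe_params=pd.Series(beta, index=self.exog_names),
            cov_fe=pd.DataFrame(cov_beta, index=self.exog_names, columns=self.exog_names),
            random_cov=G,
            sigma2=float(sigma2),
            loglik=float(penalized),
            reml_loglik=float(loglik),
            theta=theta.copy(),
            converged=True,
            singular=singular,
            optimizer_diagnostics=diagnostics,
        )


@dataclass
class HealingRateResults:
    """Fitted penalized random-slope model.

    Attributes
    ----------
    fe_params : Series
        Fixed effects on the scaled-time axis, indexed by term name.
    cov_fe : DataFrame
        Their REML covariance (conditional on the covariance parameters).
    random_cov : ndarray
        2x2 covariance G of per-individual (intercept, slope) deviations,
        slope entries per unit of *scaled* time.
    sigma2 : float
        Residual variance, mm^2.
    loglik : float
        Penalized profiled REML objective at the optimum.
    """

    model: HealingRateModel
    fe_params: pd.Series
    cov_fe: pd.DataFrame
    random_cov: np.ndarray
    sigma2: float
    loglik: float
    reml_loglik: float
    theta: np.ndarray
    converged: bool
    singular: bool
    optimizer_diagnostics: list = field(default_factory=list)

    # -- rates -------------------------------------------------------------
    @property
    def rates(self) -> pd.DataFrame:
        """Per-group healing rates in mm/day with standard errors."""
        sd = self.model.scaling.sd
        rows = []
        for grp in self.model.groups:
            j = self.model._slope_idx[grp]
            rows.append(
                {
                    "group": grp,
                    "rate_mm_per_day": self.fe_params.iloc[j] / sd,
                    "se": np.sqrt(self.cov_fe.iloc[j, j]) / sd,
                }
            )
        return pd.DataFrame(rows)

    def contrast(self, groups=None):
        """Wald chi-square test of equal slopes among ``groups``.

        Returns ``(statistic, df, p)``; df = (#groups - 1).
        """
        groups = list(groups) if groups is not None else list(self.model.groups)
        unknown = [g for g in groups if g not in self.model._slope_idx]
        if unknown:
            raise ValueError(f"unknown groups: {unknown}")
        if len(groups) < 2:
            raise ValueError("need >= 2 groups for a slope contrast")
        p = self.model.n_params
        C = np.zeros((len(groups) - 1, p))
        base = self.model._slope_idx[groups[0]]
        for r, grp in enumerate(groups[1:]):
            C[r, self.model._slope_idx[grp]] = 1.0
            C[r, base] = -1.0
        q = C @ self.fe_params.to_numpy()
        V = C @ self.cov_fe.to_numpy() @ C.T
        if np.linalg.cond(V) > 1e12:
            raise np.linalg.LinAlgError("singular fixed-effect covariance in contrast")
        stat = float(q @ np.linalg.solve(V, q))
        df = C.shape[0]
        pval = float(stats.chi2.sf(stat, df))
        return stat, df, pval

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        """Plain-text summary table of rates, covariance and diagnostics."""
        lines = [
            "Penalized random-slope model of wound healing distance",
            "=" * 58,
            f"groups ({self.model.spec.group_factor}): {len(self.model.groups)}   "
            f"individuals: {self.model.n_individuals}   records: {self.model.nobs}",
            f"time scaling: mean={self.model.scaling.mean:.4g} d, "
            f"sd={self.model.scaling.sd:.4g} d",
            "",
            f"{'group':<14}{'rate (mm/d)':>12}{'SE':>10}",
        ]
        for _, row in self.rates.iterrows():
            lines.append(
                f"{row['group']:<14}{row['rate_mm_per_day']:>12.4f}{row['se']:>10.4f}"
            )
        G = self.random_cov
        lines += [
            "",
            "random-effect covariance G (intercept, slope on scaled time):",
            f"  [[{G[0, 0]:.5g}, {G[0, 1]:.5g}], [{G[1, 0]:.5g}, {G[1, 1]:.5g}]]",
            f"residual variance sigma^2 = {self.sigma2:.5g} mm^2",
            f"penalized REML objective = {self.loglik:.4f}",
            f"converged: {self.converged}   singular: {self.singular}",
        ]
        if len(self.model.groups) >= 2:
            stat, df, pval = self.contrast()
            lines.append(
                f"slope equality (all groups): X2 = {stat:.3f}, df = {df}, p = {pval:.3g}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        out = {
            "group_factor": self.model.spec.group_factor,
            "rates": {
                row["group"]: {
                    "rate_mm_per_day": float(row["rate_mm_per_day"]),
                    "se": float(row["se"]),
                }
                for _, row in self.rates.iterrows()
            },
            "fixed_effects": {k: float(v) for k, v in self.fe_params.items()},
            "random_cov": self.random_cov.tolist(),
            "sigma2": self.sigma2,
            "loglik": self.loglik,
            "time_scaling": {"mean": self.model.scaling.mean, "sd": self.model.scaling.sd},
            "convergence": {
                "converged": self.converged,
                "singular": self.singular,
                "n_individuals": self.model.n_individuals,
                "n_records": self.model.nobs,
            },
        }
        if len(self.model.groups) >= 2:
            stat, df, pval = self.contrast()
            out["contrast_all_groups"] = {
                "groups": list(self.model.groups), "chisq": stat, "df": df, "p": pval,
            }
        return out

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def rates_to_csv(self, path: str | Path) -> None:
        self.rates.to_csv(path, index=False)

    def plot(self, ax=None):
        """Diagnostic plot: healing distance vs time with fitted group lines."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 5))
        rec = self.model.records
        gcol = self.model.spec.group_factor
        cmap = plt.get_cmap("tab10")
        for j, grp in enumerate(self.model.groups):
            sub = rec[rec[gcol].astype(str) == grp]
            ax.scatter(sub["time_days"], sub[self.model.response], s=12,
                       color=cmap(j % 10), alpha=0.5, label=grp)
            t = np.linspace(sub["time_days"].min(), sub["time_days"].max(), 20)
            s = self.model.scaling.transform(t)
            if self.model.spec.include_group_intercepts:
                i0 = self.model._slope_idx[grp] - 1
                b0 = self.fe_params.iloc[i0]
            else:
                b0 = self.fe_params.iloc[0]
            b1 = self.fe_params.iloc[self.model._slope_idx[grp]]
            ax.plot(t, b0 + b1 * s, color=cmap(j % 10))
        ax.set_xlabel("time (days)")
        ax.set_ylabel("healing distance (mm)")
        ax.legend(fontsize=8)
        return ax


# ---------------------------------------------------------------------------
# functional surface

def fit_lmm(records: pd.DataFrame, spec: ModelSpec | None = None) -> HealingRateResults:
    """Fit the penalized random-slope model described by ``spec``."""
    spec = spec or ModelSpec()
    model = HealingRateModel(
        records,
        group=spec.group_factor,
        group_intercepts=spec.include_group_intercepts,
        time_scaling=spec.time_scaling,
        penalty_strength=spec.covariance_penalty_strength,
    )
    return model.fit()


def extract_rates(fit: HealingRateResults, scaling: TimeScaling | None = None) -> pd.DataFrame:
    """Per-group rates in mm/day (slopes back-transformed from scaled time)."""
    if scaling is not None and scaling != fit.model.scaling:
        warnings.warn("ignoring external scaling; the fit stores its own", stacklevel=2)
    return fit.rates


def slope_contrast_test(fit: HealingRateResults, groups=None):
    """Wald chi-square for slope equality; see HealingRateResults.contrast."""
    return fit.contrast(groups)


_SCHEME_LABELS = {
    "median": ["low", "high"],
    "tertile": ["t1", "t2", "t3"],
    "quartile": ["q1", "q2", "q3", "q4"],
}


def assign_age_classes(ages, scheme: str = "median") -> list[str]:
    """Quantile-bin ages into classes; boundary ties go to the lower class."""
    if scheme not in _SCHEME_LABELS:
        raise ValueError(f"scheme must be one of {sorted(_SCHEME_LABELS)}")
    labels = _SCHEME_LABELS[scheme]
    k = len(labels)
    ages = np.asarray(ages, dtype=float)
    if len(np.unique(ages)) < k:
        raise ValueError(f"need >= {k} distinct ages for {scheme} classes")
    edges = np.quantile(ages, [i / k for i in range(1, k)])
    idx = (ages[:, None] > edges[None, :]).sum(axis=1)
    return [labels[i] for i in idx]
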