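"""Association stage: domain scores, mass-univariate and component models,
BH-FDR, bootstrap percentile CIs, VIF, age-tertile gamma GLM, demographics."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import linalg as sla
from scipy import stats as sps

from .parcellation import PARCEL_CODES

__all__ = [
    "COVARIATES",
    "bh_fdr",
    "standardize_scores",
    "fit_parcel_models",
    "fit_component_models",
    "bootstrap_ci",
    "vif",
    "age_tertiles",
    "gamma_glm_compare",
    "demographic_associations",
]

#: Model covariates in fixed order (sex/hypertension enter as 0/1 indicators).
COVARIATES = ("age", "sex", "education", "bpf", "hypertension")


def bh_fdr(p, level: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up: q-values and rejection flags at ``level``.

    ``q_i = min_{j >= i} m * p_(j) / j`` over the ascending order, capped at 1.
    """
    p = np.asarray(p, float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p must be a non-empty 1-D vector")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q, q <= level


def standardize_scores(
    task_scores: pd.DataFrame,
    domain_map: dict[str, str],
    reverse: set[str] | frozenset[str] = frozenset(),
) -> pd.DataFrame:
    """Composite domain scores from per-task measurements.

    Each task is z-scored (complete cases), tasks of reversed domains are
    negated, the tasks of a domain are averaged, and the composite is
    re-standardized to mean 0 / SD 1.  A subject missing any task of a domain
    has a missing domain score.
    """
    domains = sorted(set(domain_map.values()))
    for d in domains:
        tasks = [t for t, dd in domain_map.items() if dd == d]
        if len(tasks) != 3:
            raise ValueError(f"domain {d!r} must have exactly 3 tasks, has {len(tasks)}")
    z = pd.DataFrame(index=task_scores.index)
    for task, domain in domain_map.items():
        col = task_scores[task].astype(float)
        sd = col.std(ddof=1)
        if not sd > 0:
            raise ValueError(f"task {task!r} has zero variance")
        zs = (col - col.mean()) / sd
        z[task] = -zs if domain in reverse else zs
    out = pd.DataFrame(index=task_scores.index)
    for d in domains:
        tasks = [t for t, dd in domain_map.items() if dd == d]
        comp = z[tasks].mean(axis=1, skipna=False)
        comp = (comp - comp.mean()) / comp.std(ddof=1)
        out[d] = comp
    return out


def _design(df: pd.DataFrame, predictors: list[str]) -> np.ndarray:
    X = df[predictors].to_numpy(float)
    return sm.add_constant(X, has_constant="add")


def _encode(covariates: pd.DataFrame) -> pd.DataFrame:
    """Map covariates to numeric: sex 'female'→1/'male'→0 if non-numeric."""
    cov = covariates.copy()
    if "sex" in cov and not pd.api.types.is_numeric_dtype(cov["sex"]):
        cov["sex"] = (cov["sex"].astype(str).str.lower() == "female").astype(int)
    return cov


def _fit_ols(y: np.ndarray, X: np.ndarray):
    if X.shape[0] <= X.shape[1]:
        raise ValueError(f"n={X.shape[0]} <= parameters={X.shape[1]}")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient (aliased predictors)")
    return sm.OLS(y, X).fit()


def fit_parcel_models(
    parcels_log: pd.DataFrame,
    scores: pd.DataFrame,
    covariates: pd.DataFrame,
    fdr_level: float = 0.05,
) -> pd.DataFrame:
    """One OLS per (domain, parcel): domain score ~ log parcel volume + covariates.

    Complete-case per model; q-values via BH within each domain's 36 tests.
    Returns a tidy frame of per-parcel association records.
    """
    cov = _encode(covariates)
    parcel_cols = [f"p{c}" for c in PARCEL_CODES]
    missing = [c for c in parcel_cols if c not in parcels_log.columns]
    if missing:
        raise ValueError(f"missing parcel columns: {missing}")
    records = []
    for domain in scores.columns:
        dom_records = []
        for col in parcel_cols:
            df = pd.concat(
                [scores[domain], parcels_log[col], cov[list(COVARIATES)]], axis=1
            ).dropna()
            y = df[domain].to_numpy(float)
            X = _design(df, [col, *COVARIATES])
            res = _fit_ols(y, X)
            dom_records.append({
                "outcome": domain,
                "predictor": col,
                "beta": res.params[1],
                "se": res.bse[1],
                "t": res.tvalues[1],
                "p": res.pvalues[1],
                "n": int(res.nobs),
            })
        q, rej = bh_fdr(np.array([r["p"] for r in dom_records]), level=fdr_level)
        for r, qi, ri in zip(dom_records, q, rej):
            r["q"] = qi
            r["significant_fdr"] = bool(ri)
        records.extend(dom_records)
    return pd.DataFrame(records)


def vif(design: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Variance inflation factors, 1/(1-R^2_j), one per predictor column.

    The design excludes the intercept (it is added internally to each
    auxiliary regression).  Exactly collinear predictors get ``inf``.
    """
    X = np.asarray(design, float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("design must be n x p with p >= 2")
    n, p = X.shape
    out = np.empty(p)
    for j in range(p):
        y = X[:, j]
        others = sm.add_constant(np.delete(X, j, axis=1), has_constant="add")
        beta, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        ss_tot = np.sum((y - y.mean()) ** 2)
        if ss_tot == 0:
            raise ValueError(f"predictor column {j} has zero variance")
        r2 = 1.0 - np.sum(resid**2) / ss_tot
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    if np.isinf(out).any():
        warnings.warn("exact collinearity: infinite VIF reported", stacklevel=2)
    return out


@dataclass
class BootstrapResult:
    lower: np.ndarray
    upper: np.ndarray
    n_redrawn: int
    B: int


def bootstrap_ci(
    X: np.ndarray,
    y: np.ndarray,
    B: int = 1000,
    seed: int | None = None,
    lower_pct: float = 2.5,
    upper_pct: float = 97.5,
) -> BootstrapResult:
    """Case-resampling bootstrap percentile CI for OLS coefficients.

    ``X`` must already include its intercept column.  Rank-deficient
    resamples are redrawn (counted); more than 10% redraws aborts.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    if B < 2:
        raise ValueError("B must be >= 2")
    rng = np.random.default_rng(seed)
    betas = np.empty((B, p))
    n_redrawn = 0
    max_redraws = max(1, int(0.1 * B))
    b = 0
    while b < B:
        idx = rng.integers(0, n, size=n)
        Xb = X[idx]
        xtx = Xb.T @ Xb
        try:
            # Cholesky doubles as the rank-deficiency check for X'X
            c, low = sla.cho_factor(xtx)
        except (np.linalg.LinAlgError, sla.LinAlgError):
            n_redrawn += 1
            if n_redrawn > max_redraws:
                raise RuntimeError(
                    f"bootstrap: {n_redrawn} rank-deficient resamples (> 10% of B={B})"
                )
            continue
        betas[b] = sla.cho_solve((c, low), Xb.T @ y[idx])
        b += 1
    lower = np.percentile(betas, lower_pct, axis=0)
    upper = np.percentile(betas, upper_pct, axis=0)
    return BootstrapResult(lower=lower, upper=upper, n_redrawn=n_redrawn, B=B)


def fit_component_models(
    scores: pd.DataFrame,
    component_scores: pd.DataFrame,
    covariates: pd.DataFrame,
    B: int = 1000,
    seed: int | None = None,
    vif_warn_threshold: float = 10.0,
) -> pd.DataFrame:
    """Per cognitive domain, one OLS with all components + covariates.

    Records beta/SE/t/p, VIF per predictor, and case-resampling bootstrap
    percentile CIs.  VIF above the threshold warns (does not abort).
    """
    cov = _encode(covariates)
    comp_cols = list(component_scores.columns)
    predictors = comp_cols + list(COVARIATES)
    records = []
    for i, domain in enumerate(scores.columns):
        df = pd.concat(
            [
                scores[domain].reset_index(drop=True),
                component_scores.reset_index(drop=True),
                cov[list(COVARIATES)].reset_index(drop=True),
            ],
            axis=1,
        ).dropna()
        y = df[domain].to_numpy(float)
        X = _design(df, predictors)
        res = _fit_ols(y, X)
        vifs = vif(df[predictors].to_numpy(float))
        if (vifs > vif_warn_threshold).any():
            warnings.warn(
                f"{domain}: VIF above {vif_warn_threshold} "
                f"(max {np.nanmax(vifs[np.isfinite(vifs)]):.1f})",
                stacklevel=2,
            )
        boot_seed = None if seed is None else seed + i
        boot = bootstrap_ci(X, y, B=B, seed=boot_seed)
        ci = res.conf_int()
        for j, name in enumerate(predictors, start=1):
            records.append({
                "outcome": domain,
                "predictor": name,
                "beta": res.params[j],
                "se": res.bse[j],
                "t": res.tvalues[j],
                "p": res.pvalues[j],
                "ci_low": ci[j, 0],
                "ci_high": ci[j, 1],
                "boot_ci_low": boot.lower[j],
                "boot_ci_high": boot.upper[j],
                "vif": vifs[j - 1],
                "n": int(res.nobs),
            })
    return pd.DataFrame(records)


def age_tertiles(ages) -> np.ndarray:
    """Split into T1/T2/T3 at the empirical 1/3 and 2/3 quantiles.

    Values tied with a cut point go to the lower group.
    """
    ages = np.asarray(ages, float)
    if ages.size < 3:
        raise ValueError("need at least 3 subjects")
    if np.unique(ages).size < 3:
        raise ValueError("need at least 3 distinct ages")
    q1, q2 = np.quantile(ages, [1 / 3, 2 / 3])
    labels = np.where(ages <= q1, "T1", np.where(ages <= q2, "T2", "T3"))
    return labels


def gamma_glm_compare(volumes, groups) -> pd.DataFrame:
    """Pairwise group contrasts from a gamma GLM with log link.

    Each contrast is the fitted mean ratio exp(coefficient) of the second
    group over the first, with its Wald p-value.  Volumes must be strictly
    positive (apply the +1 mm^3 offset upstream if needed).
    """
    volumes = np.asarray(volumes, float)
    groups = np.asarray(groups)
    if (volumes <= 0).any():
        raise ValueError("volumes must be strictly positive (offset first)")
    levels = sorted(pd.unique(groups).tolist())
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    records = []
    for i, a in enumerate(levels):
        for b in levels[i + 1:]:
            sel = (groups == a) | (groups == b)
            y = volumes[sel]
            ind = (groups[sel] == b).astype(float)
            X = sm.add_constant(ind, has_constant="add")
            model = sm.GLM(y, X, family=sm.families.Gamma(sm.families.links.Log()))
            res = model.fit()
            records.append({
                "group_a": a,
                "group_b": b,
                "log_ratio": res.params[1],
                "ratio": float(np.exp(res.params[1])),
                "p": res.pvalues[1],
                "n_a": int((groups == a).sum()),
                "n_b": int((groups == b).sum()),
            })
    return pd.DataFrame(records)


def demographic_associations(
    component_scores: pd.DataFrame, age, sex
) -> pd.DataFrame:
    """Pearson (and Spearman) correlations with age; Welch t-test across sex."""
    age = np.asarray(age, float)
    sex = np.asarray(sex)
    if np.unique(age).size < 2:
        raise ValueError("age has zero variance")
    sex_levels = pd.unique(sex)
    records = []
    for comp in component_scores.columns:
        v = component_scores[comp].to_numpy(float)
        if v.std(ddof=1) == 0:
            raise ValueError(f"component {comp} has zero variance")
        r, rp = sps.pearsonr(v, age)
        rs, rsp = sps.spearmanr(v, age)
        rec = {
            "component": comp,
            "age_r": r,
            "age_r_p": rp,
            "age_rs": rs,
            "age_rs_p": rsp,
        }
        if len(sex_levels) == 2:
            g0 = v[sex == sex_levels[0]]
            g1 = v[sex == sex_levels[1]]
            t, tp = sps.ttest_ind(g0, g1, equal_var=False)
            rec.update({
                "sex_t": t,
                "sex_t_p": tp,
                "sex_group_a": str(sex_levels[0]),
                "sex_group_b": str(sex_levels[1]),
                "mean_a": float(g0.mean()),
                "mean_b": float(g1.mean()),
            })
        records.append(rec)
    return pd.DataFrame(records)
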