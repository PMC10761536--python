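"""Random-intercept linear mixed model for POC-minus-reference differences.

The model for the per-(animal, matrix) difference d is

    d = X beta + b_species + b_animal + e,
    b_g ~ N(0, sigma_g^2),  e ~ N(0, sigma_e^2),

with sex, centred weight/PCV/buffy-coat, and matrix as fixed effects and
species and individual as random intercepts (individuals are nested in
species by construction of the ids; coding them as crossed factors is
equivalent under nesting).

Fitting is restricted maximum likelihood with the fixed effects and the
residual variance profiled out: writing sigma_g^2 = theta_g * sigma_e^2,
the covariance is sigma_e^2 * W(theta) with
W = I + sum_g theta_g Z_g Z_g', and the optimizer works on log(theta)
(two parameters here) with L-BFGS-B from the deterministic start
theta_g = 1. Variance components may land on the boundary (theta ~ 0);
they are reported as ~0 and flagged, never an error.

Degrees of freedom for the Wald t-tests are the residual approximation
df = n_obs - p. This is anti-conservative for effects estimated between
small groups; it is stated in the output rather than patched with a
Satterthwaite correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .io_model import MeasurementTable, REFERENCE_DEVICE

logger = logging.getLogger("pocagree")

FIXED_EFFECTS = ["intercept", "sex_M", "weight_c", "pcv_c", "bc_c", "matrix_WB"]
BOUNDARY_THETA = 1e-8
_LOG_THETA_BOUNDS = (-25.0, 25.0)


@dataclass
class LMMDesign:
    """Response vector, fixed-effect matrix and grouping labels."""

    y: np.ndarray
    X: np.ndarray
    x_names: list
    groups: dict          # name -> label array, one label per row
    row_ids: list = field(default_factory=list)

    @property
    def n_obs(self) -> int:
        return self.y.size

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass
class LMMFit:
    beta: dict            # name -> dict(estimate, se, t, df, p)
    var_components: dict  # group name -> variance (response units squared)
    var_residual: float
    n_obs: int
    n_groups: dict
    converged: bool
    loglik_reml: float
    boundary: dict        # group name -> True if variance pinned near 0
    history: list         # -2*restricted-log-likelihood per optimizer iterate


def build_difference_design(
    table: MeasurementTable, analyte: str, device: str
) -> LMMDesign:
    """One response row per (animal, matrix): d = POC - reference.

    Matrix is coded plasma=0 / whole_blood=1, sex F=0 / M=1; continuous
    covariates are centred (affects only the intercept). Animals missing a
    fixed-effect covariate are dropped from the model with a warning — they
    still participate in the agreement statistics elsewhere.
    """
    df = table.df
    rep0 = df[df["replicate_id"] == 0]
    poc = rep0[(rep0["device"] == device) & (rep0["analyte"] == analyte)]
    ref = rep0[(rep0["device"] == REFERENCE_DEVICE) & (rep0["analyte"] == analyte)]
    if poc.empty or ref.empty:
        raise ValueError(f"no data for device={device!r}, analyte={analyte!r}")
    for part, label in ((poc, "POC"), (ref, "reference")):
        if (part["censored"] & part["value"].isna()).any():
            raise ValueError(f"{label} rows not imputed; apply impute_lloq first")

    merged = poc.merge(
        ref[["animal_id", "value"]], on="animal_id", suffixes=("", "_ref")
    ).sort_values(["animal_id", "matrix"], kind="mergesort")

    cov_cols = ["weight_kg", "pcv_pct", "bc_pct"]
    missing = merged[cov_cols].isna().any(axis=1)
    if missing.all():
        raise ValueError("all animals missing a fixed-effect covariate")
    if missing.any():
        bad = sorted(set(merged.loc[missing, "animal_id"]))
        logger.warning("mixed model drops animals with missing covariates: %s", bad)
        merged = merged[~missing]

    n_species = merged["species"].nunique()
    if n_species < 2:
        logger.warning("fewer than 2 species: species variance weakly identified")
    per_sp = merged.groupby("species")["animal_id"].nunique()
    if (per_sp < 2).any():
        logger.warning("species with a single animal: %s", list(per_sp[per_sp < 2].index))

    d = (merged["value"] - merged["value_ref"]).to_numpy(dtype=float)
    X = np.column_stack([
        np.ones(len(merged)),
        (merged["sex"] == "M").to_numpy(dtype=float),
        merged["weight_kg"].to_numpy(dtype=float) - merged["weight_kg"].mean(),
        merged["pcv_pct"].to_numpy(dtype=float) - merged["pcv_pct"].mean(),
        merged["bc_pct"].to_numpy(dtype=float) - merged["bc_pct"].mean(),
        (merged["matrix"] == "whole_blood").to_numpy(dtype=float),
    ])
    return LMMDesign(
        y=d,
        X=X,
        x_names=list(FIXED_EFFECTS),
        groups={
            "species": merged["species"].to_numpy(),
            "animal": merged["animal_id"].to_numpy(),
        },
        row_ids=list(zip(merged["animal_id"], merged["matrix"])),
    )


def _indicator(labels: np.ndarray) -> np.ndarray:
    levels, inv = np.unique(labels, return_inverse=True)
    Z = np.zeros((labels.size, levels.size))
    Z[np.arange(labels.size), inv] = 1.0
    return Z


def _reml_pieces(log_theta, y, X, ZZts, n, p):
    """Profiled -2 restricted log-likelihood (up to constant) and GLS pieces."""
    W = np.eye(n)
    for lt, ZZt in zip(log_theta, ZZts):
        W += np.exp(lt) * ZZt
    cf = linalg.cho_factor(W, lower=True)
    Wi_X = linalg.cho_solve(cf, X)
    Wi_y = linalg.cho_solve(cf, y)
    XtWiX = X.T @ Wi_X
    beta = linalg.solve(XtWiX, X.T @ Wi_y, assume_a="pos")
    r = y - X @ beta
    quad = float(r @ linalg.cho_solve(cf, r))
    sigma2 = quad / (n - p)
    logdet_w = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    _, logdet_xtx = np.linalg.slogdet(XtWiX)
    crit = (n - p) * np.log(sigma2) + logdet_w + logdet_xtx
    return crit, beta, sigma2, XtWiX


def fit_lmm(design: LMMDesign, method: str = "reml", maxiter: int = 500) -> LMMFit:
    """REML fit of the random-intercept model.

    Only REML is implemented (``method`` is kept for signature clarity).
    Non-convergence within ``maxiter`` iterations returns a fit with
    ``converged=False`` and the best iterate found, never an exception.
    """
    if method.lower() != "reml":
        raise ValueError("only REML fitting is implemented")
    y, X = design.y, design.X
    n, p = design.n_obs, design.p
    if n < p + 3:
        raise ValueError(f"need >= {p + 3} observations for {p} fixed effects, got {n}")

    names = list(design.groups)
    ZZts = [
        (Z := _indicator(design.groups[g])) @ Z.T for g in names
    ]

    history: list = []

    def objective(lt):
        return _reml_pieces(lt, y, X, ZZts, n, p)[0]

    def track(lt):
        history.append(float(objective(lt)))

    x0 = np.zeros(len(names))  # theta_g = 1, documented deterministic start
    history.append(float(objective(x0)))
    res = optimize.minimize(
        objective,
        x0,
        method="L-BFGS-B",
        bounds=[_LOG_THETA_BOUNDS] * len(names),
        callback=track,
        options={"maxiter": maxiter, "ftol": 1e-13, "gtol": 1e-9},
    )
    # simplex polish at tight tolerance: pins the optimum precisely enough
    # that fixed-effect estimates are invariant to row ordering
    polish = optimize.minimize(
        objective, res.x, method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-13, "maxiter": 400},
    )
    x_pol = polish.x if polish.fun <= res.fun else res.x
    x_best, success = _refine_boundary(objective, x_pol, len(names), maxiter)
    success = success and bool(res.success or polish.success)
    if objective(x_best) <= history[-1]:
        history.append(float(objective(x_best)))

    crit, beta, sigma2, XtWiX = _reml_pieces(x_best, y, X, ZZts, n, p)
    theta = np.exp(x_best)
    cov_beta = sigma2 * linalg.inv(XtWiX)
    se = np.sqrt(np.diag(cov_beta))
    df = n - p
    tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)

    loglik = -0.5 * (crit + (n - p) * (1.0 + np.log(2.0 * np.pi)))
    fit = LMMFit(
        beta={
            name: {
                "estimate": float(b), "se": float(s), "t": float(t),
                "df": int(df), "p": float(pv),
            }
            for name, b, s, t, pv in zip(design.x_names, beta, se, tvals, pvals)
        },
        var_components={
            g: float(th * sigma2) for g, th in zip(names, theta)
        },
        var_residual=float(sigma2),
        n_obs=n,
        n_groups={g: int(np.unique(design.groups[g]).size) for g in names},
        converged=bool(success),
        loglik_reml=float(loglik),
        boundary={g: bool(th < BOUNDARY_THETA) for g, th in zip(names, theta)},
        history=history,
    )
    if not success:
        logger.warning("REML optimizer did not converge: %s", res.message)
    return fit


def _refine_boundary(objective, x_opt, k, maxiter):
    """Snap near-zero variance ratios onto the boundary when REML allows it.

    The profiled criterion is extremely flat in log(theta) as theta -> 0, so
    a gradient optimizer stalls at small positive ratios even when the true
    REML optimum sits on the theta = 0 boundary. Each subset of components
    is pinned to the lower bound and the rest re-optimized; the candidate
    with the smallest criterion wins (ties go to the boundary).
    """
    from itertools import combinations

    lo = _LOG_THETA_BOUNDS[0]
    best_x, best_f, success = np.asarray(x_opt, dtype=float), float(objective(x_opt)), True
    small = [i for i in range(k) if x_opt[i] < np.log(1e-2)]
    for r in range(1, len(small) + 1):
        for pins in combinations(small, r):
            free = [i for i in range(k) if i not in pins]

            def obj_sub(z, pins=pins, free=free):
                full = np.array(best_x, copy=True)
                full[list(pins)] = lo
                full[free] = z
                return objective(full)

            if free:
                sub = optimize.minimize(
                    obj_sub, np.asarray(x_opt, dtype=float)[free],
                    method="L-BFGS-B", bounds=[_LOG_THETA_BOUNDS] * len(free),
                    options={"maxiter": maxiter},
                )
                cand = np.array(x_opt, dtype=float)
                cand[list(pins)] = lo
                cand[free] = sub.x
                f_cand, ok = float(objective(cand)), bool(sub.success)
            else:
                cand = np.full(k, lo)
                f_cand, ok = float(objective(cand)), True
            if f_cand <= best_f + 1e-10:
                best_x, best_f, success = cand, min(f_cand, best_f), ok
    return best_x, success


def significance_screen(fits: dict, alpha: float = 0.05) -> pd.DataFrame:
    """Covariate-by-model table of Wald significance flags.

    ``fits`` maps a model label (e.g. ``(device, analyte)``) to an LMMFit;
    intercepts are not screened.
    """
    rows = {}
    for label, fit in fits.items():
        rows[label] = {
            term: bool(v["p"] < alpha)
            for term, v in fit.beta.items()
            if term != "intercept"
        }
    return pd.DataFrame(rows).T
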