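"""Trait derivation and pre-adjustment for progeny-trial phenotypes.

The package works with a long-format observation table (one row per tree,
trait) with columns::

    tree_id, site, provenance, replication, trait, value

Each tree is phenotyped at exactly one site.  The pre-adjustment chain is
trait derivation (ring indices), log transforms, replication-effect
("design") adjustment per trait-site, an optional two-step VPD/HAS
correction for gas-exchange traits, and z-standardization.  Downstream
model fitting consumes the adjusted, standardized values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "compute_ring_indices",
    "log_transform",
    "adjust_design_effects",
    "adjust_gas_exchange",
    "standardize",
]

REQUIRED_COLUMNS = ("tree_id", "site", "provenance", "replication", "trait", "value")


def _check_table(t: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in t.columns]
    if missing:
        raise ValueError(f"observation table missing columns: {missing}")
    sites_per_tree = t.groupby("tree_id")["site"].nunique()
    if (sites_per_tree > 1).any():
        bad = sites_per_tree[sites_per_tree > 1].index[:5].tolist()
        raise ValueError(f"trees observed at more than one site: {bad}")


# ---------------------------------------------------------------------------
# Ring indices
# ---------------------------------------------------------------------------

def compute_ring_indices(
    years,
    bai,
    drought_year: int,
    baseline_years,
) -> tuple[float, float]:
    """Drought resistance and mean sensitivity from a basal-area-increment series.

    Resistance is the ratio of drought-year BAI to the mean BAI over the
    baseline years.  Sensitivity is the classical dendrochronology mean
    sensitivity: the average over consecutive year pairs of
    ``|2 (b_t - b_{t-1}) / (b_t + b_{t-1})|``.
    """
    years = np.asarray(years)
    bai = np.asarray(bai, dtype=np.float64)
    if len(years) != len(bai):
        raise ValueError("years and bai lengths differ")
    if len(years) > 1 and not (np.diff(years.astype(int)) > 0).all():
        raise ValueError("years must be strictly increasing")
    if (bai < 0).any():
        raise ValueError("negative BAI")
    lookup = dict(zip(years.tolist(), bai.tolist()))
    if drought_year not in lookup:
        raise ValueError(f"drought year {drought_year} absent from series")
    base = [lookup.get(y) for y in baseline_years]
    if any(b is None for b in base):
        raise ValueError("baseline year absent from series")
    base_mean = float(np.mean(base))
    if base_mean <= 0:
        raise ValueError("baseline mean BAI must be positive")
    resistance = float(lookup[drought_year] / base_mean)
    if len(bai) < 2:
        raise ValueError("need at least 2 years for sensitivity")
    b0, b1 = bai[:-1], bai[1:]
    denom = b0 + b1
    if (denom == 0).any():
        raise ValueError("consecutive years with zero total BAI")
    sensitivity = float(np.mean(np.abs(2.0 * (b1 - b0) / denom)))
    return resistance, sensitivity


# ---------------------------------------------------------------------------
# Log transform and standardization
# ---------------------------------------------------------------------------

def log_transform(t: pd.DataFrame, trait_names) -> pd.DataFrame:
    """Natural-log transform the named traits in place of their values."""
    _check_table(t)
    out = t.copy()
    sel = out["trait"].isin(set(trait_names))
    vals = out.loc[sel, "value"].to_numpy(dtype=np.float64)
    if (vals <= 0).any():
        raise ValueError("log transform requires strictly positive values")
    out.loc[sel, "value"] = np.log(vals)
    return out


def standardize(t: pd.DataFrame, scope: str = "trait") -> pd.DataFrame:
    """Z-score values to mean 0, sample variance 1.

    ``scope`` is "trait" (pooled over sites, the default — between-site
    mean and scale differences are left for the model's site-specific
    fixed effects) or "trait_site".
    """
    _check_table(t)
    keys = ["trait"] if scope == "trait" else ["trait", "site"]
    if scope not in ("trait", "trait_site"):
        raise ValueError("scope must be 'trait' or 'trait_site'")
    out = t.copy()

    def _z(x: pd.Series) -> pd.Series:
        if len(x) < 2 or x.std(ddof=1) == 0:
            raise ValueError("constant or singleton trait within standardization scope")
        return (x - x.mean()) / x.std(ddof=1)

    out["value"] = out.groupby(keys, group_keys=False)["value"].transform(_z)
    return out


# ---------------------------------------------------------------------------
# Replication-effect (design) adjustment
# ---------------------------------------------------------------------------

def _two_vc_reml(y: np.ndarray, rep_codes: np.ndarray, fam_codes: np.ndarray):
    """REML for y = mu + rep + fam + e with independent random rep and fam.

    Small dedicated profile-likelihood fit (two variance ratios via
    L-BFGS on log scale); returns (sigma2_rep, sigma2_fam, sigma2_e,
    rep_blups dict).  Kept internal: the surface is adjust_design_effects.
    """
    from scipy import linalg, optimize

    n = len(y)
    reps, rep_idx = np.unique(rep_codes, return_inverse=True)
    fams, fam_idx = np.unique(fam_codes, return_inverse=True)
    Zr = np.zeros((n, len(reps)))
    Zr[np.arange(n), rep_idx] = 1.0
    Zf = np.zeros((n, len(fams)))
    Zf[np.arange(n), fam_idx] = 1.0
    X = np.ones((n, 1))
    Kr, Kf = Zr @ Zr.T, Zf @ Zf.T

    def neg_reml(theta):
        gr, gf = np.exp(theta)  # variance ratios relative to sigma2_e
        V = gr * Kr + gf * Kf + np.eye(n)
        try:
            c, low = linalg.cho_factor(V, lower=True)
        except linalg.LinAlgError:
            return 1e10
        Vi_y = linalg.cho_solve((c, low), y)
        Vi_X = linalg.cho_solve((c, low), X)
        XtViX = X.T @ Vi_X
        beta = np.linalg.solve(XtViX, X.T @ Vi_y)
        Py = Vi_y - Vi_X @ beta
        ypy = float(y @ Py)
        logdet_V = 2.0 * np.log(np.diag(c)).sum()
        logdet_X = np.log(np.linalg.det(XtViX))
        # profile out sigma2_e
        df = n - X.shape[1]
        s2e = ypy / df
        return 0.5 * (logdet_V + logdet_X + df * np.log(s2e) + df)

    res = optimize.minimize(neg_reml, x0=np.log([0.1, 0.3]), method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 2000})
    gr, gf = np.exp(res.x)
    V = gr * Kr + gf * Kf + np.eye(n)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    P = Vi - Vi @ X @ np.linalg.solve(XtViX, X.T @ Vi)
    Py = P @ y
    s2e = float(y @ Py) / (n - X.shape[1])
    s2r, s2f = gr * s2e, gf * s2e
    # BLUP u_rep = s2r * Zr' P_actual y; P above uses V/s2e, so the ratio gr absorbs 1/s2e
    rep_blup = gr * (Zr.T @ Py)
    return s2r, s2f, s2e, dict(zip(reps, rep_blup))


def adjust_design_effects(
    t: pd.DataFrame,
    rep_model: str = "random",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Subtract estimated within-site replication (block) effects per trait-site.

    For every trait-site the model intercept + replication + maternal
    family + residual is fitted (replication random by default, family
    always random; the family term is the half-sib stand-in for a full
    pedigree model at this adjustment step).  The returned table carries
    ``value`` minus the tree's block-effect estimate; the second return
    is the replication-variance fraction of total per trait-site.

    ``rep_model='fixed'`` estimates centered block effects by ordinary
    least squares on the replication factor instead.
    """
    _check_table(t)
    if "family" not in t.columns:
        raise ValueError("adjust_design_effects requires a 'family' column")
    if rep_model not in ("random", "fixed"):
        raise ValueError("rep_model must be 'random' or 'fixed'")
    out = t.copy()
    out["value_adjusted"] = np.nan
    rows = []
    for (trait, site), grp in out.groupby(["trait", "site"]):
        if grp["replication"].nunique() < 2:
            raise ValueError(f"trait {trait} site {site}: fewer than 2 replications")
        y = grp["value"].to_numpy(dtype=np.float64)
        if rep_model == "random":
            s2r, s2f, s2e, rep_eff = _two_vc_reml(
                y, grp["replication"].to_numpy(), grp["family"].to_numpy()
            )
            frac = s2r / (s2r + s2f + s2e)
        else:
            means = grp.groupby("replication")["value"].mean()
            rep_eff = (means - means.mean()).to_dict()
            s_tot = float(np.var(y, ddof=1))
            frac = float(np.var([rep_eff[r] for r in grp["replication"]], ddof=1)) / s_tot
        eff = grp["replication"].map(rep_eff).to_numpy(dtype=np.float64)
        out.loc[grp.index, "value_adjusted"] = y - eff
        rows.append({"trait": trait, "site": site, "rep_variance_fraction": frac})
    out["value"] = out["value_adjusted"]
    out = out.drop(columns=["value_adjusted"])
    return out, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Gas-exchange (VPD / HAS) two-step correction
# ---------------------------------------------------------------------------

def adjust_gas_exchange(recs: pd.DataFrame, use_log_vpd: bool = False) -> pd.DataFrame:
    """Two-step covariate correction of gas-exchange traits per site.

    Step 1 regresses the trait value on vapor pressure deficit (VPD, or
    its natural log) and keeps residuals.  Step 2 removes the part of
    hours-after-sunrise (HAS) not explained by VPD: HAS is regressed on
    the VPD predictor, and the step-1 residuals are regressed on that
    HAS residual.  The final residuals are re-centered to the site mean.

    ``recs`` needs columns tree_id, site, value, vpd, has (single trait
    per call).
    """
    for c in ("tree_id", "site", "value", "vpd", "has"):
        if c not in recs.columns:
            raise ValueError(f"gas-exchange records missing column {c!r}")
    out = recs.copy()
    out["value_adjusted"] = np.nan
    for site, grp in out.groupby("site"):
        if len(grp) < 3:
            raise ValueError(f"site {site}: need >=3 records")
        vpd = grp["vpd"].to_numpy(dtype=np.float64)
        if use_log_vpd:
            if (vpd <= 0).any():
                raise ValueError("log-VPD predictor requires vpd > 0")
            x1 = np.log(vpd)
        else:
            x1 = vpd
        has = grp["has"].to_numpy(dtype=np.float64)
        y = grp["value"].to_numpy(dtype=np.float64)
        if np.std(x1) == 0 or np.std(has) == 0:
            raise ValueError(f"site {site}: zero variance in vpd or has")
        r1 = _ols_residuals(y, x1)
        has_resid = _ols_residuals(has, x1)
        if np.std(has_resid) > 1e-12:
            r2 = _ols_residuals(r1, has_resid)
        else:  # HAS fully collinear with VPD: nothing left to remove
            r2 = r1
        out.loc[grp.index, "value_adjusted"] = r2 + y.mean()
    out["value"] = out["value_adjusted"]
    return out.drop(columns=["value_adjusted"])


def _ols_residuals(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta
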