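"""Multi-environment individual-tree GBLUP: REML and mixed-model equations.

The model stacks per-site phenotype vectors y_s (each tree measured at
exactly one site) as

    y = X beta + Z a + e,
    a ~ N(0, Sigma_a (x) G),    e ~ N(0, R0 (x) I),

where Sigma_a is the S x S unstructured across-site additive (co)variance
matrix, G the genomic relationship matrix over all n trees, R0 the
diagonal per-site residual variances (sites are assessed separately, so
residual covariances across sites are zero), and beta the fixed effects
of genetic group (provenance) nested within site.

Because each record belongs to one tree at one site, the phenotypic
covariance matrix has the closed elementwise form

    V[i, j] = Sigma_a[s_i, s_j] * G[t_i, t_j] + delta_ij * sigma2_e[s_i],

which keeps a restricted-likelihood evaluation at O(N^3) dense algebra
for N records.  REML maximizes the restricted log-likelihood over a
log-Cholesky parameterization of Sigma_a (positive semidefinite by
construction) and log residual variances, with analytic gradients;
standard errors come from the average-information matrix at the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from megblup.geno import GenomicRelationshipMatrix

__all__ = [
    "ModelSpec",
    "VarianceComponentSet",
    "MMEResult",
    "build_model",
    "fit_reml",
    "solve_mme",
    "heritability",
    "genetic_correlation",
    "average_gxe_variance",
]


# ---------------------------------------------------------------------------
# Model specification
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Design of one trait's multi-environment analysis.

    Records are stored sorted by site.  ``tree_idx`` indexes records into
    ``grm.tree_ids`` (the random-effect universe: all genotyped trees,
    phenotyped or not), ``site_idx`` into ``sites``.
    """

    sites: list
    y: np.ndarray
    X: np.ndarray
    fixed_labels: list
    site_idx: np.ndarray
    tree_idx: np.ndarray
    grm: GenomicRelationshipMatrix
    record_tree_ids: np.ndarray = None

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_records(self) -> int:
        return len(self.y)

    @property
    def n_trees(self) -> int:
        return self.grm.n_trees

    def site_records(self, s: int) -> np.ndarray:
        return np.flatnonzero(self.site_idx == s)

    def subset(self, record_mask: np.ndarray) -> "ModelSpec":
        """Spec restricted to the masked records (fixed design rebuilt,
        empty fixed-effect columns dropped)."""
        record_mask = np.asarray(record_mask, dtype=bool)
        X = self.X[record_mask]
        keep_cols = X.any(axis=0)
        return ModelSpec(
            sites=self.sites,
            y=self.y[record_mask],
            X=X[:, keep_cols],
            fixed_labels=[l for l, k in zip(self.fixed_labels, keep_cols) if k],
            site_idx=self.site_idx[record_mask],
            tree_idx=self.tree_idx[record_mask],
            grm=self.grm,
            record_tree_ids=self.record_tree_ids[record_mask],
        )


def build_model(
    pheno: pd.DataFrame,
    grm: GenomicRelationshipMatrix,
    trait: str,
    site_order=None,
) -> ModelSpec:
    """Assemble a :class:`ModelSpec` for one trait from a long-format table.

    Fixed effects are genetic-group (provenance) indicators nested within
    site; the per-site intercept is absorbed by the provenance levels.
    Trees with phenotypes but no genotype raise.
    """
    recs = pheno.loc[(pheno["trait"] == trait) & pheno["value"].notna()].copy()
    if recs.empty:
        raise ValueError(f"no records for trait {trait!r}")
    sites = list(site_order) if site_order is not None else sorted(recs["site"].unique())
    recs = recs[recs["site"].isin(sites)]
    site_pos = {s: i for i, s in enumerate(sites)}
    tree_pos = {t: i for i, t in enumerate(grm.tree_ids)}
    missing = set(recs["tree_id"]) - set(tree_pos)
    if missing:
        raise ValueError(f"phenotyped trees absent from GRM: {sorted(missing)[:5]}")
    recs["__site"] = recs["site"].map(site_pos)
    recs = recs.sort_values(["__site", "tree_id"], kind="stable").reset_index(drop=True)
    site_idx = recs["__site"].to_numpy(dtype=np.intp)
    tree_idx = recs["tree_id"].map(tree_pos).to_numpy(dtype=np.intp)
    y = recs["value"].to_numpy(dtype=np.float64)
    levels = sorted(set(zip(recs["site"], recs["provenance"])), key=lambda x: (site_pos[x[0]], str(x[1])))
    cols = {lv: j for j, lv in enumerate(levels)}
    X = np.zeros((len(recs), len(levels)))
    for i, (s, p) in enumerate(zip(recs["site"], recs["provenance"])):
        X[i, cols[(s, p)]] = 1.0
    return ModelSpec(
        sites=sites,
        y=y,
        X=X,
        fixed_labels=[f"{s}:{p}" for s, p in levels],
        site_idx=site_idx,
        tree_idx=tree_idx,
        grm=grm,
        record_tree_ids=recs["tree_id"].to_numpy(dtype=object),
    )


# ---------------------------------------------------------------------------
# Variance components
# ---------------------------------------------------------------------------

@dataclass
class VarianceComponentSet:
    """Across-site genetic covariance Sigma_a, diagonal residuals, and fit info."""

    sites: list
    sigma_a: np.ndarray  # S x S
    r0_diag: np.ndarray  # S
    loglik: float = np.nan
    n_iter: int = 0
    converged: bool = True
    component_names: list = field(default_factory=list)
    component_cov: np.ndarray = None  # asymptotic covariance of components

    def __post_init__(self) -> None:
        self.sigma_a = np.asarray(self.sigma_a, dtype=np.float64)
        self.r0_diag = np.asarray(self.r0_diag, dtype=np.float64)
        S = len(self.sites)
        if self.sigma_a.shape != (S, S):
            raise ValueError("sigma_a shape mismatch")
        if not np.allclose(self.sigma_a, self.sigma_a.T, atol=1e-8):
            raise ValueError("sigma_a not symmetric")
        if (self.r0_diag <= 0).any():
            raise ValueError("residual variances must be positive")
        eig = np.linalg.eigvalsh(self.sigma_a)
        if eig.min() < -1e-8 * max(1.0, eig.max()):
            raise ValueError("sigma_a not positive semidefinite")

    def site_index(self, site) -> int:
        return self.sites.index(site)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        S = len(self.sites)
        for i in range(S):
            for j in range(i, S):
                rows.append({"component": f"sigma_a[{self.sites[i]},{self.sites[j]}]",
                             "value": self.sigma_a[i, j]})
        for i, s in enumerate(self.sites):
            rows.append({"component": f"sigma2_e[{s}]", "value": self.r0_diag[i]})
        return pd.DataFrame(rows)


def _component_list(S: int):
    """(kind, i, j) order: vech(Sigma_a) column-wise, then residuals."""
    comps = [("a", i, j) for j in range(S) for i in range(j, S)]
    comps += [("e", s, s) for s in range(S)]
    return comps


class _REMLWorkspace:
    """Caches record-level G and site index sets for likelihood evaluations."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        G = spec.grm.values
        self.Gbig = G[np.ix_(spec.tree_idx, spec.tree_idx)]
        self.S = spec.n_sites
        self.site_lists = [spec.site_records(s) for s in range(self.S)]
        self.site_of = spec.site_idx
        self.N, self.p = spec.X.shape
        if np.linalg.matrix_rank(spec.X) < self.p:
            raise ValueError("fixed-effect design is rank deficient")

    def build_V(self, sigma_a: np.ndarray, r0: np.ndarray) -> np.ndarray:
        V = sigma_a[np.ix_(self.site_of, self.site_of)] * self.Gbig
        V[np.diag_indices(self.N)] += r0[self.site_of]
        return V

    def reml_pieces(self, sigma_a, r0):
        """Returns (neg. restricted loglik, P, Py) or (None, ...) on failure."""
        V = self.build_V(sigma_a, r0)
        try:
            c, low = linalg.cho_factor(V, lower=True, check_finite=False)
        except linalg.LinAlgError:
            return None, None, None
        X, y = self.spec.X, self.spec.y
        Vi_y = linalg.cho_solve((c, low), y, check_finite=False)
        Vi_X = linalg.cho_solve((c, low), X, check_finite=False)
        XtViX = X.T @ Vi_X
        sign, logdet_X = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return None, None, None
        XtViX_inv = np.linalg.inv(XtViX)
        Py = Vi_y - Vi_X @ (XtViX_inv @ (X.T @ Vi_y))
        logdet_V = 2.0 * np.log(np.diag(c)).sum()
        nll = 0.5 * (logdet_V + logdet_X + float(y @ Py))
        Vi = linalg.cho_solve((c, low), np.eye(self.N), check_finite=False)
        P = Vi - Vi_X @ XtViX_inv @ Vi_X.T
        return nll, P, Py

    def component_gradients(self, P, Py):
        """d(loglik)/d(component) for each component in _component_list order."""
        A = P * self.Gbig
        u = Py
        Uouter = np.outer(u, u) * self.Gbig
        grads = []
        diagP = np.diag(P)
        for kind, i, j in _component_list(self.S):
            if kind == "a":
                Ii, Ij = self.site_lists[i], self.site_lists[j]
                tr = A[np.ix_(Ii, Ij)].sum()
                quad = Uouter[np.ix_(Ii, Ij)].sum()
                if i != j:  # symmetric pair (i,j)+(j,i)
                    tr *= 2.0
                    quad *= 2.0
            else:
                Ii = self.site_lists[i]
                tr = diagP[Ii].sum()
                quad = (u[Ii] ** 2).sum()
            grads.append(-0.5 * (tr - quad))
        return np.asarray(grads)

    def average_information(self, sigma_a, r0):
        """AI matrix over components at the given parameter point."""
        nll, P, Py = self.reml_pieces(sigma_a, r0)
        if nll is None:
            raise ValueError("singular V at AI evaluation")
        comps = _component_list(self.S)
        tvecs = []
        u = Py
        for kind, i, j in comps:
            t = np.zeros(self.N)
            if kind == "a":
                Ii, Ij = self.site_lists[i], self.site_lists[j]
                t[Ii] += self.Gbig[np.ix_(Ii, Ij)] @ u[Ij]
                if i != j:
                    t[Ij] += self.Gbig[np.ix_(Ij, Ii)] @ u[Ii]
            else:
                Ii = self.site_lists[i]
                t[Ii] = u[Ii]
            tvecs.append(t)
        T = np.column_stack(tvecs)
        PT = P @ T
        return 0.5 * (T.T @ PT), comps


def _theta_to_components(theta: np.ndarray, S: int):
    """theta = (log-Cholesky of Sigma_a, log residual sds) -> (Sigma_a, r0, L)."""
    nL = S * (S + 1) // 2
    L = np.zeros((S, S))
    k = 0
    for j in range(S):
        for i in range(j, S):
            L[i, j] = np.exp(theta[k]) if i == j else theta[k]
            k += 1
    r0 = np.exp(2.0 * theta[nL:])
    return L @ L.T, r0, L


def fit_reml(
    spec: ModelSpec,
    init: VarianceComponentSet | None = None,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> VarianceComponentSet:
    """REML estimates of (Sigma_a, diag R0) for one trait.

    Maximizes the restricted log-likelihood by quasi-Newton (L-BFGS-B)
    on the log-Cholesky parameterization of Sigma_a and log residual
    standard deviations, with analytic gradients; Sigma_a stays positive
    semidefinite by construction.  Raises on non-convergence.
    """
    ws = _REMLWorkspace(spec)
    S = spec.n_sites
    # starting values: half the per-site phenotypic variance each side,
    # genetic correlation 0.5 across sites
    vp = np.array([np.var(spec.y[ws.site_lists[s]], ddof=1) if len(ws.site_lists[s]) > 1 else 1.0
                   for s in range(S)])
    vp = np.maximum(vp, 1e-6)
    if init is not None:
        sig0, r00 = init.sigma_a, init.r0_diag
    else:
        sd = np.sqrt(0.5 * vp)
        sig0 = 0.5 * np.outer(sd, sd) + 0.5 * np.diag(sd**2)
        r00 = 0.5 * vp
    L0 = np.linalg.cholesky(sig0 + 1e-8 * np.eye(S))
    theta0 = []
    for j in range(S):
        for i in range(j, S):
            theta0.append(np.log(max(L0[i, j], 1e-6)) if i == j else L0[i, j])
    theta0 += list(0.5 * np.log(r00))
    theta0 = np.asarray(theta0)

    comps = _component_list(S)
    nL = S * (S + 1) // 2
    scale = float(np.sqrt(vp.mean()))
    bounds = []
    k = 0
    for j in range(S):
        for i in range(j, S):
            if i == j:
                bounds.append((np.log(1e-4 * scale), np.log(1e3 * scale)))
            else:
                bounds.append((-1e3 * scale, 1e3 * scale))
            k += 1
    bounds += [(np.log(1e-4 * scale), np.log(1e3 * scale))] * S

    n_eval = [0]

    def objective(theta):
        n_eval[0] += 1
        sigma_a, r0, L = _theta_to_components(theta, S)
        nll, P, Py = ws.reml_pieces(sigma_a, r0)
        if nll is None:
            return 1e10, np.zeros_like(theta)
        grads = ws.component_gradients(P, Py)  # d(ll)/d(component)
        # map symmetric-component gradient to full-matrix gradient Gbar
        Gbar = np.zeros((S, S))
        for g, (kind, i, j) in zip(grads, comps):
            if kind == "a":
                if i == j:
                    Gbar[i, i] = g
                else:
                    Gbar[i, j] = Gbar[j, i] = g / 2.0
        dL = 2.0 * Gbar @ L  # d(ll)/dL for Sigma = L L'
        grad_theta = np.zeros_like(theta)
        k = 0
        for j in range(S):
            for i in range(j, S):
                grad_theta[k] = dL[i, j] * (L[i, j] if i == j else 1.0)
                k += 1
        for s in range(S):
            g_e = grads[nL + s]
            grad_theta[nL + s] = g_e * 2.0 * r0[s]  # d sigma2 / d(log sd) = 2 sigma2
        return nll, -grad_theta

    res = optimize.minimize(
        objective, theta0, jac=True, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-6},
    )
    if not res.success and "ABNORMAL" in str(res.message).upper():
        raise RuntimeError(f"REML did not converge: {res.message}")
    sigma_a, r0, _ = _theta_to_components(res.x, S)
    try:
        AI, comp_list = ws.average_information(sigma_a, r0)
        cov = np.linalg.pinv(AI)
    except (ValueError, np.linalg.LinAlgError):
        cov, comp_list = None, comps
    names = [f"sigma_a[{i},{j}]" if k == "a" else f"sigma2_e[{i}]" for k, i, j in comp_list]
    return VarianceComponentSet(
        sites=spec.sites,
        sigma_a=(sigma_a + sigma_a.T) / 2.0,
        r0_diag=r0,
        loglik=-res.fun,
        n_iter=int(res.nit),
        converged=bool(res.success),
        component_names=names,
        component_cov=cov,
    )


# ---------------------------------------------------------------------------
# Mixed-model equations
# ---------------------------------------------------------------------------

@dataclass
class MMEResult:
    """Solutions of Henderson's equations for the multi-environment model."""

    sites: list
    tree_ids: np.ndarray
    beta: np.ndarray
    fixed_labels: list
    breeding_values: np.ndarray  # S x n, all trees at all sites
    pev: np.ndarray = None  # (S n) x (S n) random-block inverse, site-major

    def bv_site(self, s: int) -> np.ndarray:
        return self.breeding_values[s]

    def pev_block(self, s: int, t: int) -> np.ndarray:
        if self.pev is None:
            raise ValueError("MME was solved without return_pev=True")
        n = len(self.tree_ids)
        return self.pev[s * n:(s + 1) * n, t * n:(t + 1) * n]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s, site in enumerate(self.sites):
            rows.append(pd.DataFrame({
                "tree_id": self.tree_ids, "site": site,
                "breeding_value": self.breeding_values[s]}))
        return pd.concat(rows, ignore_index=True)


def solve_mme(
    spec: ModelSpec,
    vc: VarianceComponentSet,
    return_pev: bool = False,
) -> MMEResult:
    """Solve Henderson's mixed-model equations at fixed variance components.

    Every genotyped tree receives a breeding value at every site —
    information flows across sites through Sigma_a and across trees
    through G — which is what the per-site GWAS back-solution consumes.
    With ``return_pev`` the random-effect block of the coefficient-matrix
    inverse (prediction-error covariances) is also returned.
    """
    S, n, N = spec.n_sites, spec.n_trees, spec.n_records
    X, y = spec.X, spec.y
    p = X.shape[1]
    rinv = 1.0 / vc.r0_diag[spec.site_idx]
    # Z maps record i -> random index s_i * n + t_i
    zcol = spec.site_idx * n + spec.tree_idx
    dim = p + S * n
    C = np.zeros((dim, dim))
    rhs = np.zeros(dim)
    Xw = X * rinv[:, None]
    C[:p, :p] = X.T @ Xw
    rhs[:p] = Xw.T @ y
    XtZ = np.zeros((p, S * n))
    np.add.at(XtZ.T, zcol, Xw)
    C[:p, p:] = XtZ
    C[p:, :p] = XtZ.T
    ZtZ_diag = np.zeros(S * n)
    np.add.at(ZtZ_diag, zcol, rinv)
    Zty = np.zeros(S * n)
    np.add.at(Zty, zcol, rinv * y)
    rhs[p:] = Zty
    Ginv = _spd_inverse(spec.grm.values)
    sig_inv = _spd_inverse(vc.sigma_a)
    C[p:, p:] = np.kron(sig_inv, Ginv)
    C[p:, p:][np.diag_indices(S * n)] += ZtZ_diag
    try:
        cf = linalg.cho_factor(C, lower=True, check_finite=False)
    except linalg.LinAlgError as exc:
        raise ValueError("singular MME coefficient matrix (confounded fixed effects?)") from exc
    sol = linalg.cho_solve(cf, rhs, check_finite=False)
    beta = sol[:p]
    a = sol[p:].reshape(S, n)
    pev = None
    if return_pev:
        Cinv = linalg.cho_solve(cf, np.eye(dim), check_finite=False)
        pev = Cinv[p:, p:]
    return MMEResult(
        sites=vc.sites,
        tree_ids=spec.grm.tree_ids,
        beta=beta,
        fixed_labels=spec.fixed_labels,
        breeding_values=a,
        pev=pev,
    )


def _spd_inverse(M: np.ndarray) -> np.ndarray:
    try:
        cf = linalg.cho_factor(M, lower=True, check_finite=False)
    except linalg.LinAlgError as exc:
        raise ValueError("matrix not positive definite (blend the GRM or check Sigma_a)") from exc
    return linalg.cho_solve(cf, np.eye(M.shape[0]), check_finite=False)


# ---------------------------------------------------------------------------
# Derived genetic parameters
# ---------------------------------------------------------------------------

def _component_cov_entry(vc: VarianceComponentSet, name_i: str, name_j: str) -> float:
    if vc.component_cov is None:
        return np.nan
    i = vc.component_names.index(name_i)
    j = vc.component_names.index(name_j)
    return float(vc.component_cov[i, j])


def heritability(vc: VarianceComponentSet, site) -> tuple[float, float]:
    """Narrow-sense heritability h2 = sigma2_a / (sigma2_a + sigma2_e) at a site,
    with a delta-method standard error from the AI covariance."""
    s = vc.site_index(site)
    va, ve = vc.sigma_a[s, s], vc.r0_diag[s]
    tot = va + ve
    if tot == 0:
        raise ValueError("total variance is zero")
    h2 = va / tot
    grad = np.array([ve / tot**2, -va / tot**2])  # d/d va, d/d ve
    na, ne = f"sigma_a[{s},{s}]", f"sigma2_e[{s}]"
    cov = np.array([
        [_component_cov_entry(vc, na, na), _component_cov_entry(vc, na, ne)],
        [_component_cov_entry(vc, na, ne), _component_cov_entry(vc, ne, ne)],
    ])
    se = float(np.sqrt(grad @ cov @ grad)) if np.isfinite(cov).all() else np.nan
    return float(h2), se


def genetic_correlation(vc: VarianceComponentSet, site_i, site_j) -> tuple[float, float]:
    """Across-site genetic correlation r = sigma_aij / sqrt(sigma2_ai sigma2_aj),
    clamped to [-1, 1], with a delta-method standard error."""
    i, j = vc.site_index(site_i), vc.site_index(site_j)
    vi, vj, cij = vc.sigma_a[i, i], vc.sigma_a[j, j], vc.sigma_a[i, j]
    if vi <= 0 or vj <= 0:
        raise ValueError("zero genetic variance at a site")
    r = cij / np.sqrt(vi * vj)
    r_cl = float(np.clip(r, -1.0, 1.0))
    # gradient wrt (c_ij, v_i, v_j)
    grad = np.array([
        1.0 / np.sqrt(vi * vj),
        -0.5 * cij / (vi ** 1.5 * np.sqrt(vj)),
        -0.5 * cij / (np.sqrt(vi) * vj ** 1.5),
    ])
    lo, hi = (i, j) if i >= j else (j, i)  # vech stores (i>=j, column j)
    names = [f"sigma_a[{lo},{hi}]", f"sigma_a[{i},{i}]", f"sigma_a[{j},{j}]"]
    cov = np.array([[_component_cov_entry(vc, a, b) for b in names] for a in names])
    se = float(np.sqrt(grad @ cov @ grad)) if np.isfinite(cov).all() else np.nan
    return r_cl, se


def average_gxe_variance(
    vc: VarianceComponentSet,
    pair_variance_fn=None,
) -> tuple[float, float]:
    """Average genotype-by-environment interaction variance across site pairs.

    The default per-pair interaction variance is

        v_ij = (sd_ai - sd_aj)^2 / 2 + sd_ai * sd_aj * (1 - r_ij),

    the heterogeneity-of-scale plus imperfect-correlation decomposition of
    a two-environment interaction; it is deliberately pluggable through
    ``pair_variance_fn(va_i, va_j, cov_ij)`` so an alternative definition
    can be swapped in.  Returns (mean pair variance, percentage of the
    mean phenotypic variance across sites).
    """
    S = len(vc.sites)
    if S < 2:
        raise ValueError("G x E needs at least 2 sites")
    if (np.diag(vc.sigma_a) < 0).any():
        raise ValueError("negative genetic variance")
    if pair_variance_fn is None:
        def pair_variance_fn(va_i, va_j, cov_ij):
            si, sj = np.sqrt(va_i), np.sqrt(va_j)
            r = cov_ij / (si * sj) if si > 0 and sj > 0 else 0.0
            return (si - sj) ** 2 / 2.0 + si * sj * (1.0 - r)

    vals = [
        pair_variance_fn(vc.sigma_a[i, i], vc.sigma_a[j, j], vc.sigma_a[i, j])
        for i in range(S) for j in range(i + 1, S)
    ]
    gxe = float(np.mean(vals))
    mean_pheno = float(np.mean(np.diag(vc.sigma_a) + vc.r0_diag))
    return gxe, 100.0 * gxe / mean_pheno


def parameter_report(vc: VarianceComponentSet) -> pd.DataFrame:
    """Per-site h2 and per-pair genetic correlations with standard errors."""
    rows = []
    for s in vc.sites:
        h2, se = heritability(vc, s)
        rows.append({"parameter": f"h2[{s}]", "estimate": h2, "se": se})
    S = len(vc.sites)
    for i in range(S):
        for j in range(i + 1, S):
            r, se = genetic_correlation(vc, vc.sites[i], vc.sites[j])
            rows.append({"parameter": f"r_g[{vc.sites[i]},{vc.sites[j]}]",
                         "estimate": r, "se": se})
    gxe, pct = average_gxe_variance(vc) if S > 1 else (np.nan, np.nan)
    rows.append({"parameter": "gxe_variance", "estimate": gxe, "se": np.nan})
    rows.append({"parameter": "gxe_pct_phenotypic", "estimate": pct, "se": np.nan})
    return pd.DataFrame(rows)
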