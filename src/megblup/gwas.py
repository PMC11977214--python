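"""GWAS by back-solving SNP effects from genomic breeding values.

Marker effects are a linear transformation of the GBLUP breeding values:

    g_hat = lambda * W' G^{-1} a_hat_site,   lambda = 1 / (2 sum p_i (1 - p_i)),

with sampling variances

    Var(g_hat_k) = lambda^2 * w_k' G^{-1} Var(a_hat_site) G^{-1} w_k,
    Var(a_hat_site) = G * sigma2_a_site - PEV_site,

where PEV is the site-diagonal block of the coefficient-matrix inverse
from the mixed-model equations.  Two-sided normal p-values follow
p = 2 (1 - Phi(|g_hat| / sd(g_hat))).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import linalg, stats

from megblup.geno import GenomicRelationshipMatrix
from megblup.model import MMEResult, VarianceComponentSet

__all__ = [
    "SignificanceThresholds",
    "OverlapSummary",
    "backsolve_snp_effects",
    "snp_effect_variance",
    "snp_pvalues",
    "make_thresholds",
    "classify_associations",
    "count_association_tests",
    "cross_site_overlap",
    "pvalue_rank_concordance",
    "qq_manhattan_data",
    "site_association_table",
]

TIER_ORDER = ["bonferroni", "suggestive_mid", "suggestive_loose", "none"]


# ---------------------------------------------------------------------------
# Effects and p-values
# ---------------------------------------------------------------------------

def _g_inverse(grm: GenomicRelationshipMatrix) -> np.ndarray:
    try:
        cf = linalg.cho_factor(grm.values, lower=True, check_finite=False)
    except linalg.LinAlgError as exc:
        raise ValueError("GRM not invertible; use a positive blend_weight") from exc
    return linalg.cho_solve(cf, np.eye(grm.n_trees), check_finite=False)


def backsolve_snp_effects(
    bv_site: np.ndarray,
    grm: GenomicRelationshipMatrix,
    W: np.ndarray,
) -> np.ndarray:
    """Per-SNP additive effects back-solved from one site's breeding values.

    ``W`` is the frequency-centered genotype matrix (n x m) the GRM was
    built from; ``bv_site`` the length-n breeding-value vector over all
    trees at that site.
    """
    bv_site = np.asarray(bv_site, dtype=np.float64)
    if W.shape[0] != grm.n_trees or len(bv_site) != grm.n_trees:
        raise ValueError("dimension mismatch between W, GRM and breeding values")
    lam = 1.0 / grm.denom
    Ginv = _g_inverse(grm)
    return lam * (W.T @ (Ginv @ bv_site))


def snp_effect_variance(
    grm: GenomicRelationshipMatrix,
    W: np.ndarray,
    vc: VarianceComponentSet,
    mme: MMEResult,
    site,
) -> np.ndarray:
    """Sampling variance of each back-solved SNP effect at a site.

    Uses Var(a_hat) = G sigma2_a - PEV with the site-diagonal PEV block
    from :func:`megblup.model.solve_mme` (``return_pev=True``).
    Non-positive computed variances are returned as NaN (degenerate or
    numerically improper PEV) so downstream p-values are flagged missing.
    """
    s = vc.site_index(site)
    pev_ss = mme.pev_block(s, s)
    var_a = grm.values * vc.sigma_a[s, s] - pev_ss
    lam = 1.0 / grm.denom
    Ginv = _g_inverse(grm)
    B = Ginv @ var_a @ Ginv
    quad = np.einsum("ik,ij,jk->k", W, B, W, optimize=True)
    var_g = lam**2 * quad
    var_g[var_g <= 0] = np.nan
    return var_g


def snp_pvalues(effects: np.ndarray, variances: np.ndarray) -> np.ndarray:
    """Two-sided normal p-values, p = 2(1 - Phi(|g| / sqrt(Var(g))))."""
    effects = np.asarray(effects, dtype=np.float64)
    variances = np.asarray(variances, dtype=np.float64)
    if (variances[np.isfinite(variances)] <= 0).any():
        raise ValueError("non-positive SNP-effect variance")
    with np.errstate(invalid="ignore"):
        z = np.abs(effects) / np.sqrt(variances)
    p = 2.0 * stats.norm.sf(z)
    return np.where(np.isfinite(z), p, np.nan)


def site_association_table(
    bv_site: np.ndarray,
    grm: GenomicRelationshipMatrix,
    W: np.ndarray,
    snp_ids,
    vc: VarianceComponentSet,
    mme: MMEResult,
    site,
    trait: str = "trait",
) -> pd.DataFrame:
    """Full per-SNP association table (effect, sd, p) for one trait-site."""
    eff = backsolve_snp_effects(bv_site, grm, W)
    var = snp_effect_variance(grm, W, vc, mme, site)
    return pd.DataFrame({
        "snp": np.asarray(snp_ids, dtype=object),
        "trait": trait,
        "site": site,
        "effect": eff,
        "sd": np.sqrt(var),
        "p": snp_pvalues(eff, var),
    })


# ---------------------------------------------------------------------------
# Thresholds and classification
# ---------------------------------------------------------------------------

@dataclass
class SignificanceThresholds:
    """Bonferroni and suggestive p-value cutoffs with -log10 equivalents."""

    n_tests: int
    alpha: float
    bonferroni_p: float
    suggestive_p: tuple
    neg_log10: tuple  # (bonferroni, *suggestive), descending stringency

    @property
    def ordered_p(self) -> list:
        return [self.bonferroni_p, *self.suggestive_p]


def make_thresholds(
    n_tests: int,
    alpha: float = 0.05,
    suggestive_factors=(10, 100),
) -> SignificanceThresholds:
    """Family-wise thresholds: Bonferroni alpha/n plus looser suggestive tiers.

    ``n_tests`` is the number of SNPs (the Bonferroni division is by
    markers, not by marker-trait-site combinations); suggestive cutoffs
    are the Bonferroni p times each factor.
    """
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    bon = alpha / n_tests
    sugg = tuple(bon * f for f in sorted(suggestive_factors))
    p_all = (bon, *sugg)
    if not all(p_all[i] < p_all[i + 1] for i in range(len(p_all) - 1)):
        raise ValueError("thresholds not strictly ordered")
    return SignificanceThresholds(
        n_tests=n_tests,
        alpha=alpha,
        bonferroni_p=bon,
        suggestive_p=sugg,
        neg_log10=tuple(-np.log10(p) for p in p_all),
    )


def classify_associations(
    table: pd.DataFrame,
    thresholds: SignificanceThresholds,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign each SNP-site record its most stringent passed tier.

    Returns the table with a ``tier`` column plus cumulative counts per
    (trait, site, threshold): a Bonferroni hit also counts under every
    looser cutoff, matching how per-cutoff association counts are usually
    tabulated.
    """
    out = table.copy()
    p = out["p"].to_numpy(dtype=np.float64)
    tier = np.full(len(out), "none", dtype=object)
    cuts = thresholds.ordered_p  # most stringent first
    names = TIER_ORDER[: len(cuts)]
    for name, cut in zip(reversed(names), reversed(cuts)):
        tier[np.where(p < cut, True, False)] = name
    out["tier"] = tier
    rows = []
    for (trait, site), grp in out.groupby(["trait", "site"]):
        for name, cut in zip(names, cuts):
            rows.append({
                "trait": trait, "site": site, "threshold_p": cut,
                "tier": name, "n_significant": int((grp["p"] < cut).sum()),
            })
    return out, pd.DataFrame(rows)


def count_association_tests(trait_site_counts, n_snps: int) -> int:
    """Total single-SNP tests: n_snps summed over every trait-site combination.

    ``trait_site_counts`` maps a number of sites to the number of traits
    assessed at that many sites, e.g. ``{3: 12, 2: 18}``.
    """
    combos = sum(n_sites * n_traits for n_sites, n_traits in trait_site_counts.items())
    return int(combos * n_snps)


# ---------------------------------------------------------------------------
# Cross-site overlap and concordance
# ---------------------------------------------------------------------------

@dataclass
class OverlapSummary:
    sites: list
    region_counts: dict  # frozenset of site labels -> count
    n_unique: int
    n_shared_2plus: int


def cross_site_overlap(sig_sets: dict) -> OverlapSummary:
    """Venn partition of per-site significant-SNP sets.

    ``sig_sets`` maps site label -> set of SNP ids.  Region counts cover
    every non-empty site combination; they sum to the union size.
    """
    sites = list(sig_sets)
    universe = set().union(*sig_sets.values()) if sig_sets else set()
    regions: dict = {}
    for r in range(1, len(sites) + 1):
        for combo in combinations(sites, r):
            inside = set(universe)
            for s in combo:
                inside &= sig_sets[s]
            for s in sites:
                if s not in combo:
                    inside -= sig_sets[s]
            regions[frozenset(combo)] = len(inside)
    shared = sum(c for k, c in regions.items() if len(k) >= 2)
    return OverlapSummary(
        sites=sites,
        region_counts=regions,
        n_unique=len(universe),
        n_shared_2plus=shared,
    )


def pvalue_rank_concordance(p_i, p_j) -> float:
    """Spearman rank correlation of two per-SNP p-value vectors (average ranks)."""
    p_i = np.asarray(p_i, dtype=np.float64)
    p_j = np.asarray(p_j, dtype=np.float64)
    if len(p_i) != len(p_j) or len(p_i) < 3:
        raise ValueError("need two equal-length vectors of >= 3 p-values")
    if np.std(p_i) == 0 or np.std(p_j) == 0:
        raise ValueError("constant p-value vector")
    rho, _ = stats.spearmanr(p_i, p_j)
    return float(rho)


# ---------------------------------------------------------------------------
# Plot-ready tables
# ---------------------------------------------------------------------------

def qq_manhattan_data(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """QQ and Manhattan source tables from an association table.

    QQ: observed -log10 p sorted against expected quantiles
    -log10((rank - 0.5) / m).  Manhattan: SNP ordinal index against
    -log10 p (no genome coordinates — markers are unanchored).
    """
    p = table["p"].to_numpy(dtype=np.float64)
    ok = np.isfinite(p)
    obs = np.sort(p[ok])
    m = len(obs)
    ranks = np.arange(1, m + 1)
    qq = pd.DataFrame({
        "expected_neglog10": -np.log10((ranks - 0.5) / m),
        "observed_neglog10": -np.log10(obs),
    }).sort_values("expected_neglog10", ascending=True, ignore_index=True)
    man = pd.DataFrame({
        "snp_index": np.arange(len(table)),
        "snp": table["snp"].to_numpy(dtype=object) if "snp" in table else np.arange(len(table)),
        "neglog10_p": -np.log10(p),
    })
    return qq, man
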