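"""Synthetic open-pollinated multi-site progeny-trial generator.

Emulates the structure of a typical conifer progeny-trial genomic study:
maternal half-sib families from a handful of provenances planted across
a few sites, genotyped at unlinked biallelic SNPs, with per-site additive
variances tied together by an unstructured across-site genetic covariance
(so the genotype-by-environment signal is a controlled input), diagonal
residuals, replication (block) effects within site, and optional
trait-by-site missingness.

Mothers are drawn from Hardy-Weinberg equilibrium at per-SNP allele
frequencies; each offspring combines one maternal gamete with a gamete
from a fresh unrelated pollen parent, so families are maternal half-sib
(expected relatedness 0.25) with no paternal half-sibs.  The genetic
architecture is either a sparse set of QTLs (GWAS power is testable) or
infinitesimal (breeding values drawn directly from Sigma_a (x) G).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from megblup.geno import GenotypeMatrix, compute_grm

__all__ = [
    "SimulationConfig",
    "TruthSet",
    "simulate_population",
    "simulate_phenotypes",
    "write_fixture_set",
    "read_fixture_set",
]


@dataclass
class SimulationConfig:
    """Study design and genetic architecture of one simulated trial.

    Defaults are a desk-scale rendition of a three-site open-pollinated
    program: 30 maternal families from 10 provenances, eight offspring
    per family at sites 1 and 3 and four at site 2 (600 trees), six
    replications per site, 2000 unlinked SNPs with minor-allele
    frequencies uniform on [maf_min, 0.5], 20 QTLs, per-site additive
    variance 0.5 with pairwise genetic correlation 0.8, and residual
    variance 0.5 (h2 = 0.5 per site).
    """

    seed: int
    n_families: int = 30
    n_sites: int = 3
    n_provenances: int = 10
    offspring_per_family_per_site: tuple = (8, 4, 8)
    n_snps: int = 2000
    maf_min: float = 0.05
    n_qtl: int = 20
    sigma2_a: tuple = (0.5, 0.5, 0.5)
    r_g: float = 0.8
    sigma2_e: tuple = (0.5, 0.5, 0.5)
    provenance_sd: float = 0.3
    n_replications: int = 6
    replication_sd: float = 0.3
    site_means: tuple = None
    trait_name: str = "trait1"
    missing_rate_by_site: dict = field(default_factory=dict)
    architecture: str = "qtl"  # or "infinitesimal"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if len(self.offspring_per_family_per_site) != self.n_sites:
            raise ValueError("offspring counts must match n_sites")
        if len(self.sigma2_a) != self.n_sites or len(self.sigma2_e) != self.n_sites:
            raise ValueError("variance tuples must match n_sites")
        if not (0 < self.maf_min <= 0.5):
            raise ValueError("maf_min must be in (0, 0.5]")
        if self.architecture not in ("qtl", "infinitesimal"):
            raise ValueError("architecture must be 'qtl' or 'infinitesimal'")
        if self.site_means is None:
            self.site_means = tuple(float(2 * s) for s in range(self.n_sites))
        eig = np.linalg.eigvalsh(self.sigma_a_target())
        if eig.min() < -1e-10:
            raise ValueError("Sigma_a target not positive semidefinite")

    def sigma_a_target(self) -> np.ndarray:
        sd = np.sqrt(np.asarray(self.sigma2_a, dtype=np.float64))
        R = np.full((self.n_sites, self.n_sites), self.r_g)
        np.fill_diagonal(R, 1.0)
        return np.outer(sd, sd) * R

    @property
    def n_trees(self) -> int:
        return self.n_families * int(sum(self.offspring_per_family_per_site))


@dataclass
class TruthSet:
    """Ground truth of a simulated dataset, recomputable from its parts."""

    tree_ids: np.ndarray
    sites: list
    true_bv: np.ndarray  # S x n true breeding values (all trees, all sites)
    qtl_ids: np.ndarray
    qtl_effects: np.ndarray  # n_qtl x S (empty for infinitesimal)
    provenance_effects: dict
    replication_effects: dict  # (site, replication) -> effect
    realized_h2: dict
    realized_r_g: dict

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s, site in enumerate(self.sites):
            rows.append(pd.DataFrame({
                "tree_id": self.tree_ids, "site": site, "true_bv": self.true_bv[s]}))
        return pd.concat(rows, ignore_index=True)


def _gamete(geno_row: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One meiotic gamete from an unlinked multilocus genotype."""
    g = np.where(geno_row == 1, rng.integers(0, 2, size=geno_row.shape), geno_row // 2)
    return g.astype(np.int64)


def simulate_population(cfg: SimulationConfig):
    """Simulate genotypes and pedigree for the configured trial.

    Returns (GenotypeMatrix with no missing calls, pedigree DataFrame
    with tree_id, family_id, mother_id, provenance_id, site, replication).
    """
    rng = np.random.default_rng(cfg.seed)
    p = rng.uniform(cfg.maf_min, 0.5, size=cfg.n_snps)
    flip = rng.random(cfg.n_snps) < 0.5  # mirror so alt allele is not always minor
    p = np.where(flip, 1.0 - p, p)
    mothers = rng.binomial(2, p, size=(cfg.n_families, cfg.n_snps))
    fam_prov = rng.integers(0, cfg.n_provenances, size=cfg.n_families)
    rows, ped = [], []
    counter = 0
    for fam in range(cfg.n_families):
        for s in range(cfg.n_sites):
            for _ in range(cfg.offspring_per_family_per_site[s]):
                maternal = _gamete(mothers[fam], rng)
                paternal = rng.binomial(1, p)  # gamete of a fresh HWE pollen parent
                rows.append(maternal + paternal)
                tree_id = f"T{counter:05d}"
                ped.append({
                    "tree_id": tree_id,
                    "family_id": f"F{fam:03d}",
                    "mother_id": f"M{fam:03d}",
                    "provenance_id": f"P{fam_prov[fam]:02d}",
                    "site": f"S{s + 1}",
                    "replication": f"R{rng.integers(1, cfg.n_replications + 1)}",
                })
                counter += 1
    calls = np.asarray(rows, dtype=np.float64)
    geno = GenotypeMatrix(
        tree_ids=np.asarray([r["tree_id"] for r in ped], dtype=object),
        snp_ids=np.asarray([f"snp{j:05d}" for j in range(cfg.n_snps)], dtype=object),
        calls=calls,
        missing_mask=np.zeros(calls.shape, dtype=bool),
    )
    return geno, pd.DataFrame(ped)


def simulate_phenotypes(geno: GenotypeMatrix, ped: pd.DataFrame, cfg: SimulationConfig):
    """Simulate one trait's phenotypes with known truth.

    QTL architecture: per-site QTL effect vectors are multivariate normal
    across sites with covariance Sigma_a_target / c, c = sum_q 2 p_q (1 - p_q),
    so realized per-site additive variances and correlations hit the
    target in expectation.  Infinitesimal architecture draws breeding
    values directly from N(0, Sigma_a (x) G).  Phenotype = site mean +
    provenance + replication + BV_site + residual; each tree is observed
    only at its assigned site, with optional extra missingness per site.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    n = geno.n_trees
    S = cfg.n_sites
    sites = [f"S{s + 1}" for s in range(S)]
    sigma_target = cfg.sigma_a_target()
    p_obs = geno.allele_frequencies()
    if cfg.architecture == "qtl":
        qtl_idx = rng.choice(geno.n_snps, size=cfg.n_qtl, replace=False)
        Wq = geno.calls[:, qtl_idx] - 2.0 * p_obs[qtl_idx][None, :]
        c = float(2.0 * (p_obs[qtl_idx] * (1.0 - p_obs[qtl_idx])).sum())
        alpha = rng.multivariate_normal(np.zeros(S), sigma_target / c, size=cfg.n_qtl)
        bv = (Wq @ alpha).T  # S x n
        qtl_ids = geno.snp_ids[qtl_idx]
    else:
        grm = compute_grm(geno, p_obs, blend_weight=0.01)
        chol_G = np.linalg.cholesky(grm.values + 1e-8 * np.eye(n))
        chol_S = np.linalg.cholesky(sigma_target + 1e-10 * np.eye(S))
        bv = chol_S @ rng.standard_normal((S, n)) @ chol_G.T
        qtl_ids, alpha = np.asarray([], dtype=object), np.zeros((0, S))
    prov_levels = sorted(ped["provenance_id"].unique())
    prov_eff = {pr: float(rng.normal(0, cfg.provenance_sd)) for pr in prov_levels}
    rep_eff = {
        (site, f"R{r}"): float(rng.normal(0, cfg.replication_sd))
        for site in sites for r in range(1, cfg.n_replications + 1)
    }
    tree_pos = {t: i for i, t in enumerate(geno.tree_ids)}
    rows = []
    for _, rec in ped.iterrows():
        i = tree_pos[rec["tree_id"]]
        s = sites.index(rec["site"])
        if rng.random() < cfg.missing_rate_by_site.get(rec["site"], 0.0):
            continue
        value = (
            cfg.site_means[s]
            + prov_eff[rec["provenance_id"]]
            + rep_eff[(rec["site"], rec["replication"])]
            + bv[s, i]
            + rng.normal(0, np.sqrt(cfg.sigma2_e[s]))
        )
        rows.append({
            "tree_id": rec["tree_id"],
            "site": rec["site"],
            "provenance": rec["provenance_id"],
            "replication": rec["replication"],
            "family": rec["family_id"],
            "trait": cfg.trait_name,
            "value": value,
        })
    pheno = pd.DataFrame(rows)
    # realized quantities: within the trees actually planted at each site
    site_of_tree = dict(zip(ped["tree_id"], ped["site"]))
    realized_h2, realized_rg = {}, {}
    for s, site in enumerate(sites):
        own = np.array([tree_pos[t] for t, st in site_of_tree.items() if st == site])
        va = float(np.var(bv[s, own], ddof=1))
        realized_h2[site] = va / (va + cfg.sigma2_e[s])
    for i in range(S):
        for j in range(i + 1, S):
            if np.std(bv[i]) > 0 and np.std(bv[j]) > 0:
                realized_rg[(sites[i], sites[j])] = float(np.corrcoef(bv[i], bv[j])[0, 1])
            else:
                realized_rg[(sites[i], sites[j])] = float("nan")
    truth = TruthSet(
        tree_ids=geno.tree_ids,
        sites=sites,
        true_bv=bv,
        qtl_ids=qtl_ids,
        qtl_effects=alpha,
        provenance_effects=prov_eff,
        replication_effects=rep_eff,
        realized_h2=realized_h2,
        realized_r_g=realized_rg,
    )
    return pheno, truth


# ---------------------------------------------------------------------------
# Fixture bundles
# ---------------------------------------------------------------------------

def write_fixture_set(geno, ped, pheno, truth, cfg, outdir) -> dict:
    """Write a plain-text fixture bundle (tsv012 genotypes, pedigree,
    phenotypes, truth, manifest with config and seed)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gdf = pd.DataFrame(geno.calls.astype(np.int64), index=geno.tree_ids, columns=geno.snp_ids)
    gdf = gdf.astype(object).where(~geno.missing_mask, "NA")
    gdf.index.name = "tree_id"
    paths = {
        "genotypes": outdir / "genotypes.tsv",
        "pedigree": outdir / "pedigree.tsv",
        "phenotypes": outdir / "phenotypes.tsv",
        "truth": outdir / "truth.tsv",
        "manifest": outdir / "manifest.json",
    }
    gdf.to_csv(paths["genotypes"], sep="\t")
    ped.to_csv(paths["pedigree"], sep="\t", index=False)
    pheno.to_csv(paths["phenotypes"], sep="\t", index=False)
    truth.to_frame().to_csv(paths["truth"], sep="\t", index=False)
    manifest = {"config": asdict(cfg)}
    manifest["config"]["missing_rate_by_site"] = dict(cfg.missing_rate_by_site)
    paths["manifest"].write_text(json.dumps(manifest, indent=2, default=str))
    return {k: str(v) for k, v in paths.items()}


def read_fixture_set(outdir):
    """Read back a fixture bundle written by :func:`write_fixture_set`."""
    from megblup.geno import read_genotype_matrix, read_pedigree

    outdir = Path(outdir)
    geno = read_genotype_matrix(outdir / "genotypes.tsv", format="tsv012")
    ped = read_pedigree(outdir / "pedigree.tsv")
    pheno = pd.read_csv(outdir / "phenotypes.tsv", sep="\t")
    truth = pd.read_csv(outdir / "truth.tsv", sep="\t")
    manifest = json.loads((outdir / "manifest.json").read_text())
    return geno, ped, pheno, truth, manifest
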