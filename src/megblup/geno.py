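"""Genotype ingestion, filtering, imputation and genomic relationships.

SNP calls are coded additively as the count of the alternative allele
(0, 1, 2).  The realized genomic relationship matrix follows VanRaden's
first method,

    G = W W' / (2 * sum_i p_i (1 - p_i)),    W = M - 2p,

with allele frequencies taken from the observed (pre-imputation) calls of
the analyzed cohort.  Monomorphic loci contribute a zero column to W and
are excluded from the denominator so they never produce 0/0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "GenomicRelationshipMatrix",
    "PedigreeConflictReport",
    "VariantFilterLog",
    "LDSummary",
    "read_genotype_matrix",
    "read_pedigree",
    "filter_variants",
    "mean_impute",
    "compute_grm",
    "verify_pedigree",
    "pairwise_ld",
]


@dataclass
class GenotypeMatrix:
    """Trees x SNPs additive genotype calls with a missingness mask.

    ``calls`` is float64; before imputation every non-missing entry is one
    of {0, 1, 2}, after mean imputation entries may be any real in [0, 2]
    (``imputed`` is then True and the mask is all-False).
    """

    tree_ids: np.ndarray
    snp_ids: np.ndarray
    calls: np.ndarray
    missing_mask: np.ndarray
    imputed: bool = False

    def __post_init__(self) -> None:
        self.tree_ids = np.asarray(self.tree_ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.calls = np.asarray(self.calls, dtype=np.float64)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n, m = self.calls.shape
        if self.missing_mask.shape != (n, m):
            raise ValueError("calls and missing_mask dimensions disagree")
        if len(self.tree_ids) != n or len(self.snp_ids) != m:
            raise ValueError("id vectors do not match call matrix dimensions")
        if len(set(self.tree_ids)) != n:
            raise ValueError("duplicate tree ids")
        if len(set(self.snp_ids)) != m:
            raise ValueError("duplicate SNP ids")
        obs = self.calls[~self.missing_mask]
        if not self.imputed and obs.size and not np.isin(obs, (0.0, 1.0, 2.0)).all():
            bad = obs[~np.isin(obs, (0.0, 1.0, 2.0))]
            raise ValueError(f"invalid genotype code(s) outside {{0,1,2}}: {bad[:5]}")
        if self.imputed and obs.size and (obs.min() < 0 or obs.max() > 2):
            raise ValueError("imputed calls outside [0, 2]")

    @property
    def n_trees(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """Alternative-allele frequency per SNP from non-missing calls only."""
        calls = np.where(self.missing_mask, np.nan, self.calls)
        n_obs = (~self.missing_mask).sum(axis=0)
        if (n_obs == 0).any():
            raise ValueError("SNP with zero non-missing calls")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(calls, axis=0) / 2.0


@dataclass
class GenomicRelationshipMatrix:
    """n x n realized relationship matrix with its VanRaden scaling constant."""

    tree_ids: np.ndarray
    values: np.ndarray
    blend_weight: float
    denom: float

    def __post_init__(self) -> None:
        self.tree_ids = np.asarray(self.tree_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.tree_ids)
        if self.values.shape != (n, n):
            raise ValueError("GRM shape does not match tree ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("GRM is not symmetric")
        if not (0 <= self.blend_weight < 1):
            raise ValueError("blend_weight must be in [0, 1)")

    @property
    def n_trees(self) -> int:
        return len(self.tree_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.tree_ids, columns=self.tree_ids)


@dataclass
class VariantFilterLog:
    n_input: int
    n_dropped_missing: int
    n_dropped_mac: int
    n_retained: int


@dataclass
class PedigreeConflictReport:
    """Pairwise relationship conflicts against half-sib expectations."""

    pairs: pd.DataFrame  # tree_a, tree_b, expected, observed_g, deviation, flag
    removed_tree_ids: list = field(default_factory=list)

    @property
    def n_flagged(self) -> int:
        return int(self.pairs["flag"].sum())

    def retained_ids(self, all_ids) -> list:
        removed = set(self.removed_tree_ids)
        return [t for t in all_ids if t not in removed]


@dataclass
class LDSummary:
    pairs: pd.DataFrame  # snp_a, snp_b, r2 (NaN when undefined)
    count_pairs: int
    count_above: int
    fraction_above: float


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_genotype_matrix(
    path,
    format: str = "tsv012",
    missing: str = "NA",
    strict: bool = True,
) -> GenotypeMatrix:
    """Read a genotype matrix from a tsv012 table or a VCF.

    tsv012: header row of SNP ids, first column tree id, cells in
    {0, 1, 2, NA}.  VCF: biallelic SNP records via cyvcf2; multi-allelic
    records raise under ``strict`` and are skipped otherwise; ``./.``
    genotypes map to missing.
    """
    if format == "tsv012":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        raw = df.to_numpy(dtype=object)
        mask = np.vectorize(lambda v: pd.isna(v) or str(v) == missing)(raw) if raw.size else np.zeros(raw.shape, bool)
        calls = np.zeros(raw.shape, dtype=np.float64)
        obs = ~mask
        if obs.any():
            try:
                vals = raw[obs].astype(np.float64)
            except ValueError as exc:
                raise ValueError(f"non-numeric genotype code in {path}: {exc}") from exc
            calls[obs] = vals
        return GenotypeMatrix(
            tree_ids=df.index.to_numpy(dtype=object),
            snp_ids=df.columns.to_numpy(dtype=object),
            calls=calls,
            missing_mask=mask,
        )
    if format == "vcf":
        return _read_vcf(path, strict=strict)
    raise ValueError(f"unknown genotype format: {format!r}")


def _read_vcf(path, strict: bool = True) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snp_ids, rows = [], []
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            if strict:
                raise ValueError(f"non-biallelic-SNP record at {rec.CHROM}:{rec.POS}")
            continue
        snp_ids.append(rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}")
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = rec.gt_types
        row = np.where(gt == 3, 2.0, np.where(gt == 2, np.nan, gt.astype(np.float64)))
        rows.append(row)
    calls = np.column_stack(rows) if rows else np.zeros((len(samples), 0))
    mask = np.isnan(calls)
    calls = np.nan_to_num(calls)
    return GenotypeMatrix(
        tree_ids=np.asarray(samples, dtype=object),
        snp_ids=np.asarray(snp_ids, dtype=object),
        calls=calls,
        missing_mask=mask,
    )


def read_pedigree(path) -> pd.DataFrame:
    """Read a pedigree TSV with columns tree_id, family_id[, mother_id, provenance_id]."""
    ped = pd.read_csv(path, sep="\t", dtype=str)
    if "tree_id" not in ped.columns or "family_id" not in ped.columns:
        raise ValueError("pedigree must have tree_id and family_id columns")
    if ped["tree_id"].duplicated().any():
        raise ValueError("duplicate tree_id in pedigree")
    if ped["family_id"].isna().any() or (ped["family_id"] == "").any():
        raise ValueError("empty family_id in pedigree")
    return ped


# ---------------------------------------------------------------------------
# Filtering and imputation
# ---------------------------------------------------------------------------

def filter_variants(
    g: GenotypeMatrix,
    max_missing_rate: float = 0.30,
    min_mac: int = 1,
) -> tuple[GenotypeMatrix, VariantFilterLog]:
    """Drop SNPs by per-SNP missingness and minor-allele count.

    Retains SNPs with missing fraction <= ``max_missing_rate`` and minor
    allele count >= ``min_mac``; the defaults (0.30, 1) also drop every
    monomorphic locus.
    """
    if not (0 <= max_missing_rate <= 1):
        raise ValueError("max_missing_rate must be in [0, 1]")
    if min_mac < 0:
        raise ValueError("min_mac must be >= 0")
    miss_rate = g.missing_mask.mean(axis=0)
    obs = np.where(g.missing_mask, 0.0, g.calls)
    n_obs = (~g.missing_mask).sum(axis=0)
    alt_count = obs.sum(axis=0)
    mac = np.minimum(alt_count, 2 * n_obs - alt_count)
    pass_miss = miss_rate <= max_missing_rate
    pass_mac = mac >= min_mac
    keep = pass_miss & pass_mac
    log = VariantFilterLog(
        n_input=g.n_snps,
        n_dropped_missing=int((~pass_miss).sum()),
        n_dropped_mac=int((pass_miss & ~pass_mac).sum()),
        n_retained=int(keep.sum()),
    )
    if log.n_retained == 0:
        warnings.warn("all SNPs removed by variant filters", UserWarning)
    out = GenotypeMatrix(
        tree_ids=g.tree_ids,
        snp_ids=g.snp_ids[keep],
        calls=g.calls[:, keep],
        missing_mask=g.missing_mask[:, keep],
        imputed=g.imputed,
    )
    return out, log


def mean_impute(g: GenotypeMatrix) -> tuple[GenotypeMatrix, np.ndarray]:
    """Replace missing calls with the per-SNP mean of observed calls.

    Returns the imputed matrix and the allele-frequency vector p computed
    from the observed calls before imputation.
    """
    p = g.allele_frequencies()
    col_mean = 2.0 * p
    calls = np.where(g.missing_mask, col_mean[None, :], g.calls)
    out = GenotypeMatrix(
        tree_ids=g.tree_ids,
        snp_ids=g.snp_ids,
        calls=calls,
        missing_mask=np.zeros_like(g.missing_mask),
        imputed=True,
    )
    return out, p


# ---------------------------------------------------------------------------
# Genomic relationship matrix
# ---------------------------------------------------------------------------

def centered_genotypes(g: GenotypeMatrix, p: np.ndarray) -> np.ndarray:
    """W = M - 2p, the frequency-centered genotype matrix."""
    if g.missing_mask.any():
        raise ValueError("genotypes must be imputed before centering")
    return g.calls - 2.0 * np.asarray(p, dtype=np.float64)[None, :]


def vanraden_denominator(p: np.ndarray) -> float:
    """2 * sum p_i (1 - p_i) over polymorphic SNPs."""
    p = np.asarray(p, dtype=np.float64)
    poly = (p > 0) & (p < 1)
    return float(2.0 * (p[poly] * (1.0 - p[poly])).sum())


def compute_grm(
    g: GenotypeMatrix,
    p: np.ndarray | None = None,
    blend_weight: float = 0.01,
) -> GenomicRelationshipMatrix:
    """VanRaden genomic relationship matrix, optionally identity-blended.

    The raw matrix W W' / denom is blended as (1 - w) G + w I so that the
    result is safely invertible for the mixed-model equations (the raw G
    is singular whenever n exceeds the marker rank or trees duplicate).
    """
    if g.missing_mask.any():
        raise ValueError("GRM requires imputed (no-missing) genotypes")
    if p is None:
        p = g.allele_frequencies()
    denom = vanraden_denominator(p)
    if denom == 0.0:
        raise ValueError("all SNPs monomorphic: VanRaden denominator is zero")
    W = centered_genotypes(g, p)
    G = (W @ W.T) / denom
    if blend_weight > 0:
        G = (1.0 - blend_weight) * G + blend_weight * np.eye(g.n_trees)
    G = (G + G.T) / 2.0
    return GenomicRelationshipMatrix(
        tree_ids=g.tree_ids, values=G, blend_weight=blend_weight, denom=denom
    )


# ---------------------------------------------------------------------------
# Pedigree-conflict screening
# ---------------------------------------------------------------------------

def verify_pedigree(
    grm: GenomicRelationshipMatrix,
    ped: pd.DataFrame,
    halfsib_expect: float = 0.25,
    deviation_tol: float = 0.15,
) -> PedigreeConflictReport:
    """Flag GRM entries that contradict the recorded half-sib structure.

    Same-family pairs are expected near ``halfsib_expect`` (0.25 for
    maternal half-sibs), cross-family pairs near 0.  Pairs deviating by
    more than ``deviation_tol`` are flagged, and a greedy removal set is
    built by repeatedly dropping the tree involved in the most remaining
    conflicts (ties broken by id for determinism).
    """
    fam = dict(zip(ped["tree_id"], ped["family_id"]))
    missing = [t for t in grm.tree_ids if t not in fam]
    if missing:
        raise ValueError(f"trees present in GRM but absent from pedigree: {missing[:5]}")
    ids = grm.tree_ids
    n = len(ids)
    iu, ju = np.triu_indices(n, k=1)
    observed = grm.values[iu, ju]
    fam_arr = np.asarray([fam[t] for t in ids], dtype=object)
    same = fam_arr[iu] == fam_arr[ju]
    expected = np.where(same, halfsib_expect, 0.0)
    deviation = observed - expected
    flag = np.abs(deviation) > deviation_tol
    pairs = pd.DataFrame(
        {
            "tree_a": ids[iu],
            "tree_b": ids[ju],
            "expected_relationship": expected,
            "observed_g": observed,
            "deviation": deviation,
            "flag": flag,
        }
    )
    removed: list = []
    live = pairs.loc[pairs["flag"], ["tree_a", "tree_b"]].copy()
    while len(live):
        counts: dict = {}
        for col in ("tree_a", "tree_b"):
            for t, c in live[col].value_counts().items():
                counts[t] = counts.get(t, 0) + c
        worst = sorted(counts.items(), key=lambda kv: (-kv[1], str(kv[0])))[0][0]
        removed.append(worst)
        live = live[(live["tree_a"] != worst) & (live["tree_b"] != worst)]
    return PedigreeConflictReport(pairs=pairs, removed_tree_ids=removed)


# ---------------------------------------------------------------------------
# Linkage disequilibrium
# ---------------------------------------------------------------------------

def pairwise_ld(
    g: GenotypeMatrix,
    snp_subset=None,
    r2_threshold: float = 0.90,
    keep_pairs: bool = True,
) -> LDSummary:
    """Pairwise r-squared (squared Pearson correlation of additive codes).

    A subset SNP with zero variance yields NaN r2 for its pairs; those
    pairs still count in ``count_pairs`` but never in ``count_above``.
    """
    if g.missing_mask.any():
        raise ValueError("LD requires imputed genotypes")
    if snp_subset is None:
        snp_subset = g.snp_ids
    idx = {s: j for j, s in enumerate(g.snp_ids)}
    cols = [idx[s] for s in snp_subset]
    if len(cols) < 2:
        raise ValueError("need at least 2 SNPs for pairwise LD")
    X = g.calls[:, cols]
    sd = X.std(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        Xc = (X - X.mean(axis=0)) / np.where(sd == 0, np.nan, sd)
        R = (Xc.T @ Xc) / X.shape[0]
    r2 = R**2
    k = len(cols)
    iu, ju = np.triu_indices(k, k=1)
    vals = r2[iu, ju]
    count_pairs = k * (k - 1) // 2
    count_above = int(np.nansum(vals > r2_threshold))
    pairs = (
        pd.DataFrame(
            {
                "snp_a": np.asarray(snp_subset, dtype=object)[iu],
                "snp_b": np.asarray(snp_subset, dtype=object)[ju],
                "r2": vals,
            }
        )
        if keep_pairs
        else pd.DataFrame(columns=["snp_a", "snp_b", "r2"])
    )
    return LDSummary(
        pairs=pairs,
        count_pairs=count_pairs,
        count_above=count_above,
        fraction_above=count_above / count_pairs,
    )
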