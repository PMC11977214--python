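"""K-fold cross-validated genomic prediction.

Folds partition the phenotyped trees; in each fold the validation trees'
phenotypes are masked, the mixed-model equations are re-solved at the
full-data variance components, and the masked trees' breeding values at
their own site are recorded.  Predictive ability is the Pearson
correlation between full-data and validation breeding values divided by
sqrt(h2) of the trait-site; prediction (dispersion) bias is the slope of
the full-data values regressed on the validation predictions, 1 meaning
no bias.  Across-site differences are assessed by one-way ANOVA over
fold replicates followed by Tukey's HSD with a compact letter display.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from megblup.model import ModelSpec, VarianceComponentSet, solve_mme, heritability

__all__ = [
    "FoldAssignment",
    "make_folds",
    "cv_predict",
    "predictive_ability",
    "prediction_bias",
    "site_comparison",
    "run_crossval",
]


@dataclass
class FoldAssignment:
    k: int
    seed: int
    tree_ids: np.ndarray
    fold_of: np.ndarray  # fold index per tree, aligned with tree_ids

    def fold_members(self, f: int) -> np.ndarray:
        return self.tree_ids[self.fold_of == f]


def make_folds(tree_ids, k: int = 10, seed: int = 0) -> FoldAssignment:
    """Uniformly random balanced partition of trees into k folds.

    Fold sizes differ by at most one; the assignment is a pure function
    of (tree set, k, seed).
    """
    tree_ids = np.asarray(tree_ids, dtype=object)
    n = len(tree_ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError("more folds than trees")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fold_of = np.empty(n, dtype=np.intp)
    fold_of[order] = np.arange(n) % k
    return FoldAssignment(k=k, seed=seed, tree_ids=tree_ids, fold_of=fold_of)


def cv_predict(
    spec: ModelSpec,
    vc_full: VarianceComponentSet,
    folds: FoldAssignment,
    mask_validation: bool = True,
) -> pd.DataFrame:
    """Validation breeding values per tree at its own site.

    Variance components stay fixed at the full-data estimates across
    folds.  Returns one row per phenotyped tree: tree_id, site, fold,
    bv_cv.  ``mask_validation=False`` is a debugging switch that skips
    the masking (predictions then equal the full-data solutions).
    """
    rows = []
    fold_lookup = dict(zip(folds.tree_ids, folds.fold_of))
    rec_fold = np.array([fold_lookup.get(t, -1) for t in spec.record_tree_ids])
    if (rec_fold < 0).any():
        raise ValueError("phenotyped tree missing from fold assignment")
    for f in range(folds.k):
        val_mask = rec_fold == f
        train = spec.subset(~val_mask) if mask_validation else spec
        if train.X.shape[1] < spec.X.shape[1]:
            warnings.warn(
                f"fold {f}: fixed-effect level emptied by masking; level dropped",
                UserWarning,
            )
        mme = solve_mme(train, vc_full)
        for i in np.flatnonzero(val_mask):
            s = spec.site_idx[i]
            rows.append({
                "tree_id": spec.record_tree_ids[i],
                "site": spec.sites[s],
                "fold": f,
                "bv_cv": mme.breeding_values[s, spec.tree_idx[i]],
            })
    return pd.DataFrame(rows)


def predictive_ability(
    a_full: np.ndarray,
    a_cv: np.ndarray,
    h2: float,
    adjust: str = "divide",
) -> float:
    """Predictive ability: cor(full-data BV, validation BV) / sqrt(h2).

    Division by sqrt(h2) is the Legarra-style accuracy adjustment and the
    default; ``adjust='multiply'`` is available for sensitivity analysis.
    The adjusted value may exceed 1 and is deliberately not clipped.
    """
    a_full = np.asarray(a_full, dtype=np.float64)
    a_cv = np.asarray(a_cv, dtype=np.float64)
    if len(a_full) < 3:
        raise ValueError("need >= 3 validation trees")
    if np.std(a_full) == 0 or np.std(a_cv) == 0:
        raise ValueError("zero variance in breeding-value vector")
    if h2 <= 0:
        raise ValueError("h2 must be positive")
    r = float(np.corrcoef(a_full, a_cv)[0, 1])
    if adjust == "divide":
        return r / np.sqrt(h2)
    if adjust == "multiply":
        return r * np.sqrt(h2)
    raise ValueError("adjust must be 'divide' or 'multiply'")


def prediction_bias(a_full: np.ndarray, a_cv: np.ndarray) -> float:
    """Dispersion bias: OLS slope of full-data BVs on validation BVs."""
    a_full = np.asarray(a_full, dtype=np.float64)
    a_cv = np.asarray(a_cv, dtype=np.float64)
    if len(a_full) < 3:
        raise ValueError("need >= 3 validation trees")
    v = np.var(a_cv)
    if v == 0:
        raise ValueError("zero variance in validation predictions")
    return float(np.cov(a_full, a_cv)[0, 1] / np.var(a_cv, ddof=1))


def run_crossval(
    spec: ModelSpec,
    vc_full: VarianceComponentSet,
    folds: FoldAssignment,
    trait: str = "trait",
    adjust: str = "divide",
) -> pd.DataFrame:
    """Per-fold per-site predictive ability and bias for one trait.

    Solves the full-data MME once for the reference breeding values, then
    each fold's masked MME; yields k replicates per trait-site for the
    downstream ANOVA/Tukey site comparison.
    """
    mme_full = solve_mme(spec, vc_full)
    full_bv = {}
    for i in range(spec.n_records):
        s = spec.site_idx[i]
        full_bv[spec.record_tree_ids[i]] = (s, mme_full.breeding_values[s, spec.tree_idx[i]])
    cv = cv_predict(spec, vc_full, folds)
    rows = []
    for (site, fold), grp in cv.groupby(["site", "fold"]):
        af = np.array([full_bv[t][1] for t in grp["tree_id"]])
        ac = grp["bv_cv"].to_numpy(dtype=np.float64)
        if len(af) < 3 or np.std(af) == 0 or np.std(ac) == 0:
            continue
        h2, _ = heritability(vc_full, site)
        rows.append({
            "trait": trait,
            "site": site,
            "fold": fold,
            "pa": predictive_ability(af, ac, h2, adjust=adjust),
            "pb": prediction_bias(af, ac),
            "n_validation": len(af),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ANOVA + Tukey site comparison
# ---------------------------------------------------------------------------

def _compact_letters(groups, not_different: set) -> dict:
    """Insert-and-absorb compact letter display.

    ``not_different`` holds unordered pairs that share a letter.  Greedy
    construction: each group joins every letter column it is compatible
    with, new columns open when needed.
    """
    columns: list[set] = []
    for g in groups:
        placed = False
        for col in columns:
            if all(frozenset((g, other)) in not_different for other in col):
                col.add(g)
                placed = True
        if not placed:
            columns.append({g})
    # absorb columns fully contained in another
    columns = [c for i, c in enumerate(columns)
               if not any(i != j and c < d for j, d in enumerate(columns))]
    letters = {g: "" for g in groups}
    for col, letter in zip(columns, "abcdefghijklmnopqrstuvwxyz"):
        for g in sorted(col, key=str):
            letters[g] += letter
    return {g: "".join(sorted(v)) for g, v in letters.items()}


def site_comparison(
    values: pd.DataFrame,
    value_col: str = "pa",
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One-way ANOVA across sites plus Tukey HSD letter groupings.

    ``values`` has columns site and ``value_col`` with fold-level
    replicates.  Returns (anova table, per-site summary with Tukey
    letters — sites sharing a letter do not differ at ``alpha``).
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    sites = sorted(values["site"].unique(), key=str)
    if len(sites) < 2:
        raise ValueError("need >= 2 sites")
    samples = [values.loc[values["site"] == s, value_col].to_numpy(dtype=np.float64)
               for s in sites]
    if any(len(x) < 2 for x in samples):
        raise ValueError("every site needs >= 2 replicates")
    F, p = stats.f_oneway(*samples)
    anova = pd.DataFrame([{
        "F": float(F), "p": float(p),
        "df_between": len(sites) - 1,
        "df_within": sum(len(x) for x in samples) - len(sites),
    }])
    if all(np.allclose(x, samples[0].mean()) for x in samples):
        letters = {s: "a" for s in sites}  # no variation at all
    else:
        tuk = pairwise_tukeyhsd(
            values[value_col].to_numpy(dtype=np.float64),
            values["site"].astype(str).to_numpy(),
            alpha=alpha,
        )
        res = pd.DataFrame(tuk.summary().data[1:], columns=tuk.summary().data[0])
        not_diff = {
            frozenset((str(r["group1"]), str(r["group2"])))
            for _, r in res.iterrows() if not bool(r["reject"])
        }
        letters = _compact_letters([str(s) for s in sites], not_diff)
    summary = pd.DataFrame([{
        "site": s,
        "mean": float(np.mean(x)),
        "sd": float(np.std(x, ddof=1)),
        "n": len(x),
        "letters": letters[str(s)],
    } for s, x in zip(sites, samples)])
    return anova, summary
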