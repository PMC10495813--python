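"""Trait tables, scaling, phenotypic distances, and the phylogeny-phenotype
distance correlation.

A trait table is a strain-by-trait :class:`pandas.DataFrame` of quantitative
phenotypes (growth efficiencies, wine physicochemical parameters, ...) with
``NaN`` for missing measurements.  Distances between strains are Euclidean
distances over centred-and-scaled trait values; their correlation with
cophenetic distance summarises how much of the phenotypic variation tracks
the phylogeny.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "read_trait_table",
    "write_trait_table",
    "scale_traits",
    "trait_distance_matrix",
    "distance_correlation",
]

MISSING = "NA"


def read_trait_table(path) -> pd.DataFrame:
    """Read a strain-by-trait TSV (row-label column ``strain_id``, missing = NA)."""
    df = pd.read_csv(path, sep="\t", na_values=[MISSING], keep_default_na=True)
    if "strain_id" not in df.columns:
        raise ValueError("trait table must have a 'strain_id' column")
    df = df.set_index("strain_id")
    return df.astype(float)


def write_trait_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", na_rep=MISSING, index_label="strain_id")


def scale_traits(table: pd.DataFrame, min_obs: int = 3) -> pd.DataFrame:
    """Centre and scale each trait column to mean 0 and sample (n-1) SD 1
    over its non-missing entries.

    Columns that are constant (zero sample SD) or have fewer than
    ``min_obs`` non-missing values cannot be scaled and are dropped with a
    warning — degenerate traits should not silently poison distances.
    Missing entries stay missing.  The operation is idempotent.
    """
    kept = {}
    dropped = []
    for col in table.columns:
        x = table[col]
        n = x.notna().sum()
        sd = x.std(ddof=1)
        if n < min_obs or not np.isfinite(sd) or sd == 0:
            dropped.append(col)
            continue
        kept[col] = (x - x.mean()) / sd
    if dropped:
        warnings.warn(f"dropped unscalable trait columns: {dropped}", stacklevel=2)
    return pd.DataFrame(kept, index=table.index)


def trait_distance_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Euclidean phenotypic distance between strains.

    Uses pairwise-complete traits, rescaled by ``sqrt(p_total / p_shared)``
    so distances remain comparable between pairs with different amounts of
    missing data.  A pair sharing fewer than 2 traits gets a missing
    distance (with a warning).
    """
    X = table.to_numpy(dtype=float)
    n, p = X.shape
    obs = np.isfinite(X)
    D = np.zeros((n, n))
    few = []
    for i in range(n):
        for j in range(i + 1, n):
            shared = obs[i] & obs[j]
            k = int(shared.sum())
            if k < 2:
                D[i, j] = D[j, i] = np.nan
                few.append((table.index[i], table.index[j]))
                continue
            diff = X[i, shared] - X[j, shared]
            D[i, j] = D[j, i] = np.sqrt((diff @ diff) * p / k)
    if few:
        warnings.warn(f"pairs sharing <2 traits left missing: {few}", stacklevel=2)
    return pd.DataFrame(D, index=table.index, columns=table.index)


def _upper_triangle(d: pd.DataFrame) -> np.ndarray:
    a = d.to_numpy(dtype=float)
    iu = np.triu_indices(a.shape[0], k=1)
    return a[iu]


def distance_correlation(
    d_phylo: pd.DataFrame,
    d_pheno: pd.DataFrame,
    n_perm: int = 999,
    seed: int | None = None,
) -> dict:
    """Pearson correlation between two distance matrices over tip pairs.

    Returns ``r`` with two p-values: ``p_naive`` from the standard
    correlation test on the upper-triangle pairs (what a plain ``cor.test``
    reports, ignoring the non-independence of pairs sharing a strain), and
    ``p_mantel`` from a one-sided Mantel permutation test that permutes the
    strain labels of one matrix ``n_perm`` times.
    """
    if list(d_phylo.index) != list(d_pheno.index):
        common = sorted(set(d_phylo.index) & set(d_pheno.index))
        if len(common) < 3:
            raise ValueError("matrices share fewer than 3 labels")
        d_phylo = d_phylo.loc[common, common]
        d_pheno = d_pheno.loc[common, common]
    x = _upper_triangle(d_phylo)
    y = _upper_triangle(d_pheno)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant distance vector: correlation undefined")
    r, p_naive = stats.pearsonr(x, y)

    p_mantel = np.nan
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        a = d_phylo.to_numpy()
        n = a.shape[0]
        iu = np.triu_indices(n, k=1)
        yv = d_pheno.to_numpy()[iu]
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            xv = a[np.ix_(perm, perm)][iu]
            m = np.isfinite(xv) & np.isfinite(yv)
            r_perm = stats.pearsonr(xv[m], yv[m])[0]
            if r_perm >= r:
                hits += 1
        p_mantel = (1 + hits) / (1 + n_perm)
    return {"r": float(r), "p_naive": float(p_naive), "p_mantel": float(p_mantel), "n_pairs": int(ok.sum())}
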