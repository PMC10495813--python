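"""Phylogenetic imputation of missing trait values under Brownian motion.

A tip with an unobserved trait is predicted as the conditional expectation of
the Gaussian trait model on the tree given the observed tips — equivalently,
rerooting the phylogeny at the missing tip's attachment point and taking the
maximum-likelihood ancestral state.  With C the Brownian covariance,
partitioned into observed (o) and missing (m) tips:

    mu_hat   = (1' C_oo^-1 x_o) / (1' C_oo^-1 1)            (GLS root state)
    x_hat_m  = mu_hat + C_mo C_oo^-1 (x_o - mu_hat 1)
    var_m    = s2 * [ (C_mm - C_mo C_oo^-1 C_om)_diag
                      + (1 - C_mo C_oo^-1 1)^2 / (1' C_oo^-1 1) ]

where the second variance term propagates the uncertainty of the estimated
root state (universal-kriging correction).

Cross-validated accuracy is measured by leave-one-out prediction at four
taxonomic exclusion radii: remove only the focal strain itself, or also its
identical-marker group, conspecifics, or congeners, mimicking prediction of
progressively less-sampled newcomers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .signal import lambda_transform
from .tree import Phylogeny, bm_covariance, cophenetic_matrix, pnnd

__all__ = [
    "ImputationResult",
    "impute_tips",
    "loocv_impute",
    "accuracy_vs_signal",
    "derive_marker_groups",
    "EXCLUSION_LEVELS",
]

logger = logging.getLogger(__name__)

EXCLUSION_LEVELS = ("strain", "marker", "species", "genus")


@dataclass
class ImputationResult:
    predictions: pd.DataFrame
    variances: pd.DataFrame
    exclusion_level: str
    per_trait_r: pd.Series = field(default=None)
    per_strain_error: pd.Series = field(default=None)


def _conditional_gaussian(C: np.ndarray, obs_idx, mis_idx, x_obs: np.ndarray):
    Coo = C[np.ix_(obs_idx, obs_idx)]
    Cmo = C[np.ix_(mis_idx, obs_idx)]
    Cmm = np.diag(C)[mis_idx]
    n_o = len(obs_idx)
    ridge = 0.0
    for _ in range(2):
        try:
            cf = linalg.cho_factor(Coo + ridge * np.eye(n_o), lower=True)
            break
        except linalg.LinAlgError:
            ridge = 1e-10 * float(np.diag(C).max())
            logger.debug("near-singular observed covariance; ridge %.3g added", ridge)
    ones = np.ones(n_o)
    Ci1 = linalg.cho_solve(cf, ones)
    Cix = linalg.cho_solve(cf, x_obs)
    denom = ones @ Ci1
    mu = (ones @ Cix) / denom
    r = x_obs - mu
    sigma2 = (r @ linalg.cho_solve(cf, r)) / n_o
    W = linalg.cho_solve(cf, Cmo.T)        # C_oo^-1 C_om, (n_o, n_m)
    point = mu + Cmo @ linalg.cho_solve(cf, r)
    cond_var = Cmm - np.einsum("mo,om->m", Cmo, W)
    mean_term = (1.0 - Cmo @ Ci1) ** 2 / denom
    var = sigma2 * (np.maximum(cond_var, 0.0) + mean_term)
    return point, var, mu, sigma2


def impute_tips(
    tree: Phylogeny, x: pd.Series, lam: float = 1.0
) -> tuple[pd.Series, pd.Series]:
    """Predict missing tip values of one trait from the observed tips.

    ``x`` is indexed by tip label with NaN marking missing tips; tips absent
    from ``x`` are also treated as missing.  ``lam`` optionally plugs a
    Pagel's-lambda transform into the covariance (default 1: pure Brownian).
    Returns point estimates and predictive variances for the missing tips.
    """
    C = bm_covariance(tree)
    if lam != 1.0:
        C = lambda_transform(C, lam)
    labels = list(C.index)
    x = x.reindex(labels)
    obs = np.flatnonzero(x.notna().to_numpy())
    mis = np.flatnonzero(x.isna().to_numpy())
    if len(obs) < 1:
        raise ValueError("no observed tips to impute from")
    if len(mis) == 0:
        empty = pd.Series(dtype=float)
        return empty, empty
    if len(obs) == 1:
        # single observation: the GLS mean is that value, rate unidentifiable
        only = float(x.iloc[obs[0]])
        mlabels = [labels[i] for i in mis]
        return (
            pd.Series(only, index=mlabels),
            pd.Series(np.nan, index=mlabels),
        )
    point, var, _, _ = _conditional_gaussian(
        C.to_numpy(), obs, mis, x.iloc[obs].to_numpy(dtype=float)
    )
    mlabels = [labels[i] for i in mis]
    return pd.Series(point, index=mlabels), pd.Series(var, index=mlabels)


def derive_marker_groups(tree: Phylogeny, tol: float = 1e-9) -> pd.Series:
    """Group tips at zero cophenetic distance (identical marker sequences).

    Connected components of the graph joining tips whose patristic distance
    is below ``tol * height``; used when strain metadata lacks an explicit
    marker-identity column.
    """
    d = cophenetic_matrix(tree).to_numpy()
    thr = tol * max(tree.height, np.finfo(float).tiny)
    n = len(tree.tips)
    group = -np.ones(n, dtype=int)
    g = 0
    for i in range(n):
        if group[i] >= 0:
            continue
        stack = [i]
        group[i] = g
        while stack:
            k = stack.pop()
            for j in np.flatnonzero(d[k] <= thr):
                if group[j] < 0:
                    group[j] = g
                    stack.append(int(j))
        g += 1
    return pd.Series([f"m{k}" for k in group], index=tree.tips, name="marker_group")


def _excluded(metadata: pd.DataFrame, focal: str, level: str) -> set[str]:
    if level == "strain":
        return {focal}
    col = {"marker": "marker_group", "species": "species", "genus": "genus"}[level]
    return set(metadata.index[metadata[col] == metadata.loc[focal, col]]) | {focal}


def loocv_impute(
    tree: Phylogeny,
    traits: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
    exclusion_level: str = "strain",
    lam: float = 1.0,
) -> ImputationResult:
    """Leave-one-out cross-validated imputation at a taxonomic exclusion radius.

    For each focal strain, all strains in its exclusion set (itself; or its
    marker group / species / genus) are dropped from the observed set before
    predicting each of its traits.  Accuracy is summarised per trait as the
    Pearson correlation between predicted and observed (unscaled) values, and
    per strain as the mean absolute error in per-trait SD units.
    """
    if exclusion_level not in EXCLUSION_LEVELS:
        raise ValueError(f"exclusion_level must be one of {EXCLUSION_LEVELS}")
    C = bm_covariance(tree)
    if lam != 1.0:
        C = lambda_transform(C, lam)
    labels = [l for l in C.index if l in traits.index]
    Cm = C.loc[labels, labels].to_numpy()
    X = traits.reindex(labels)
    if exclusion_level != "strain":
        if metadata is None:
            raise ValueError("metadata required for taxonomic exclusion levels")
        metadata = metadata.reindex(labels)
        if "marker_group" not in metadata.columns:
            metadata = metadata.join(derive_marker_groups(tree))
    pred = pd.DataFrame(np.nan, index=labels, columns=traits.columns)
    var = pd.DataFrame(np.nan, index=labels, columns=traits.columns)
    pos = {l: i for i, l in enumerate(labels)}
    for focal in labels:
        if exclusion_level == "strain":
            dropped = {focal}
        else:
            dropped = _excluded(metadata, focal, exclusion_level)
        base = [l for l in labels if l not in dropped]
        if len(base) == len(labels) - 1 and len(base) < 2:
            logger.warning("focal %s: exclusion leaves <2 strains", focal)
        fi = pos[focal]
        for col in traits.columns:
            xcol = X[col]
            if pd.isna(xcol.loc[focal]):
                continue
            obs_labels = [l for l in base if pd.notna(xcol.loc[l])]
            if len(obs_labels) < 2:
                logger.warning(
                    "focal %s trait %s: exclusion leaves <2 observed strains; skipped",
                    focal, col,
                )
                continue
            oi = [pos[l] for l in obs_labels]
            p, v, _, _ = _conditional_gaussian(
                Cm, oi, [fi], xcol.loc[obs_labels].to_numpy(dtype=float)
            )
            pred.loc[focal, col] = p[0]
            var.loc[focal, col] = v[0]

    per_trait_r = {}
    for col in traits.columns:
        ok = pred[col].notna() & X[col].notna()
        if ok.sum() >= 3 and X[col][ok].std() > 0 and pred[col][ok].std() > 0:
            per_trait_r[col] = float(stats.pearsonr(pred[col][ok], X[col][ok])[0])
        else:
            per_trait_r[col] = np.nan
    sds = X.std(ddof=1)
    scaled_err = (pred - X).abs() / sds
    per_strain_error = scaled_err.mean(axis=1, skipna=True)
    return ImputationResult(
        predictions=pred,
        variances=var,
        exclusion_level=exclusion_level,
        per_trait_r=pd.Series(per_trait_r, name="pearson_r"),
        per_strain_error=per_strain_error.rename("mean_abs_scaled_error"),
    )


def accuracy_vs_signal(
    signal: pd.DataFrame, imputation: ImputationResult, tree: Phylogeny | None = None
) -> dict:
    """Pair per-trait signal strength with imputation accuracy.

    Returns the per-trait (lambda, r) table with their Pearson correlation;
    if a tree is supplied, also pairs each strain's phylogenetic
    nearest-neighbour distance with its imputation error.
    """
    sig = signal.set_index("trait")["lambda"] if "trait" in signal.columns else signal["lambda"]
    common = sig.index.intersection(imputation.per_trait_r.index)
    if len(common) == 0:
        raise ValueError("signal and imputation cover disjoint trait sets")
    pairs = pd.DataFrame(
        {"lambda": sig.loc[common], "r": imputation.per_trait_r.loc[common]}
    ).dropna()
    if len(pairs) < 2:
        raise ValueError("need at least 2 traits to correlate signal with accuracy")
    if pairs["lambda"].std() == 0 or pairs["r"].std() == 0:
        corr = np.nan
    else:
        corr = float(stats.pearsonr(pairs["lambda"], pairs["r"])[0])
    out = {"per_trait": pairs, "signal_accuracy_r": corr}
    if tree is not None:
        nnd = pnnd(tree)
        strains = nnd.index.intersection(imputation.per_strain_error.dropna().index)
        sp = pd.DataFrame(
            {"pnnd": nnd.loc[strains], "error": imputation.per_strain_error.loc[strains]}
        ).dropna()
        out["per_strain"] = sp
        if len(sp) >= 2 and sp["pnnd"].std() > 0 and sp["error"].std() > 0:
            out["pnnd_error_r"] = float(stats.pearsonr(sp["pnnd"], sp["error"])[0])
        else:
            out["pnnd_error_r"] = np.nan
    return out
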