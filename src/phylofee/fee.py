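"""Functional effect equations (FEEs) and community-function landscape prediction.

The measured function F of a consortium is the fraction of fermentable
sugars it consumes, in [0, 1].  The functional effect of strain i on a
background community B is dF_i(B) = F(B + i) - F(B), and the FEE links it
linearly to the background's function:

    dF_i(B) = a_i + b_i * F(B) + theta_i(B)

with per-strain intercept a_i, slope b_i and residual theta.  Concatenating
FEEs along chains of single-strain additions predicts the function of an
unmeasured target community from any measured sub-community; the residuals
are resolved jointly by weighted least squares over the subset lattice
between the best observed anchor c0 and the target, which makes the
prediction independent of the order in which strains are "added".

The additive baseline ignores the background dependence entirely:
F_A = F_Sc + sum of pairwise effects against a focal strain.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from math import sqrt

import numpy as np
import pandas as pd

__all__ = [
    "Community",
    "CommunityDataset",
    "FEEParams",
    "PredictionResult",
    "community_function",
    "functional_effect",
    "fit_fee",
    "fit_all_fees",
    "predict_function",
    "additive_predict",
    "additive_from_dataset",
    "evaluate_predictions",
    "write_fees",
    "read_fees",
]

SIGMA2_FLOOR = 1e-4  # on the [0,1] function scale; keeps edge weights finite

Community = tuple[str, ...]  # canonical form: sorted tuple of strain ids


def key_str(members) -> str:
    """String form of a community's canonical identity: ';'-joined sorted ids."""
    return ";".join(canon(members))


def canon(members) -> Community:
    """Canonical identity of a community: sorted tuple of unique strain ids."""
    if isinstance(members, str):
        members = [m for m in members.split(";") if m]
    lst = list(members)
    ms = tuple(sorted(set(lst)))
    if len(ms) != len(lst):
        raise ValueError(f"duplicate members in community: {lst}")
    return ms


def community_function(initial_sugars: float, residual_sugars: float) -> float:
    """Fraction of sugars consumed: (initial - residual) / initial, clipped to [0, 1].

    A residual slightly above the initial concentration (within 5%) is
    treated as measurement noise and clipped to 0; beyond that it is an
    assay inconsistency.
    """
    if residual_sugars > initial_sugars * 1.05:
        raise ValueError(
            f"residual sugars {residual_sugars} exceed initial {initial_sugars} by >5%"
        )
    return float(np.clip((initial_sugars - residual_sugars) / initial_sugars, 0.0, 1.0))


class CommunityDataset:
    """Replicate measurements of community function, keyed by composition.

    The empty community is always present with F = 0 (un-inoculated medium
    consumes nothing); it anchors monoculture effects dF_i(empty) = F({i}).
    """

    def __init__(self, measurements: pd.DataFrame):
        req = {"members", "replicate", "F"}
        if not req.issubset(measurements.columns):
            raise ValueError(f"measurement table needs columns {sorted(req)}")
        df = measurements.copy()
        if not df["F"].between(-1e-9, 1 + 1e-9).all():
            bad = df.loc[~df["F"].between(-1e-9, 1 + 1e-9), "F"]
            raise ValueError(f"function values outside [0,1]: {bad.tolist()[:5]}")
        df["F"] = df["F"].clip(0.0, 1.0)
        df["key"] = df["members"].map(canon)
        self.df = df
        agg = df.groupby("key")["F"].agg(["mean", "std", "count"])
        self._mean = agg["mean"].to_dict()
        self._sd = agg["std"].to_dict()
        self._n = agg["count"].to_dict()
        self._mean.setdefault((), 0.0)
        self._sd.setdefault((), 0.0)
        self._n.setdefault((), 1)

    @classmethod
    def from_records(cls, records: list[tuple]) -> "CommunityDataset":
        """records: iterable of (members, replicate, F) with members an iterable of ids."""
        rows = [
            {"members": ";".join(sorted(set(m))), "replicate": rep, "F": f}
            for m, rep, f in records
        ]
        return cls(pd.DataFrame(rows, columns=["members", "replicate", "F"]))

    @classmethod
    def read_csv(cls, path) -> "CommunityDataset":
        df = pd.read_csv(path, keep_default_na=False)
        df["F"] = df["F"].astype(float)
        return cls(df)

    def to_csv(self, path) -> None:
        cols = [c for c in ("community_id", "members", "replicate", "F") if c in self.df.columns]
        self.df[cols].to_csv(path, index=False)

    @property
    def communities(self) -> list[Community]:
        return sorted(self._mean, key=lambda k: (len(k), k))

    def is_measured(self, members) -> bool:
        return canon(members) in self._mean

    def mean_F(self, members) -> float:
        key = canon(members)
        if key not in self._mean:
            raise KeyError(f"community {key} not measured")
        return float(self._mean[key])

    def sd_F(self, members) -> float:
        v = self._sd[canon(members)]
        return 0.0 if pd.isna(v) else float(v)

    def n_replicates(self, members) -> int:
        return int(self._n[canon(members)])

    @property
    def strains(self) -> list[str]:
        out = set()
        for key in self._mean:
            out.update(key)
        return sorted(out)


@dataclass
class FEEParams:
    strain_id: str
    a: float
    b: float
    sigma2: float
    n_points: int
    r2: float
    residuals: pd.DataFrame | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "strain_id": self.strain_id, "a": self.a, "b": self.b,
            "sigma2": self.sigma2, "n_points": self.n_points, "r2": self.r2,
        }


@dataclass
class PredictionResult:
    target: Community
    F_pred: float
    F_pred_raw: float
    lattice_nodes: int
    anchors: list[Community]
    clipped: bool


def functional_effect(
    dataset: CommunityDataset, strain: str, background
) -> tuple[float, float]:
    """dF_i(B) = mean F(B + i) - mean F(B), with independent-sample SD propagation."""
    bg = canon(background)
    if strain in bg:
        raise ValueError(f"strain {strain} already in background {bg}")
    aug = canon(bg + (strain,))
    if not dataset.is_measured(bg) or not dataset.is_measured(aug):
        raise KeyError(f"both {bg} and {aug} must be measured")
    dF = dataset.mean_F(aug) - dataset.mean_F(bg)
    sd = sqrt(
        dataset.sd_F(aug) ** 2 / dataset.n_replicates(aug)
        + dataset.sd_F(bg) ** 2 / dataset.n_replicates(bg)
    )
    return float(dF), float(sd)


def _fee_pairs(dataset: CommunityDataset, strain: str) -> pd.DataFrame:
    rows = []
    measured = set(dataset.communities)
    for aug in measured:
        if strain not in aug:
            continue
        bg = tuple(s for s in aug if s != strain)
        if bg in measured or bg == ():
            rows.append(
                {
                    "background": bg,
                    "F_B": dataset.mean_F(bg),
                    "dF": dataset.mean_F(aug) - dataset.mean_F(bg),
                }
            )
    return pd.DataFrame(rows, columns=["background", "F_B", "dF"])


def fit_fee(dataset: CommunityDataset, strain: str) -> FEEParams:
    """Ordinary least squares of dF_i(B) on F(B) over all measured (B, B+i) pairs.

    Replicates enter through their means; sigma2 = SSR / (n - 2) with a small
    floor so zero-residual fits cannot give infinite lattice edge weights.
    """
    pairs = _fee_pairs(dataset, strain)
    n = len(pairs)
    if n < 3:
        raise ValueError(f"strain {strain}: only {n} background pairs, need >= 3")
    x = pairs["F_B"].to_numpy()
    y = pairs["dF"].to_numpy()
    if np.ptp(x) == 0:
        raise ValueError(f"strain {strain}: degenerate design, no variance in F(B)")
    A = np.column_stack([np.ones(n), x])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    a, b = float(coef[0]), float(coef[1])
    resid = y - (a + b * x)
    ssr = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ssr / sst if sst > 0 else np.nan
    sigma2 = max(ssr / (n - 2), SIGMA2_FLOOR)
    pairs = pairs.assign(residual=resid)
    return FEEParams(strain, a, b, sigma2, n, r2, residuals=pairs)


def fit_all_fees(dataset: CommunityDataset, strains=None) -> dict[str, FEEParams]:
    """Fit a FEE for every strain (or the given subset); unfittable strains are skipped
    with their error recorded under ``fit_all_fees.failures``."""
    strains = strains if strains is not None else dataset.strains
    fees: dict[str, FEEParams] = {}
    failures: dict[str, str] = {}
    for s in strains:
        try:
            fees[s] = fit_fee(dataset, s)
        except ValueError as exc:
            failures[s] = str(exc)
    fit_all_fees.failures = failures
    return fees


def write_fees(fees: dict[str, FEEParams], path) -> None:
    with open(path, "w") as fh:
        json.dump([fees[s].to_dict() for s in sorted(fees)], fh, indent=2)


def read_fees(path) -> dict[str, FEEParams]:
    with open(path) as fh:
        data = json.load(fh)
    return {
        d["strain_id"]: FEEParams(
            d["strain_id"], d["a"], d["b"], d["sigma2"], d["n_points"], d["r2"]
        )
        for d in data
    }


def _observed_subsets(dataset: CommunityDataset, target: Community) -> list[Community]:
    tset = set(target)
    return [c for c in dataset.communities if set(c) <= tset]


def predict_function(
    target,
    dataset: CommunityDataset,
    fees: dict[str, FEEParams],
    scope: str = "interval",
) -> PredictionResult:
    """Predict the function of a target community by lattice-WLS FEE concatenation.

    Nodes are all communities S with c0 <= S <= target (c0 = the largest
    observed subset; ties broken by replicate count, then lexicographically)
    plus every other observed subset of the target (``scope='powerset'``
    instead uses every subset of the target).  Each single-addition edge
    (S, S + i) contributes the FEE identity F(S+i) = F(S) + a_i + b_i F(S)
    weighted by 1/sigma_i; observed nodes are fixed at their replicate
    means, the empty community at 0, and the latent node values solve the
    sparse weighted least-squares system.  The result is invariant to member
    ordering and node enumeration order, and reduces to the closed-form
    single-addition chain when only one strain is missing.
    """
    t = canon(target)
    if dataset.is_measured(t):
        f = dataset.mean_F(t)
        return PredictionResult(t, f, f, 1, [t], clipped=False)

    observed = _observed_subsets(dataset, t)  # always contains ()
    # c0: largest observed subset; ties -> most replicates, then lexicographic
    max_size = max(len(c) for c in observed)
    best = [c for c in observed if len(c) == max_size]
    best_n = max(dataset.n_replicates(c) for c in best)
    c0 = min(c for c in best if dataset.n_replicates(c) == best_n)

    missing = [s for s in t if s not in c0]
    for s in missing:
        if s not in fees:
            raise ValueError(f"strain {s} has no fitted FEE; cannot bridge to target")

    if scope == "interval":
        nodes = {canon(c0 + tuple(sub)) for r in range(len(missing) + 1)
                 for sub in combinations(missing, r)}
        nodes |= set(observed)
    elif scope == "powerset":
        nodes = {canon(sub) for r in range(len(t) + 1) for sub in combinations(t, r)}
    else:
        raise ValueError("scope must be 'interval' or 'powerset'")

    node_list = sorted(nodes, key=lambda k: (len(k), k))
    obs_set = set(observed)
    fixed = {c: dataset.mean_F(c) for c in node_list if c in obs_set}
    latent = [c for c in node_list if c not in obs_set]
    idx = {c: i for i, c in enumerate(latent)}

    rows, rhs = [], []
    node_set = set(node_list)
    for S in node_list:
        sset = set(S)
        for strain, fee in fees.items():
            if strain in sset:
                continue
            Sp = canon(S + (strain,))
            if Sp not in node_set:
                continue
            w = 1.0 / sqrt(fee.sigma2)
            row = np.zeros(len(latent))
            const = fee.a * w
            # equation: F(S+i) - (1+b_i) F(S) = a_i, weighted by 1/sigma_i
            if Sp in fixed:
                const -= fixed[Sp] * w
            else:
                row[idx[Sp]] += w
            if S in fixed:
                const += (1.0 + fee.b) * fixed[S] * w
            else:
                row[idx[S]] -= (1.0 + fee.b) * w
            if Sp in fixed and S in fixed:
                continue  # both ends observed: nothing to solve
            rows.append(row)
            rhs.append(const)
    if latent:
        A = np.array(rows)
        bvec = np.array(rhs)
        sol, *_ = np.linalg.lstsq(A, bvec, rcond=None)
        values = dict(fixed)
        values.update({c: float(sol[i]) for c, i in idx.items()})
    else:
        values = dict(fixed)
    raw = values[t]
    pred = float(np.clip(raw, 0.0, 1.0))
    return PredictionResult(
        target=t, F_pred=pred, F_pred_raw=float(raw),
        lattice_nodes=len(node_list), anchors=sorted(fixed, key=lambda k: (len(k), k)),
        clipped=pred != raw,
    )


def additive_predict(
    added_strains, f_focal: float, pairwise_effects: dict[str, float]
) -> tuple[float, float]:
    """Additive baseline: F_A = F_Sc + sum of the added strains' pairwise effects.

    Returns (clipped, raw); missing pairwise effects are an error.
    """
    total = f_focal
    for s in set(added_strains):
        if s not in pairwise_effects:
            raise KeyError(f"no pairwise effect for strain {s}")
        total += pairwise_effects[s]
    return float(np.clip(total, 0.0, 1.0)), float(total)


def additive_from_dataset(
    dataset: CommunityDataset, target, focal: str
) -> tuple[float, float]:
    """Additive prediction of a community containing the focal strain, using its
    monoculture function and its pairwise co-culture effects from the dataset."""
    t = canon(target)
    if focal not in t:
        raise ValueError(f"focal strain {focal} not in target {t}")
    f_focal = dataset.mean_F((focal,))
    effects = {}
    for s in t:
        if s == focal:
            continue
        effects[s], _ = functional_effect(dataset, s, (focal,))
    return additive_predict([s for s in t if s != focal], f_focal, effects)


def evaluate_predictions(
    predictions: pd.Series, observations: pd.Series, group_by_richness: bool = True
) -> dict:
    """Accuracy of community-function predictions.

    ``predictions`` and ``observations`` are indexed by canonical community
    tuples.  Reports overall Pearson r and RMSE, per-community squared and
    absolute errors, and per-richness RMSE when requested.
    """
    common = predictions.index.intersection(observations.index)
    if len(common) == 0:
        raise ValueError("no communities in common between predictions and observations")
    p = predictions.loc[common].astype(float)
    o = observations.loc[common].astype(float)
    err = p - o
    rmse = float(np.sqrt((err**2).mean()))
    if len(common) >= 2 and p.std() > 0 and o.std() > 0:
        r = float(np.corrcoef(p, o)[0, 1])
    else:
        r = np.nan
    per_comm = pd.DataFrame(
        {
            "F_pred": p, "F_obs": o,
            "squared_error": err**2, "abs_error": err.abs(),
            "richness": [len(canon(c)) for c in common],
        }
    )
    out = {"r": r, "rmse": rmse, "n": int(len(common)), "per_community": per_comm}
    if group_by_richness:
        out["rmse_by_richness"] = per_comm.groupby("richness")["squared_error"].mean().pow(0.5)
    return out
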