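"""Synthetic data with the statistical structure the analyses assume.

Three generators:

* pure-birth (Yule) ultrametric trees, height scaled to 1, standing in for
  a marker-gene chronogram of a strain collection;
* trait tables drawn from MVN(mu, sigma2 * C(lambda)) with per-trait
  Pagel's lambda, emulating a ~60-strain x 43-trait phenotyping campaign;
* community-function experiments over a 12-strain pool (10 background
  strains plus 2 focal fermenters) whose ground truth is a
  permutation-symmetric functional-effect-equation landscape: the true
  function of a community is the average of the FEE recursion over all of
  its single-removal parents, plus lattice noise tau, observed in
  triplicate with measurement noise eps.

Every generator is deterministic given its seed; the generating parameters
are returned as a SyntheticTruth so recovery tests can compare estimates
with the truth.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .fee import Community, CommunityDataset, canon
from .signal import lambda_transform
from .tree import Phylogeny, bm_covariance, cophenetic_matrix, read_newick_string

__all__ = [
    "SyntheticTruth",
    "simulate_yule_tree",
    "simulate_bm_traits",
    "simulate_collection",
    "simulate_community_experiment",
    "sample_validation_communities",
    "DEFAULT_TRUTH_RANGES",
]

# Per-strain (a, b) draws span the qualitative strain classes seen in
# wine-yeast consortia, all within a in [-0.1, 1.0], b in [-1.2, 0.2]:
# mildly positive strains that consume some sugar, strongly negative strains
# that stall fermentation, and Sc-like strong fermenters that push the
# community towards completion.  sigma is the per-strain FEE residual scale.
DEFAULT_TRUTH_RANGES = {
    "positive": {"a": (0.10, 0.35), "b": (-0.5, 0.0), "sigma": (0.01, 0.1)},
    "negative": {"a": (-0.10, 0.05), "b": (-1.2, -0.6), "sigma": (0.01, 0.1)},
    "sc_like": {"a": (0.80, 0.95), "b": (-1.0, -0.8), "sigma": (0.01, 0.05)},
}


def simulate_yule_tree(n_tips: int, seed: int, height: float = 1.0) -> Phylogeny:
    """Ultrametric pure-birth tree with ``n_tips`` extant tips, total height
    rescaled to ``height``; tips labelled s001, s002, ... deterministically.

    The process runs one exponential waiting time beyond the last speciation
    before the present is fixed, so terminal branches have positive length
    (a chronogram never places a split exactly at the present).
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    t = 0.0
    left = {"tb": 0.0, "split": None}
    right = {"tb": 0.0, "split": None}
    active = [left, right]
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        k = int(rng.integers(len(active)))
        parent = active.pop(k)
        c1 = {"tb": t, "split": None}
        c2 = {"tb": t, "split": None}
        parent["split"] = (t, c1, c2)
        active.extend([c1, c2])
    # one more waiting time before fixing the present, so the youngest
    # cherry gets positive pendant branches
    t += rng.exponential(1.0 / len(active))

    counter = {"k": 0}

    def render(lin) -> str:
        if lin["split"] is None:
            counter["k"] += 1
            return f"s{counter['k']:03d}:{t - lin['tb']:.17g}"
        t_split, c1, c2 = lin["split"]
        return f"({render(c1)},{render(c2)}):{t_split - lin['tb']:.17g}"

    newick = f"({render(left)},{render(right)});"
    phylo = read_newick_string(newick)
    scale = height / phylo.height
    for node in phylo.tree.preorder_node_iter():
        if node.edge.length is not None:
            node.edge.length *= scale
    return Phylogeny(phylo.tree)


def _chol(C: np.ndarray) -> np.ndarray:
    jitter = 0.0
    for _ in range(3):
        try:
            return np.linalg.cholesky(C + jitter * np.eye(len(C)))
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10, 1e-10 * float(np.diag(C).max()))
    raise np.linalg.LinAlgError("covariance not positive definite")


def simulate_bm_traits(
    tree: Phylogeny,
    lam: float = 1.0,
    sigma2: float = 1.0,
    mu: float = 0.0,
    n_traits: int = 1,
    seed: int | None = None,
    names: list[str] | None = None,
) -> pd.DataFrame:
    """Draw trait columns from MVN(mu, sigma2 * C(lambda)) on the tree's tips."""
    C = lambda_transform(bm_covariance(tree), lam)
    rng = np.random.default_rng(seed)
    L = _chol(sigma2 * C.to_numpy()) if sigma2 > 0 else None
    n = tree.n_tips
    Z = rng.standard_normal((n, n_traits))
    X = mu + (L @ Z if L is not None else np.zeros((n, n_traits)))
    cols = names or [f"trait_{k + 1:02d}" for k in range(n_traits)]
    return pd.DataFrame(X, index=tree.tips, columns=cols)


def _clades_at(d: np.ndarray, threshold: float) -> np.ndarray:
    """Single-linkage components of tips within cophenetic distance threshold
    (on an ultrametric tree these are exactly the clades cut at that depth)."""
    if threshold <= 0:
        # exact-duplicate grouping
        lab = -np.ones(len(d), dtype=int)
        g = 0
        for i in range(len(d)):
            if lab[i] < 0:
                lab[d[i] <= 1e-12] = g
                g += 1
        return lab
    Z = linkage(squareform(d, checks=False), method="single")
    return fcluster(Z, t=threshold, criterion="distance")


@dataclass
class SyntheticTruth:
    """Generating parameters of a synthetic dataset, kept for recovery tests."""

    seed: int
    trait_lambda: pd.Series | None = None
    trait_sigma2: float = 1.0
    trait_mu: float = 0.0
    fee_a: dict[str, float] = field(default_factory=dict)
    fee_b: dict[str, float] = field(default_factory=dict)
    fee_sigma: dict[str, float] = field(default_factory=dict)
    tau: float = 0.0
    eps: float = 0.0
    n_replicates: int = 3
    per_strain_noise: bool = False
    _lattice: dict[Community, float] = field(default_factory=dict)
    n_clipped: int = 0

    def true_F(self, members) -> float:
        """Ground-truth function of a community.

        Built bottom-up by the permutation-symmetric FEE recursion: the
        average over every single-removal parent S\\{i} of
        (1 + b_i) F*(S\\{i}) + a_i, plus N(0, tau^2) lattice noise, clipped
        to [0, 1].  Noise is keyed to the composition (not to evaluation
        order), so any community's truth is reproducible on demand.
        """
        key = canon(members)
        if key == ():
            return 0.0
        if key in self._lattice:
            return self._lattice[key]
        parents = [self.true_F(tuple(s for s in key if s != i)) for i in key]
        rng = np.random.default_rng(
            [self.seed & 0x7FFFFFFF, zlib.crc32(";".join(key).encode())]
        )
        terms = []
        for i, fp in zip(key, parents):
            t = (1.0 + self.fee_b[i]) * fp + self.fee_a[i]
            if self.per_strain_noise:
                t += rng.normal(0.0, self.fee_sigma[i])
            terms.append(t)
        raw = float(np.mean(terms)) + (rng.normal(0.0, self.tau) if self.tau > 0 else 0.0)
        val = float(np.clip(raw, 0.0, 1.0))
        if val != raw:
            self.n_clipped += 1
        self._lattice[key] = val
        return val

    def measure(self, members, assay_tag: str = "") -> list[float]:
        """Replicate observations: true_F plus N(0, eps^2), clipped to [0, 1]."""
        f = self.true_F(members)
        key = ";".join(canon(members)) + "|" + assay_tag
        rng = np.random.default_rng(
            [self.seed & 0x7FFFFFFF, 0x5EED, zlib.crc32(key.encode())]
        )
        return [
            float(np.clip(f + (rng.normal(0.0, self.eps) if self.eps > 0 else 0.0), 0, 1))
            for _ in range(self.n_replicates)
        ]


def simulate_collection(
    n_strains: int = 60,
    n_traits: int = 43,
    lambda_grid=None,
    seed: int = 0,
    sigma2: float = 1.0,
    mu: float = 0.0,
    missing_rate: float = 0.0,
    marker_depth: float = 0.025,
    species_depth: float = 0.175,
    genus_depth: float = 0.45,
) -> tuple[Phylogeny, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Tree + trait table + strain metadata emulating a phenotyped collection.

    Per-trait lambda is drawn from ``lambda_grid`` (default 0, 0.1, ..., 1).
    Metadata assigns marker_group, species and genus by cutting the
    ultrametric tree at fixed depths below the tips (defaults 0.025, 0.175
    and 0.45 on a height-1 tree), so the three partitions are nested.
    """
    if n_strains < 2 or n_traits < 1:
        raise ValueError("need >= 2 strains and >= 1 trait")
    if lambda_grid is None:
        lambda_grid = np.round(np.linspace(0.0, 1.0, 11), 2)
    rng = np.random.default_rng(seed)
    tree = simulate_yule_tree(n_strains, seed=seed)
    lams = pd.Series(
        rng.choice(np.asarray(lambda_grid, dtype=float), size=n_traits),
        index=[f"trait_{k + 1:02d}" for k in range(n_traits)],
        name="lambda",
    )
    cols = {}
    for k, (name, lam) in enumerate(lams.items()):
        cols[name] = simulate_bm_traits(
            tree, lam=float(lam), sigma2=sigma2, mu=mu, n_traits=1,
            seed=int(rng.integers(2**31 - 1)), names=[name],
        )[name]
    traits = pd.DataFrame(cols, index=tree.tips)
    if missing_rate > 0:
        mask = rng.random(traits.shape) < missing_rate
        traits = traits.mask(mask)
    d = cophenetic_matrix(tree).to_numpy()
    meta = pd.DataFrame(index=pd.Index(tree.tips, name="strain_id"))
    # a clade cut at depth t below the tips joins tips within cophenetic 2t
    meta["marker_group"] = [f"m{g:02d}" for g in _clades_at(d, 2 * marker_depth)]
    meta["species"] = [f"sp{g:02d}" for g in _clades_at(d, 2 * species_depth)]
    meta["genus"] = [f"g{g:02d}" for g in _clades_at(d, 2 * genus_depth)]
    truth = SyntheticTruth(seed=seed, trait_lambda=lams, trait_sigma2=sigma2, trait_mu=mu)
    return tree, traits, meta, truth


def _deal_backgrounds(
    pool: list[str], sizes: list[int], rng: np.random.Generator
) -> list[tuple[str, ...]]:
    """Deal strain ids into backgrounds of the given sizes by greedy
    minimum-usage selection: each background takes the ``size`` least-used
    strains, ties broken by a fresh shuffle.  A strain is only incremented
    while it is among the least-used, so final usage counts differ by at
    most 1 across the pool and no background contains duplicates."""
    counts = {s: 0 for s in pool}
    out = []
    for size in sizes:
        order = list(pool)
        rng.shuffle(order)
        order.sort(key=lambda s: counts[s])  # stable: ties keep shuffled order
        chunk = order[:size]
        for s in chunk:
            counts[s] += 1
        out.append(tuple(sorted(chunk)))
    return out


def prevalence_spread(backgrounds: list[tuple[str, ...]], pool: list[str]) -> float:
    """(max - min) / max of per-strain membership counts across backgrounds."""
    counts = np.array([sum(s in b for b in backgrounds) for s in pool], dtype=float)
    return float((counts.max() - counts.min()) / counts.max())


def simulate_community_experiment(
    strains: list[str] | None = None,
    truth_params: dict | None = None,
    n_base_backgrounds: int = 16,
    base_sizes: tuple[int, ...] = (2, 3, 4, 5),
    tau: float = 0.01,
    eps: float = 0.01,
    n_replicates: int = 3,
    seed: int = 0,
    per_strain_noise: bool = False,
) -> tuple[CommunityDataset, SyntheticTruth]:
    """Simulate the consortium experiment design over a 12-strain pool.

    The first ``len(strains) - 2`` ids form the background pool and the last
    two are focal fermenter strains.  Base backgrounds (sizes cycling through
    ``base_sizes``) are dealt with balanced per-strain prevalence (spread
    <= 20%); each pool strain is then added to each base background, giving
    16 + 16*10 = 176 backgrounds of 2-6 members.  Every background is
    assayed alone and with each focal strain (3 inoculation schemes, 528
    assays), plus all monocultures and pairwise co-cultures, in replicate.
    """
    if strains is None:
        strains = [f"ns{k:02d}" for k in range(1, 11)] + ["sc01", "sc02"]
    pool, focals = list(strains[:-2]), list(strains[-2:])
    rng = np.random.default_rng(seed)
    if truth_params is None:
        # half the pool mildly positive, half strongly negative (mirroring a
        # 5-up / 5-down strain selection); focal strains are strong fermenters
        truth_params = {}
        for k, s in enumerate(pool):
            cls = "positive" if k < len(pool) // 2 else "negative"
            r = DEFAULT_TRUTH_RANGES[cls]
            truth_params[s] = (
                float(rng.uniform(*r["a"])),
                float(rng.uniform(*r["b"])),
                float(rng.uniform(*r["sigma"])),
            )
        for f in focals:
            r = DEFAULT_TRUTH_RANGES["sc_like"]
            truth_params[f] = (
                float(rng.uniform(*r["a"])),
                float(rng.uniform(*r["b"])),
                float(rng.uniform(*r["sigma"])),
            )
    for s, (a, b, sg) in truth_params.items():
        if b <= -2:
            raise ValueError(f"strain {s}: slope {b} <= -2 makes the recursion unstable")
    truth = SyntheticTruth(
        seed=seed,
        fee_a={s: v[0] for s, v in truth_params.items()},
        fee_b={s: v[1] for s, v in truth_params.items()},
        fee_sigma={s: v[2] for s, v in truth_params.items()},
        tau=tau, eps=eps, n_replicates=n_replicates,
        per_strain_noise=per_strain_noise,
    )

    sizes = [base_sizes[k % len(base_sizes)] for k in range(n_base_backgrounds)]
    if max(sizes) > len(pool):
        raise ValueError("background size exceeds strain pool")
    base = _deal_backgrounds(pool, sizes, rng)
    backgrounds: list[tuple[str, ...]] = list(base)
    for b in base:
        for s in pool:
            backgrounds.append(tuple(sorted(set(b) | {s})))

    compositions: list[tuple[tuple[str, ...], str]] = []
    for k, b in enumerate(backgrounds):
        compositions.append((b, f"bg{k:03d}"))
        for f in focals:
            compositions.append((tuple(sorted(b + (f,))), f"bg{k:03d}+{f}"))
    for s in strains:
        compositions.append(((s,), f"mono:{s}"))
    for pair in combinations(strains, 2):
        compositions.append((tuple(sorted(pair)), "pair:" + ";".join(sorted(pair))))

    rows = []
    for members, tag in compositions:
        for rep, f in enumerate(truth.measure(members, assay_tag=tag), start=1):
            rows.append(
                {
                    "community_id": tag,
                    "members": ";".join(members),
                    "replicate": rep,
                    "F": round(f, 6),
                }
            )
    dataset = CommunityDataset(pd.DataFrame(rows))
    return dataset, truth


def sample_validation_communities(
    truth: SyntheticTruth,
    dataset: CommunityDataset,
    pool: list[str],
    focal: str | None = None,
    n: int = 120,
    sizes: tuple[int, ...] = (2, 3, 4, 5, 6),
    seed: int = 0,
    exclude_measured: bool = True,
) -> pd.Series:
    """Draw held-out communities (optionally containing a focal strain) and
    return their ground-truth function, indexed by canonical composition."""
    rng = np.random.default_rng(seed)
    measured = set(dataset.communities)
    out: dict[Community, float] = {}
    attempts = 0
    while len(out) < n and attempts < 50 * n:
        attempts += 1
        size = int(rng.choice(sizes))
        members = list(rng.choice(pool, size=size, replace=False))
        if focal is not None:
            members.append(focal)
        key = canon(members)
        if exclude_measured and key in measured:
            continue
        if key not in out:
            out[key] = truth.true_F(key)
    keys = sorted(out, key=lambda k: (len(k), k))
    return pd.Series(
        [out[k] for k in keys], index=[";".join(k) for k in keys], name="F_true"
    )
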