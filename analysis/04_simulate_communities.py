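"""Generate the synthetic consortium experiment.

Emulates the 12-strain design: 16 base background communities dealt with
balanced strain prevalence, each pool strain added to each base background
(176 backgrounds of 2-6 members), every background assayed alone and with
each of the two focal fermenter strains (528 assays), plus 12 monocultures
and 66 pairwise co-cultures (606 assays), in biological triplicate, with
lattice noise tau = 0.01 and measurement noise eps = 0.01.

Writes results/communities/{measurements.csv, truth.json}.
"""

import json
from pathlib import Path

from phylofee import design_counts, simulate_community_experiment
from phylofee.simulate import prevalence_spread

SEED = 4
TAU = EPS = 0.01
OUT = Path(__file__).resolve().parents[1] / "results" / "communities"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    dataset, truth = simulate_community_experiment(tau=TAU, eps=EPS, seed=SEED)
    dataset.to_csv(OUT / "measurements.csv")
    (OUT / "truth.json").write_text(
        json.dumps(
            {
                "seed": SEED, "tau": TAU, "eps": EPS,
                "a": {k: round(v, 6) for k, v in truth.fee_a.items()},
                "b": {k: round(v, 6) for k, v in truth.fee_b.items()},
                "sigma": {k: round(v, 6) for k, v in truth.fee_sigma.items()},
            },
            indent=2, sort_keys=True,
        )
        + "\n"
    )
    counts = design_counts(176, 3, 12)
    n_assays = dataset.df["community_id"].nunique()
    pool = [f"ns{k:02d}" for k in range(1, 11)]
    bases = [c for c in dataset.communities if 0 < len(c) and set(c) <= set(pool)]
    print(f"assays: {n_assays} (design bookkeeping: {counts['total_assays']})")
    print(f"distinct compositions: {len(dataset.communities) - 1}, replicate rows: {len(dataset.df)}")
    print(f"lattice nodes realised: {len(truth._lattice)}, clipped: {truth.n_clipped}")
    print(f"prevalence spread over pool-only backgrounds: {prevalence_spread(bases, pool):.2f}")


if __name__ == "__main__":
    main()
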