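"""Generate the synthetic strain collection: a 60-tip ultrametric tree,
43 quantitative traits with per-trait phylogenetic signal, and strain
metadata (marker group / species / genus by clade depth).

Writes results/collection/{tree.nwk, traits.tsv, metadata.tsv, truth.json}.
"""

import json
from pathlib import Path

from phylofee import simulate, traits

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results" / "collection"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    tree, table, meta, truth = simulate.simulate_collection(
        n_strains=60, n_traits=43, seed=SEED
    )
    (OUT / "tree.nwk").write_text(tree.as_newick() + "\n")
    traits.write_trait_table(table, OUT / "traits.tsv")
    meta.to_csv(OUT / "metadata.tsv", sep="\t")
    (OUT / "truth.json").write_text(
        json.dumps(
            {"seed": SEED, "trait_lambda": truth.trait_lambda.round(6).to_dict()},
            indent=2, sort_keys=True,
        )
        + "\n"
    )
    lam = truth.trait_lambda
    print(f"collection: {tree.n_tips} strains, {table.shape[1]} traits -> {OUT}")
    print(f"generating lambda: min={lam.min():.2f} median={lam.median():.2f} max={lam.max():.2f}")
    print(
        "metadata partitions:"
        f" {meta['marker_group'].nunique()} marker groups,"
        f" {meta['species'].nunique()} species,"
        f" {meta['genus'].nunique()} genera"
    )


if __name__ == "__main__":
    main()
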