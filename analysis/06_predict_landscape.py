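"""Predict held-out community function: FEE concatenation vs additive baseline.

Draws 120 communities never measured in the training design (random pool
subsets plus a focal fermenter), predicts their function by lattice-WLS FEE
concatenation and by the additive model (focal monoculture plus pairwise
effects), and compares both with the ground truth overall and by richness.

Writes results/landscape/{predictions.csv, metrics.json}.
"""

import json
from pathlib import Path

import pandas as pd

from phylofee import (
    CommunityDataset,
    additive_from_dataset,
    evaluate_predictions,
    predict_function,
)
from phylofee.fee import read_fees
from phylofee.simulate import SyntheticTruth, sample_validation_communities

SEED = 5
N_HELD_OUT = 120
FOCAL = "sc01"
BASE = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ds = CommunityDataset.read_csv(BASE / "communities" / "measurements.csv")
    fees = read_fees(BASE / "fees" / "fees.json")
    tj = json.loads((BASE / "communities" / "truth.json").read_text())
    truth = SyntheticTruth(
        seed=tj["seed"], fee_a=tj["a"], fee_b=tj["b"], fee_sigma=tj["sigma"],
        tau=tj["tau"], eps=tj["eps"],
    )
    out = BASE / "landscape"
    out.mkdir(parents=True, exist_ok=True)

    pool = [s for s in ds.strains if s.startswith("ns")]
    val = sample_validation_communities(
        truth, ds, pool, focal=FOCAL, n=N_HELD_OUT, seed=SEED
    )
    fee_pred, add_pred, rows = {}, {}, []
    for key in val.index:
        pr = predict_function(key, ds, fees)
        fee_pred[key] = pr.F_pred
        add_clip, add_raw = additive_from_dataset(ds, key, FOCAL)
        add_pred[key] = add_clip
        rows.append(
            {
                "members": key, "F_true": round(val[key], 6),
                "F_fee": round(pr.F_pred, 6), "F_fee_raw": round(pr.F_pred_raw, 6),
                "F_additive": round(add_clip, 6), "F_additive_raw": round(add_raw, 6),
                "lattice_nodes": pr.lattice_nodes,
            }
        )
    pd.DataFrame(rows).to_csv(out / "predictions.csv", index=False)

    ev_fee = evaluate_predictions(pd.Series(fee_pred), val)
    ev_add = evaluate_predictions(pd.Series(add_pred), val)
    metrics = {
        "n_held_out": ev_fee["n"],
        "fee": {"r": ev_fee["r"], "rmse": ev_fee["rmse"],
                "rmse_by_richness": {str(k): float(v) for k, v in ev_fee["rmse_by_richness"].items()}},
        "additive": {"r": ev_add["r"], "rmse": ev_add["rmse"],
                     "rmse_by_richness": {str(k): float(v) for k, v in ev_add["rmse_by_richness"].items()}},
    }
    (out / "metrics.json").write_text(json.dumps(metrics, indent=2) + "\n")
    print(f"held-out communities: {ev_fee['n']}")
    print(f"FEE lattice model:  r = {ev_fee['r']:.3f}, RMSE = {ev_fee['rmse']:.3f}")
    print(f"additive baseline:  r = {ev_add['r']:.3f}, RMSE = {ev_add['rmse']:.3f}")
    print("additive RMSE by richness:",
          {k: round(float(v), 3) for k, v in ev_add["rmse_by_richness"].items()})
    print("FEE RMSE by richness:     ",
          {k: round(float(v), 3) for k, v in ev_fee["rmse_by_richness"].items()})


if __name__ == "__main__":
    main()
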