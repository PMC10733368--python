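#!/usr/bin/env python
"""Predict the held-out double- and triple-cursor conditions from the
single-cursor fits, and contrast the two models.

The DN model predicts that adding a same-direction cursor leaves the learning
response nearly unchanged (duplicate-like), while the MLE model predicts it
grows; opposite-direction cursors suppress the response under both, but only
the DN pattern matches data generated by a normalizing population.  Writes
the per-condition prediction table and the e1-averaged summary to
results/predictions/.
"""

import json
from pathlib import Path

import pandas as pd

from divnorm import (
    FitResult,
    averaged_response,
    build_exp1_schedule,
    canonical_id,
    collapse_symmetric,
    condition_means,
    predict_conditions,
    r_squared,
)

DATA = Path("results/data/exp1_responses.csv")
FITS = Path("results/fits")
OUT = Path("results/predictions")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    schedule = build_exp1_schedule()
    means = condition_means(
        collapse_symmetric(pd.read_csv(DATA), schedule)
    ).set_index("condition_id")["response"]
    reps = {
        c.condition_id: c.perturbation
        for c in schedule.conditions
        if canonical_id(c.perturbation) == c.condition_id
    }
    cond_ids = sorted(reps)
    rows = []
    summaries = {}
    for model in ("dn", "mle"):
        fit = FitResult.from_dict(json.loads((FITS / f"exp1_fit_{model}.json").read_text()))
        pred = dict(zip(cond_ids, predict_conditions(fit.params, [reps[c] for c in cond_ids])))
        for cid in cond_ids:
            rows.append((model, cid, pred[cid], float(means[cid])))
        held = [c for c in cond_ids if not c.startswith("single")]
        doubles = [c for c in cond_ids if c.startswith("double")]
        r2_held = r_squared([means[c] for c in held], [pred[c] for c in held])
        r2_dbl = r_squared([means[c] for c in doubles], [pred[c] for c in doubles])
        summaries[model] = {"r2_prediction_held_out": r2_held, "r2_prediction_double": r2_dbl}
        print(f"{model.upper()} out-of-condition prediction: "
              f"R^2 (all held out) = {r2_held:.4f}, R^2 (doubles) = {r2_dbl:.4f}")
        av = averaged_response(pred)
        summaries[model]["averaged_response_by_e2"] = {str(k): v for k, v in av.items()}

    av_data = averaged_response(dict(means))
    summaries["data"] = {"averaged_response_by_e2": {str(k): v for k, v in av_data.items()}}
    print("observed e1-averaged responses by e2 (single reference "
          f"{av_data['single']:.1f}):")
    for e2 in (-45.0, -30.0, -15.0, 0.0, 15.0, 30.0, 45.0):
        print(f"  e2 = {e2:+5.1f} -> {av_data[e2]:7.2f}")

    pd.DataFrame(rows, columns=["model", "condition_id", "predicted", "observed"]).to_csv(
        OUT / "exp1_predictions.csv", index=False
    )
    (OUT / "exp1_summary.json").write_text(json.dumps(summaries, indent=2))
    print(f"wrote {OUT}/exp1_predictions.csv and {OUT}/exp1_summary.json")


if __name__ == "__main__":
    main()
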