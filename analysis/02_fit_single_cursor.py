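#!/usr/bin/env python
"""Fit the DN and MLE single-cursor models to the collapsed condition means
of the simulated multi-cursor experiment.

Only the five collapsed single-cursor conditions (e1 = 0, 7.5, 15, 30, 45 deg)
enter the fit; the fitted parameters, fit R^2, and the DN nonlinearity index
w^2/k are printed and written to results/fits/.
"""

import json
from pathlib import Path

import pandas as pd

from divnorm import (
    build_exp1_schedule,
    collapse_symmetric,
    condition_means,
    fit_dn_single,
    fit_mle_single,
    nonlinearity_index,
)

DATA = Path("results/data/exp1_responses.csv")
OUT = Path("results/fits")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    schedule = build_exp1_schedule()
    table = pd.read_csv(DATA)
    means = condition_means(collapse_symmetric(table, schedule))
    singles = means[means.condition_id.str.startswith("single")].copy()
    singles["error"] = singles.condition_id.str.removeprefix("single_").astype(float)
    points = sorted(zip(singles["error"], singles["response"]))
    print("collapsed single-cursor condition means (error deg -> response):")
    for e, r in points:
        print(f"  {e:5.1f} -> {r:7.2f}")

    dn = fit_dn_single(points)
    print(
        f"DN fit: w = {dn.params.w:.4e}, k = {dn.params.k:.4e}, "
        f"R^2 = {dn.r_squared:.4f}, w^2/k = {nonlinearity_index(dn.params.w, dn.params.k):.4f}"
    )
    mle = fit_mle_single(points)
    print(
        f"MLE fit: c = {mle.params.c:.4e}, sigma_v/sigma_p = {mle.params.ratio_sv:.4g}, "
        f"k_v/sigma_p = {mle.params.ratio_kv:.4g}, R^2 = {mle.r_squared:.4f}"
    )
    (OUT / "exp1_fit_dn.json").write_text(json.dumps(dn.to_dict(), indent=2))
    (OUT / "exp1_fit_mle.json").write_text(json.dumps(mle.to_dict(), indent=2))
    print(f"wrote {OUT}/exp1_fit_dn.json and {OUT}/exp1_fit_mle.json")


if __name__ == "__main__":
    main()
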