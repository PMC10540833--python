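#!/usr/bin/env python
"""Estimate per-cell metabolic and synthesis rates from synthetic assay data.

Emulates the wet-lab measurement campaign end to end: for each species,
flux-analyzer traces (oxygen + pH) and spheroid GAG assays are generated
with the configured per-cell rates embedded as ground truth, then pushed
through the estimation pipeline (blank correction, plateau fitting,
standard-curve inversion, outlier screening, per-cell normalization).
Writes a tidy table of estimated vs true rates to results/rates.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

import discregen as dr
from discregen.flux_estimation import (
    estimate_gag_synthesis_rate,
    estimate_lpr,
    estimate_ocr,
    remove_outliers,
)
from discregen.synthetic import (
    GeneratorSpec,
    default_standard_curve,
    generate_flux_trace,
    generate_gag_assay,
)

N_REPLICATES = 25  # technical replicates per species and quantity
N_CELLS = 5000.0  # cells per spheroid
CULTURE_DAYS = 14.0


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    spec = GeneratorSpec(seed=args.seed)
    rng = spec.rng()
    curve = default_standard_curve()
    rows = []
    for species in ("rat", "goat", "human_grade3"):
        p = dr.load_species_parameters(dr.builtin_config_path(species))
        true_ocr = p.metabolic_rates["np"].vmax_o2
        true_lpr = p.metabolic_rates["np"].lpr
        true_lam1 = p.gag.synthesis_rate

        ocrs, lprs, lams = [], [], []
        for _ in range(N_REPLICATES):
            trace, blank, _ = generate_flux_trace(
                spec, true_ocr=true_ocr, true_lpr=true_lpr, n_cells=N_CELLS,
                rng=rng)
            ocr, flagged = estimate_ocr(trace, blank, N_CELLS)
            if not flagged:
                ocrs.append(ocr)
            lprs.append(estimate_lpr(trace, blank, curve, N_CELLS))
            assay, _ = generate_gag_assay(spec, true_lam1, N_CELLS,
                                          CULTURE_DAYS, rng=rng)
            lams.append(estimate_gag_synthesis_rate(assay))

        for name, true, values in (("ocr", true_ocr, ocrs),
                                   ("lpr", true_lpr, lprs),
                                   ("gag_synthesis", true_lam1, lams)):
            screened = remove_outliers(values)
            est = float(np.mean(screened.kept))
            rows.append({
                "species": species, "quantity": name, "true": true,
                "estimate": est, "sd": float(np.std(screened.kept)),
                "n_kept": len(screened.kept),
                "n_outliers": int(screened.flags.sum()),
                "rel_error": abs(est - true) / true,
            })
            print(f"{species:13s} {name:13s} true={true:7.2f} "
                  f"est={est:7.2f} +/- {rows[-1]['sd']:.2f} "
                  f"(outliers removed: {rows[-1]['n_outliers']})")

    df = pd.DataFrame(rows)
    df.to_csv(args.out / "rates.csv", index=False)
    worst = df["rel_error"].max()
    print(f"\nall rates recovered within {100 * worst:.1f}% of truth; "
          f"table written to {args.out / 'rates.csv'}")


if __name__ == "__main__":
    main()
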