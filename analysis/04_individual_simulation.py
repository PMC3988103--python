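#!/usr/bin/env python
"""Individual-level sampling simulation: why averaged GSI differs from the ratio.

Simulates the field design (males per species, ten sperm packages per male,
spermatophore area x width pairs) around the published species targets and
contrasts two GSI conventions: the ratio of species means versus the species
mean of per-male ratios. With individual variation the two diverge (Jensen's
inequality: E[tm/bm] > E[tm]/E[bm] for independent positive draws) — the
mechanical explanation for small discrepancies between tabulated GSI values
and mean-ratio arithmetic. Writes results/synthetic_gsi.json.
"""

import argparse
import json
from pathlib import Path

from scorpallo import gsi, load_trait_table, simulate_study

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n-males", type=int, default=10_000,
                        help="males per species (large, to show convergence)")
    args = parser.parse_args()

    targets = load_trait_table("vrech2014")
    study = simulate_study(targets, seed=args.seed, n_males=args.n_males)
    sdf = targets.df.set_index("species")
    tdf = study.table.df.set_index("species")

    rows = {}
    print(f"{args.n_males} simulated males/species, study SDs:")
    print(f"{'species':<30s} {'ratio-of-means':>14s} {'mean-of-ratios':>14s} {'shift%':>7s}")
    for sp in sdf.index:
        ratio = gsi(sdf.loc[sp, "body_mass_g"], sdf.loc[sp, "testes_mass_mg"])
        individual = float(study.gsi_individual[sp])
        shift = 100 * (individual - ratio) / ratio
        rows[sp] = {
            "gsi_ratio_of_means": ratio,
            "gsi_mean_of_ratios": individual,
            "relative_shift_percent": shift,
            "derived_body_mass_g": float(tdf.loc[sp, "body_mass_g"]),
            "derived_testes_mass_mg": float(tdf.loc[sp, "testes_mass_mg"]),
        }
        print(f"{sp:<30s} {ratio:14.3f} {individual:14.3f} {shift:6.1f}%")

    max_err = max(
        abs(tdf.loc[sp, c] / sdf.loc[sp, c] - 1)
        for sp in sdf.index
        for c in ("body_mass_g", "testes_mass_mg", "sperm_length_um")
    )
    print(f"Derived species means are within {100 * max_err:.2f}% of targets.")
    print("Per-male averaging inflates GSI wherever body-mass variation is "
          "large (e.g. Timogenes dorbignyi), and leaves it untouched when "
          "individual SDs are zero.")

    OUT.mkdir(exist_ok=True)
    payload = {"seed": args.seed, "n_males": args.n_males,
               "max_relative_mean_error": max_err, "species": rows}
    (OUT / "synthetic_gsi.json").write_text(json.dumps(payload, indent=2))
    print(f"Wrote {OUT / 'synthetic_gsi.json'}")


if __name__ == "__main__":
    main()
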