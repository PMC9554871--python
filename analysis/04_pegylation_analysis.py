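#!/usr/bin/env python
"""Quantify PEG conjugation across feeding ratios and derive the
conjugation metrics.

Simulates hydrolysates of PEGylated particles at feed ratios 1:0.1 to 1:2,
integrates the 3.70-3.90 ppm window, removes the overlapping ethoxy CH2
contribution via the 2:3 proton ratio against the ethoxy CH3 peak, converts
to moles of PEG through the internal standard, and tabulates substitution,
reaction efficiency, and weight percentages.  Writes
results/pegylation_metrics.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from psiqnmr import AcquisitionParams, SpeciesComposition, peg_metrics
from psiqnmr.pipeline import PEG_FEED_RATIOS, PEG_LOADINGS_UMOL_PER_MG
from psiqnmr.quantify import peg_loading_from_spectrum
from psiqnmr.synthetic import generate_pegylation_series

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--n-nh2", type=float, default=0.294,
                        help="amine content (umol per mg particle)")
    args = parser.parse_args()

    comp = SpeciesComposition(amine_loading_umol_per_mg=args.n_nh2)
    acq = AcquisitionParams(seed=args.seed, noise_sigma=1e-4)
    series = generate_pegylation_series(
        PEG_FEED_RATIOS, PEG_LOADINGS_UMOL_PER_MG, comp, 0.4, acq
    )
    rows = []
    for (ratio, spec), planted in zip(series, PEG_LOADINGS_UMOL_PER_MG):
        q = peg_loading_from_spectrum(spec, 1.0)
        m = peg_metrics(q.moles_umol, args.n_nh2, ratio, 5000.0, 1.0)
        rows.append({
            "feed_ratio": f"1:{ratio:g}",
            "n_peg_umol": round(q.moles_umol, 3),
            "planted_umol": planted,
            "pct_amine_substituted": round(m.pct_amine_substituted, 1),
            "pct_reaction_efficiency": round(m.pct_reaction_efficiency, 1),
            "pct_weight": round(m.pct_weight, 1),
        })
    table = pd.DataFrame(rows)
    out = ROOT / "results" / "pegylation_metrics.csv"
    out.parent.mkdir(exist_ok=True)
    table.to_csv(out, index=False)
    print(table.to_string(index=False))
    print("\nconjugated PEG rises with the feeding ratio while the reaction "
          "efficiency falls; weight percent reaches "
          f"{rows[-1]['pct_weight']}% at the highest ratio")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
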