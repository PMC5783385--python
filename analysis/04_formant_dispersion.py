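#!/usr/bin/env python
"""Formant dispersion versus the uniform-tube prediction.

Synthesizes roar-like calls for four virtual animals whose vocal tracts
are uniform tubes of length ~11 cm (the species' measured mean), runs the
Burg-LPC formant tracker over each call, computes measured dispersion
(mean adjacent-formant spacing) per animal, and compares it with the
uniform-tube prediction c/(2*VTL) by a paired t-test.

Writes results/formant_dispersion.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from pacavoc import formants as fm
from pacavoc import synth

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 11
N_ANIMALS = 4
CALLS_PER_ANIMAL = 10


def main() -> None:
    rng = np.random.default_rng(SEED)
    rows = []
    for animal in range(N_ANIMALS):
        vtl = float(rng.normal(0.110, 0.002))
        truth = [(2 * i - 1) * fm.SPEED_OF_SOUND / (4 * vtl) for i in range(1, 6)]
        dfs = []
        for call in range(CALLS_PER_ANIMAL):
            f0 = float(rng.uniform(95, 130))
            w = synth.generate_formant_waveform(
                f0, truth, duration=0.6, rate=22_050,
                seed=int(rng.integers(2**31)),
            )
            track = fm.estimate_formants(w, max_formant=truth[-1] * 1.15)
            dfs.append(fm.measured_dispersion(track))
        pred = fm.predicted_dispersion(fm.VocalTractSpec(vtl=vtl))
        mean_df = float(np.mean([d.df for d in dfs]))
        sd_frac = float(np.mean([d.sd_fraction for d in dfs]))
        rows.append(
            {"animal": f"animal{animal}", "vtl_cm": 100 * vtl,
             "measured_df": mean_df, "predicted_df": pred,
             "sd_fraction": sd_frac}
        )
    table = pd.DataFrame(rows)
    print(table.round(2).to_string(index=False))

    t = fm.compare_dispersions(table["measured_df"], table["predicted_df"])
    rel = (table["measured_df"] / table["predicted_df"] - 1).mean()
    print(
        f"\npaired t-test measured vs predicted: t = {t['t']:.2f}, "
        f"df = {t['df']}, p = {t['p']:.2g}"
    )
    print(
        f"mean relative deviation {100 * rel:+.1f}% (small systematic LPC bias; "
        "with near-zero between-animal variance in this synthetic fixture the "
        "paired test detects it, unlike noisy field measurements)"
    )
    print(f"mean interval-SD fraction: {100 * table['sd_fraction'].mean():.1f}% "
          "(uniform-tube approximation quality)")

    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "formant_dispersion.csv", index=False)


if __name__ == "__main__":
    main()
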