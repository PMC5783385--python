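#!/usr/bin/env python
"""Validate the eight putative call types on the synthetic element table.

Standardizes the four acoustic parameters, fits the linear discriminant
model, tests it with a MANOVA (Wilks' lambda), cross-validates with
leave-one-out nearest-centroid classification, tests the accuracy against
the 12.5% chance level with an exact binomial test, and fits the two-way
call-type x age-class linear model on per-individual means.

Writes results/repertoire_report.json and results/confusion_matrix.csv.
"""

import json
from pathlib import Path

from pacavoc import io as pio
from pacavoc import repertoire

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"


def main() -> None:
    table = pio.read_element_csv(OUT / "elements.csv")

    model = repertoire.fit_lda(table)
    ev = model.explained_variance
    print(f"LDA: first two axes explain {100 * ev[:2].sum():.1f}% of variance")
    print("DF1 loadings:\n", model.loadings["DF1"].round(2).to_string())

    wilks = repertoire.manova_wilks(table)
    print(
        f"MANOVA: Wilks lambda = {wilks['wilks_lambda']:.3f}, "
        f"F({wilks['df1']}, {wilks['df2']:.0f}) = {wilks['F']:.2f}, p = {wilks['p']:.2g}"
    )

    cm = repertoire.loo_crossvalidate(table)
    acc = cm.per_class_accuracy
    print(f"leave-one-out accuracy: {100 * cm.overall_accuracy:.1f}% overall; "
          f"range {100 * acc.min():.0f}% ({acc.idxmin()}) to {100 * acc.max():.0f}% ({acc.idxmax()})")
    p = repertoire.binomial_vs_chance(cm.n_correct, cm.n_total, 0.125)
    print(f"binomial test vs 12.5% chance: p = {p:.2g}")

    glm_input = (
        table.groupby(["individual_id", "age_class", "call_type"], observed=True)["duration"]
        .mean()
        .rename("value")
        .reset_index()
    )
    # keep call types emitted by both age classes
    both = (
        glm_input.groupby("call_type")["age_class"].nunique().loc[lambda s: s == 2].index
    )
    glm = repertoire.age_type_linear_model(glm_input[glm_input.call_type.isin(both)])
    print("GLM on per-individual mean durations:")
    print(glm[["F", "PR(>F)"]].round(3).to_string())

    cm.counts.to_csv(OUT / "confusion_matrix.csv")
    report = {
        "model": model.to_report(),
        "manova": wilks,
        "overall_accuracy": cm.overall_accuracy,
        "per_class_accuracy": acc.to_dict(),
        "binomial_p": p,
        "glm": glm.to_dict(orient="index"),
    }
    (OUT / "repertoire_report.json").write_text(
        json.dumps(report, indent=2, default=pio._json_default)
    )


if __name__ == "__main__":
    main()
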