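#!/usr/bin/env python
"""Section-level anatomy comparisons on a synthetic cohort.

Generates a cohort with a BTBR expansion of the vermal layers and a small
Purkinje linear-density deficit, then applies the reporting contracts:
two-way ANOVA (strain x lobule/layer) with Bonferroni-corrected per-level
comparisons, plus the spine-density comparison from 03_morphometry.py.
Writes results/anatomy_stats.json.
"""
import json
from pathlib import Path

import pandas as pd

from blinkscore.stats import (
    anova_report,
    planned_comparisons,
    two_sample_test,
    two_way_anova,
)
from blinkscore.synthetic import generate_cohort

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 777
DESIGN = {("C57", "M"): 8, ("BTBR", "M"): 8}
EFFECTS = {
    "layer_area_mm2": 0.25,  # vermal expansion
    "linear_density_per_100um": -0.3,  # fewer Purkinje cells per 100 um
    "n_folia": 4.0,  # abnormal foliation
}


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    cohort = generate_cohort(DESIGN, effects=EFFECTS, seed=SEED)
    cohort.to_csv(RESULTS / "anatomy_cohort.csv", index=False)
    report = {}
    for measure, repeated in (
        ("layer_area_mm2", False),
        ("linear_density_per_100um", False),
    ):
        tab = cohort[cohort.measure == measure]
        aov = two_way_anova(tab, repeated=repeated)
        aov.post_hoc = planned_comparisons(tab)
        report[measure] = anova_report(aov)
        n_sig = int((aov.post_hoc["p_adjusted"] < 0.05).sum())
        print(
            f"{measure}: strain F = {aov['strain'].F:.2f}, "
            f"p = {aov['strain'].p:.2e}; {n_sig}/{len(aov.post_hoc)} "
            "levels significant after Bonferroni"
        )

    folia = cohort[cohort.measure == "n_folia"]
    t = two_sample_test(
        folia.loc[folia.strain == "C57", "value"],
        folia.loc[folia.strain == "BTBR", "value"],
    )
    report["n_folia_t"] = {"t": t.t, "df": t.df, "p": t.p}
    print(f"folia count t-test: t = {t.t:.2f}, p = {t.p:.2e}")

    cells_path = RESULTS / "morphometry_cells.csv"
    if cells_path.exists():
        cells = pd.read_csv(cells_path)
        t = two_sample_test(
            cells.loc[cells.strain == "C57", "spine_density_per_um"],
            cells.loc[cells.strain == "BTBR", "spine_density_per_um"],
        )
        report["spine_density_t"] = {"t": t.t, "df": t.df, "p": t.p}
        print(f"spine density t-test: t = {t.t:.2f}, p = {t.p:.4f}")

    out = RESULTS / "anatomy_stats.json"
    out.write_text(json.dumps(report, indent=2))
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
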