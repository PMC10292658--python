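#!/usr/bin/env python
"""Statistical report on the simulated behavioral cohort.

Per sex: repeated-measures (mixed) ANOVA of percent CR over the 12 training
sessions with strain as the between factor, a two-sample t-test on terminal
performance, and a t-test on CS-only peak times. Reads the tables written
by 01_simulate_and_score_behavior.py; writes results/behavior_stats.json.
"""
import json
from pathlib import Path

import pandas as pd

from blinkscore.stats import anova_report, two_sample_test, two_way_anova

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    sessions = pd.read_csv(RESULTS / "session_summaries.csv")
    terminal = pd.read_csv(RESULTS / "terminal_performance.csv")
    report = {}
    for sex in ("M", "F"):
        sub = sessions[sessions.sex == sex].rename(
            columns={"session_index": "level", "percent_cr": "value"}
        )
        aov = two_way_anova(sub, repeated=True)
        term = terminal[terminal.sex == sex]
        t_term = two_sample_test(
            term.loc[term.strain == "C57", "terminal_percent_cr"],
            term.loc[term.strain == "BTBR", "terminal_percent_cr"],
        )
        peaks = term.dropna(subset=["peak_time_ms"])
        t_peak = two_sample_test(
            peaks.loc[peaks.strain == "C57", "peak_time_ms"],
            peaks.loc[peaks.strain == "BTBR", "peak_time_ms"],
        )
        report[sex] = {
            "rm_anova_percent_cr": anova_report(aov),
            "terminal_t": {"t": t_term.t, "df": t_term.df, "p": t_term.p},
            "peak_time_t": {"t": t_peak.t, "df": t_peak.df, "p": t_peak.p},
        }
        print(
            f"sex {sex}: strain p = {aov['strain'].p:.4f}, "
            f"session p = {aov['factor2'].p:.2e}, "
            f"interaction p = {aov['interaction'].p:.4f}; "
            f"terminal t-test p = {t_term.p:.4f}; peak-time p = {t_peak.p:.4f}"
        )

    out = RESULTS / "behavior_stats.json"
    out.write_text(json.dumps(report, indent=2))
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
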