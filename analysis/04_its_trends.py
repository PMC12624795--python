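"""Interrupted time-series trends in mental health and healthcare use.

Fits logistic random-intercept models for the binary outcomes (mentally
unhealthy, mental healthcare use, medication use) over 2012-2019 with a
trend change at the 2016 campaign start, adjusted for the business-cycle
confounder, plus differential trend-change contrasts by gender, social
support, urbanicity, education and migration background. Compares the
recovered trend-change coefficients with the sealed generating truth.

Run after 01_simulate_panel.py:  python analysis/04_its_trends.py
"""

import json
from pathlib import Path

import pandas as pd

from resilnet import read_panel_csv, trend_change_report

OUT = Path("results/analysis")


def main() -> None:
    panel = read_panel_csv(OUT / "panel.csv")
    conf = pd.read_csv(OUT / "confounder.csv", comment="#")
    confounder = dict(zip(conf["year"].astype(int), conf["value"]))
    truth = json.loads((OUT / "truth.json").read_text())

    report = trend_change_report(panel, confounder=confounder)
    report.to_csv(OUT / "its_report.csv", index=False)

    print(report.round(4).to_string(index=False))
    print()
    models = truth["outcome_models"]
    for outcome, model in models.items():
        row = report[(report["outcome"] == outcome)
                     & (report["contrast"] == "trend_change")]
        if not row.empty:
            r = row.iloc[0]
            print(f"{outcome}: overall trend change beta={r.beta:+.3f} "
                  f"(SE {r.se:.3f}, p={r.p:.3g}); generating value "
                  f"{model['t_post']:+.2f}")
        for key, coef in model.get("contrasts", {}).items():
            var, lvl = key.split(":")
            term = f"{var}[{lvl}]:t_post"
            row = report[(report["outcome"] == outcome)
                         & (report["contrast"] == term)]
            if not row.empty:
                r = row.iloc[0]
                print(f"{outcome}: {term} beta={r.beta:+.3f} "
                      f"(SE {r.se:.3f}, p={r.p:.3g}); generating value "
                      f"{coef:+.2f}")


if __name__ == "__main__":
    main()
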