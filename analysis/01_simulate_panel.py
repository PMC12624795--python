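"""Simulate the study panel.

Generates the default LISS-like rotating panel (2012-2022, no 2014
survey, ~10% yearly attrition with refreshment) with known generating
truth, and writes panel, truth record and business-cycle confounder to
results/analysis/. All later analysis steps read these files.

Run from the repository root:  python analysis/01_simulate_panel.py
"""

import json
from pathlib import Path

from resilnet import GeneratorConfig, generate_panel, write_panel_csv

SEED = 20120101
N_TARGET = 3000  # scaled-down panel; the study waves were n ~ 4400-5800

OUT = Path("results/analysis")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = GeneratorConfig(seed=SEED, n_target=N_TARGET)
    panel, truth = generate_panel(config)
    write_panel_csv(panel, OUT / "panel.csv", [f"seed={SEED}"])
    (OUT / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    with open(OUT / "confounder.csv", "w") as fh:
        fh.write("year,value\n")
        for year, value in truth["confounder"].items():
            fh.write(f"{year},{value!r}\n")
    n_by_year = panel.df.groupby("year").size()
    print(f"wrote {len(panel.df)} participant-year records "
          f"({n_by_year.min()}-{n_by_year.max()} per year) to {OUT}/panel.csv")
    print(f"survey years: {panel.years} (2014 not administered)")
    print("generating conditions: mean node threshold falls from "
          f"{truth['year_params'][2012][0]} (2012) to "
          f"{truth['year_params'][2015][0]} (2015), then plateaus; "
          "truth sealed in truth.json")


if __name__ == "__main__":
    main()
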