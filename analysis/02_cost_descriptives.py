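"""Descriptive service-use summary of the synthetic trial (Table-1 shape).

Reads results/data (run 01_simulate.py first) and writes the per-arm
total-cost summary plus per-provider and per-condition visit tables.
"""

from pathlib import Path

from trialcea import load_trial_data, summarize_costs

OUT = Path("results")


def main() -> None:
    ds = load_trial_data(OUT / "data")
    summary = summarize_costs(ds)
    summary.totals.to_csv(OUT / "table1_totals.csv", index=False, float_format="%.2f")
    summary.providers.to_csv(OUT / "table1_providers.csv", index=False, float_format="%.2f")
    summary.conditions.to_csv(OUT / "table1_conditions.csv", index=False, float_format="%.2f")
    print("per-arm total health-care cost (zeros included):")
    print(summary.totals.to_string(index=False))
    print(f"wrote table1_* files under {OUT}/")


if __name__ == "__main__":
    main()
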