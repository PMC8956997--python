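"""Bootstrap probabilistic sensitivity analysis on the synthetic trial.

Stratified resampling with full per-replicate refits; writes the draw
table, CE-plane quadrant fractions for web vs home and home vs control,
and the acceptability curves for all four outcomes.  Uses 500 replicates
here to keep the driver quick; the shipped default for a production run
is 10,000 (see BootstrapConfig).
"""

from pathlib import Path

import pandas as pd

from trialcea import (
    BootstrapConfig,
    bootstrap_draws,
    ce_plane,
    ceac,
    default_program_specs,
    default_wtp_grid,
    load_trial_data,
)
from trialcea.cea import ScenarioSpec, scenario_program_costs

SEED = 1
N_REPS = 500
OUT = Path("results")


def main() -> None:
    ds = load_trial_data(OUT / "data")
    prog = scenario_program_costs(
        default_program_specs(True), ScenarioSpec("base"), 0.5, ds.arm_sizes()
    )
    draws = bootstrap_draws(ds, prog, BootstrapConfig(n_reps=N_REPS, seed=SEED))
    print(f"{draws.n_reps} replicates kept, {draws.n_failed} failed, "
          f"{int(draws.flagged.sum())} flagged")

    rows = []
    for ref, comp in (("home", "web"), ("control", "home")):
        for name in draws.outcome_names:
            plane = ce_plane(draws, ref, comp, name)
            rows.append({"reference": ref, "comparator": comp, "outcome": name,
                         **plane.quadrants})
    quad = pd.DataFrame(rows)
    quad.to_csv(OUT / "ce_plane_quadrants.csv", index=False, float_format="%.4f")
    print("\nCE-plane quadrant fractions:")
    print(quad.to_string(index=False))

    for name in draws.outcome_names:
        curve = ceac(draws, default_wtp_grid(), name)
        curve.probabilities.reset_index().to_csv(
            OUT / f"ceac_{name}.csv", index=False, float_format="%.4f"
        )
    sample = ceac(draws, [0, 100, 400], "pmpse").probabilities
    print("\nP(cost-effective), self-efficacy, at WTP 0/100/400 SGD per score:")
    print(sample.to_string())


if __name__ == "__main__":
    main()
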