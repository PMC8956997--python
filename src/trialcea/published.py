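"""Published summary inputs of the three-arm postnatal-care trial.

The original participant-level data were never deposited; what the study
reports are arm-level summaries (service-use table, adjusted
cost-effectiveness table, projection constants).  These printed numbers are
the *inputs* to everything this package recomputes: the synthetic-data
generator is calibrated to them, the worked ICER/dominance examples take
them directly, and the budget projection runs from the program-cost
constants.

All monetary amounts are SGD (2016-2017; SGD 1 = USD 0.75).
"""

from __future__ import annotations

ARM_SIZES = {"web": 64, "home": 63, "control": 66}  # analysis set, N=193

#: Mothers with zero health-service use over the 6-month follow-up.
ZERO_COST_COUNTS = {"web": 28, "home": 20, "control": 30}

#: Mean (SD) health-care cost per participant over all mothers of the arm,
#: zeros included.
HEALTH_COST_MEAN = {"web": 339.9, "home": 375.4, "control": 411.2}
HEALTH_COST_SD = {"web": 493.0, "home": 699.9, "control": 601.0}

#: Program-level cost components.
WEB_UPFRONT = 17_210.0          # website + educational video development
WEB_RECURRING_ANNUAL = 2_900.0  # web maintenance per year
HOME_UPFRONT = 233.40           # one-time nurse training fee
HOME_VISIT_COST = 77.42         # per 1-hour home visit (manpower+materials+transport)
PROGRAM_LIFETIME_YEARS = 5
DEPRECIATION_RATE = 0.03
TRIAL_HORIZON_YEARS = 0.5       # 6-month follow-up

#: Covariate-adjusted 6-month effectiveness (score scale, raw orientation)
#: per arm and instrument.
ADJUSTED_EFFECTS = {
    "web": {"pmpse": 59.11, "picss": 81.6, "epds": 4.44, "hadsa": 3.36},
    "control": {"pmpse": 56.28, "picss": 75.3, "epds": 6.17, "hadsa": 4.81},
    "home": {"pmpse": 57.27, "picss": 79.9, "epds": 5.45, "hadsa": 4.37},
}

#: Covariate-adjusted total cost per participant, base case.
ADJUSTED_TOTAL_COST = {"web": 376.50, "control": 417.90, "home": 457.60}

#: Adjusted health-care-only cost (the 0%-program-cost scenario row).
ADJUSTED_HEALTH_COST = {"web": 325.55, "home": 380.22, "control": 417.90}

#: Per-participant program components implied by the scenario panels
#: (total minus health-care-only; the 200%/300% rows pin these down).
PROGRAM_COMPONENT = {
    "web": (427.38 - 325.55) / 2,    # 50.915
    "home": (613.61 - 380.22) / 3,   # 77.797
    "control": 0.0,
}

#: Program components under the 3-year-lifetime scenario panel.
PROGRAM_COMPONENT_3YR = {
    "web": 392.90 - 325.55,          # 67.35
    "home": 458.20 - 380.22,         # 77.98
    "control": 0.0,
}

#: Budget-impact projection constants.
ANNUAL_COHORT = 20_000              # first-time mothers per year nationwide
COVERAGE_LEVELS = (0.10, 0.50, 1.00)
PROJECTION_YEARS = 5
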