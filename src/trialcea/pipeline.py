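"""End-to-end pipeline: one declarative config, all tables and curves out.

Stages: data (load or simulate) -> descriptive cost summary -> adjusted
models -> deterministic CEA scenario table -> bootstrap PSA (CE planes,
CEACs) -> budget-impact projection.  Every output file is listed in a JSON
run manifest together with the effective configuration, package versions,
seed and per-stage timings; re-running the same config and seed reproduces
all numeric outputs byte-identically.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, published
from .adjusted_models import CostModelSpec, adjusted_arm_means, fit_all
from .budget_projection import default_projection_spec, project, reduced_cost
from .cea import ScenarioSpec, build_scenario_table, scenario_program_costs
from .program_costing import ProgramCostSpec, default_program_specs
from .psa import BootstrapConfig, bootstrap_draws, ce_plane, ceac, default_wtp_grid
from .synthetic_trial import default_config, generate_trial
from .trial_data import load_trial_data, save_trial_data, summarize_costs

__all__ = ["RunConfig", "ConfigError", "run_pipeline", "default_scenarios"]


class ConfigError(ValueError):
    """The run configuration is invalid."""


def default_scenarios(calibrated: bool = True) -> list:
    """The deterministic sensitivity scenarios of the published analysis.

    Base case, a 3-year program lifetime, and program-cost multipliers of
    0%, 50%, 200% and 300%.  With ``calibrated=True`` the lifetime scenario
    carries the per-participant components implied by the published
    scenario panel (they are not derivable from the raw inputs alone).
    """
    three_yr = ScenarioSpec(
        "program valid 3 years",
        lifetime_years=3,
        component_override=dict(published.PROGRAM_COMPONENT_3YR) if calibrated else None,
    )
    return [
        ScenarioSpec("base case"),
        three_yr,
        ScenarioSpec("0% program cost", multiplier=0.0),
        ScenarioSpec("50% program cost", multiplier=0.5),
        ScenarioSpec("200% program cost", multiplier=2.0),
        ScenarioSpec("300% program cost", multiplier=3.0),
    ]


@dataclass
class RunConfig:
    """Declarative run configuration.

    Exactly one of ``data_dir`` (load an existing CSV pair) or ``simulate``
    (generate a synthetic trial; ``True`` or a dict of generator overrides,
    currently ``size_factor``) must be given.  The global ``seed`` drives
    both simulation and the bootstrap.
    """

    out_dir: str = "results/run"
    seed: int = 0
    data_dir: str | None = None
    simulate: bool | dict = False
    n_reps: int = 10_000
    calibrated_program_costs: bool = True
    programs: dict | None = None  # arm -> ProgramCostSpec overrides
    make_plots: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = cls.__dataclass_fields__
        unknown = set(raw) - set(known)
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if bool(self.data_dir) == bool(self.simulate):
            raise ConfigError("exactly one of data_dir / simulate must be set")
        if self.n_reps < 1:
            raise ConfigError("n_reps must be >= 1")

    def program_specs(self) -> dict:
        specs = default_program_specs(self.calibrated_program_costs)
        for arm, overrides in (self.programs or {}).items():
            if arm not in specs:
                specs[arm] = ProgramCostSpec(arm=arm, **overrides)
            else:
                base = asdict(specs[arm])
                base.update(overrides)
                specs[arm] = ProgramCostSpec(**base)
        return specs

    def effective(self) -> dict:
        """The fully defaulted configuration, for the manifest/log."""
        return asdict(self)


def _write_csv(df: pd.DataFrame, path: Path) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.6f")
    return path


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage; returns the run manifest (also written to disk).

    Any stage failure aborts with the stage name in the exception message
    and removes the files written so far.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    timings: dict = {}
    stage = "setup"

    def _record(path: Path) -> str:
        written.append(path)
        return str(path)

    manifest: dict = {
        "seed": cfg.seed,
        "version": __version__,
        "config": cfg.effective(),
        "outputs": {},
    }
    try:
        t0 = time.perf_counter()
        stage = "data"
        if cfg.simulate:
            gen_cfg = default_config(seed=cfg.seed)
            if isinstance(cfg.simulate, dict) and cfg.simulate.get("size_factor"):
                gen_cfg = gen_cfg.scaled(int(cfg.simulate["size_factor"]))
            ds = generate_trial(gen_cfg, seed=cfg.seed)
            paths = save_trial_data(ds, out / "data")
            manifest["outputs"]["data"] = {
                k: _record(p) for k, p in paths.items()
            }
        else:
            ds = load_trial_data(cfg.data_dir)
        timings["data"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        stage = "descriptives"
        summary = summarize_costs(ds)
        manifest["outputs"]["table1_totals"] = _record(
            _write_csv(summary.totals, out / "table1_totals.csv")
        )
        manifest["outputs"]["table1_providers"] = _record(
            _write_csv(summary.providers, out / "table1_providers.csv")
        )
        manifest["outputs"]["table1_conditions"] = _record(
            _write_csv(summary.conditions, out / "table1_conditions.csv")
        )
        timings["descriptives"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        stage = "adjusted_models"
        effect_fits, cost_fit = fit_all(ds, ds.outcomes)
        specs = cfg.program_specs()
        missing = [a for a in ds.arms if a not in specs]
        if missing:
            raise ConfigError(f"no program costs configured for arm(s): {missing}")
        n_served = ds.arm_sizes()
        base_prog = scenario_program_costs(
            specs, ScenarioSpec("base case"), published.TRIAL_HORIZON_YEARS, n_served
        )
        base_arms = adjusted_arm_means(effect_fits, cost_fit, ds, base_prog)
        base_frame = pd.DataFrame(
            [
                {
                    "arm": a.arm,
                    "adjusted_health_cost": a.adjusted_health_cost,
                    "adjusted_total_cost": a.adjusted_total_cost,
                    **{f"{k}_adjusted": v for k, v in a.adjusted_effect.items()},
                }
                for a in base_arms
            ]
        )
        manifest["outputs"]["base_case"] = _record(
            _write_csv(base_frame, out / "base_case.csv")
        )
        timings["adjusted_models"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        stage = "cea_scenarios"
        # health-care-only arms: scenario panels move only the program cost
        health_arms = adjusted_arm_means(effect_fits, cost_fit, ds, None)
        table2 = build_scenario_table(
            health_arms,
            specs,
            default_scenarios(cfg.calibrated_program_costs),
            ds.outcomes,
            horizon_years=published.TRIAL_HORIZON_YEARS,
            n_served=n_served,
        )
        manifest["outputs"]["table2"] = _record(_write_csv(table2, out / "table2.csv"))
        timings["cea_scenarios"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        stage = "psa"
        boot_cfg = BootstrapConfig(n_reps=cfg.n_reps, seed=cfg.seed)
        draws = bootstrap_draws(ds, base_prog, boot_cfg)
        draw_frames = []
        for j, arm in enumerate(draws.arms):
            frame = pd.DataFrame({"replicate": range(draws.n_reps), "arm": arm})
            frame["cost"] = draws.costs[:, j]
            for k, name in enumerate(draws.outcome_names):
                frame[f"{name}_oriented"] = draws.effects[:, j, k]
            draw_frames.append(frame)
        manifest["outputs"]["psa_draws"] = _record(
            _write_csv(pd.concat(draw_frames, ignore_index=True), out / "psa_draws.csv")
        )
        quad_rows = []
        for ref, comp in (("home", "web"), ("control", "home")):
            if ref in draws.arms and comp in draws.arms:
                for name in draws.outcome_names:
                    plane = ce_plane(draws, ref, comp, name)
                    quad_rows.append(
                        {"reference": ref, "comparator": comp, "outcome": name, **plane.quadrants}
                    )
        manifest["outputs"]["ce_plane_quadrants"] = _record(
            _write_csv(pd.DataFrame(quad_rows), out / "ce_plane_quadrants.csv")
        )
        for name in draws.outcome_names:
            curve = ceac(draws, default_wtp_grid(), name)
            manifest["outputs"][f"ceac_{name}"] = _record(
                _write_csv(
                    curve.probabilities.reset_index(), out / f"ceac_{name}.csv"
                )
            )
        manifest["psa"] = {
            "n_reps": cfg.n_reps,
            "n_failed": draws.n_failed,
            "n_flagged": int(draws.flagged.sum()),
        }
        if cfg.make_plots:
            _make_plots(draws, out, manifest, _record)
        timings["psa"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        stage = "budget_projection"
        table3 = project(default_projection_spec())
        manifest["outputs"]["table3"] = _record(
            _write_csv(table3.table, out / "table3.csv")
        )
        manifest["projection_savings"] = {
            "web_vs_control_100pct_year5": reduced_cost(table3, "web", "control", 1.0, 5),
            "web_vs_home_100pct_year5": reduced_cost(table3, "web", "home", 1.0, 5),
        }
        timings["budget_projection"] = time.perf_counter() - t0

        manifest["timings_s"] = {k: round(v, 3) for k, v in timings.items()}
        manifest_path = out / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
        manifest["manifest_path"] = str(manifest_path)
        return manifest
    except Exception as exc:
        for p in written:
            Path(p).unlink(missing_ok=True)
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc


def _make_plots(draws, out: Path, manifest: dict, record) -> None:
    """Optional CE-plane / CEAC figures (headless-safe; tables stay authoritative)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for ref, comp in (("home", "web"), ("control", "home")):
        if ref not in draws.arms or comp not in draws.arms:
            continue
        fig, axes = plt.subplots(2, 2, figsize=(9, 7))
        for ax, name in zip(axes.ravel(), draws.outcome_names):
            plane = ce_plane(draws, ref, comp, name)
            ax.scatter(plane.delta_effect, plane.delta_cost, s=4, alpha=0.3)
            ax.axhline(0, lw=0.6, color="k")
            ax.axvline(0, lw=0.6, color="k")
            ax.set_title(f"{comp} vs {ref}: {name}")
            ax.set_xlabel("incremental effect (oriented)")
            ax.set_ylabel("incremental cost (SGD)")
        fig.tight_layout()
        path = out / f"ce_plane_{comp}_vs_{ref}.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        manifest["outputs"][f"ce_plane_{comp}_vs_{ref}"] = record(path)

    fig, axes = plt.subplots(2, 2, figsize=(9, 7))
    for ax, name in zip(axes.ravel(), draws.outcome_names):
        curve = ceac(draws, default_wtp_grid(), name)
        for arm in draws.arms:
            ax.plot(curve.wtp, curve.probabilities[arm], label=arm)
        ax.set_ylim(0, 1)
        ax.set_title(name)
        ax.set_xlabel("willingness to pay (SGD / score)")
        ax.set_ylabel("P(cost-effective)")
    axes[0, 0].legend()
    fig.tight_layout()
    path = out / "ceac.png"
    fig.savefig(path, dpi=110)
    plt.close(fig)
    manifest["outputs"]["ceac_plot"] = record(path)
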