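"""Carbon/nitrogen uptake scenarios and the C/N-ratio sweep.

Three scenarios probe the switch from carbon- to nitrogen-limited growth:

* s1 — bicarbonate uptake rises stepwise, nitrate constant; excess carbon can
  only leave through the DMSP demand, excess nitrogen through nitrate storage.
* s2 — as s1, but nitrate supply ramps up once carbon uptake reaches a
  threshold, so nitrogen never becomes limiting and no DMSP is released.
* s3 — DMSP closed; excess carbon must be stored via the TAG or
  chrysolaminarin demands (parsimonious FBA picks the cheaper TAG route).
* cn_sweep — s1-style sweep reporting biomass against the carbon/nitrogen
  uptake ratio and locating the limitation breakpoint.

Forced uptake at each step uses equality bounds (uptake negative).  The
breakpoint is the last grid point at which biomass still increased, i.e. the
start of the plateau; its resolution is one grid step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .fba import parsimonious
from .model import MetabolicModel

__all__ = ["ScenarioSpec", "ScenarioResult", "run_scenario", "cn_sweep"]

#: biomass increase below this counts as stagnation
TOL_FLAT = 1e-8


@dataclass
class ScenarioSpec:
    scenario: str  # s1 | s2 | s3 | cn_sweep
    carbon_rxn: str = "EX_hco3_e"
    nitrogen_rxn: str = "EX_no3_e"
    carbon_grid: list[float] = field(default_factory=list)
    nitrogen_base: float = 0.535
    nitrogen_rule: str = "constant"  # or "ramp_after_threshold"
    ramp_threshold: float | None = None
    ramp_step: float | None = None
    open_demands: set[str] = field(default_factory=set)
    closed_demands: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if list(self.carbon_grid) != sorted(self.carbon_grid) or len(
            set(self.carbon_grid)
        ) != len(self.carbon_grid):
            raise ValueError("carbon_grid must be strictly increasing")
        if self.nitrogen_rule == "ramp_after_threshold":
            if self.ramp_threshold is None or self.ramp_step is None:
                raise ValueError(
                    "ramp_threshold and ramp_step are required for the ramp rule"
                )
        elif self.nitrogen_rule != "constant":
            raise ValueError(f"unknown nitrogen_rule: {self.nitrogen_rule!r}")


@dataclass
class ScenarioResult:
    spec: ScenarioSpec
    steps: pd.DataFrame  # one row per grid point
    breakpoint_carbon: float | None
    breakpoint_cn_ratio: float | None

    def demand_flux(self, demand_id: str) -> pd.Series:
        return self.steps[demand_id]


def _nitrogen_at(spec: ScenarioSpec, grid_index: int) -> float:
    if spec.nitrogen_rule == "constant":
        return spec.nitrogen_base
    count = sum(
        1 for u in spec.carbon_grid[: grid_index + 1] if u >= spec.ramp_threshold
    )
    return spec.nitrogen_base + spec.ramp_step * count


def run_scenario(
    model: MetabolicModel, spec: ScenarioSpec, tol_flat: float = TOL_FLAT
) -> ScenarioResult:
    """Sweep the carbon grid, solving parsimoniously at each forced uptake."""
    for rid in (spec.carbon_rxn, spec.nitrogen_rxn):
        if not model.has_reaction(rid):
            raise KeyError(f"scenario uptake reaction not in model: {rid}")
    demands = sorted(spec.open_demands | spec.closed_demands)
    missing = [d for d in demands if not model.has_reaction(d)]
    if missing:
        raise KeyError(f"scenario demand reactions not in model: {missing}")

    work = model.copy()
    for did in spec.open_demands:
        work.set_bounds(did, 0.0, 1000.0)
    for did in spec.closed_demands:
        work.set_bounds(did, 0.0, 0.0)

    rows = []
    for i, u_c in enumerate(spec.carbon_grid):
        u_n = _nitrogen_at(spec, i)
        work.set_bounds(spec.carbon_rxn, -u_c, -u_c)
        work.set_bounds(spec.nitrogen_rxn, -u_n, -u_n)
        sol = parsimonious(work)
        if not sol.ok:
            raise RuntimeError(
                f"scenario {spec.scenario} step {i} (carbon {u_c}): {sol.status}"
            )
        row = {
            "carbon_uptake": u_c,
            "nitrogen_uptake": u_n,
            "cn_ratio": u_c / u_n if u_n else float("inf"),
            "biomass": sol.objective_value,
        }
        for did in demands:
            row[did] = sol.fluxes[did]
        rows.append(row)
    steps = pd.DataFrame(rows)

    breakpoint_carbon = breakpoint_ratio = None
    biomass = steps["biomass"].to_numpy()
    for i in range(1, len(biomass)):
        if biomass[i] - biomass[i - 1] < tol_flat:
            breakpoint_carbon = float(steps["carbon_uptake"].iloc[i - 1])
            breakpoint_ratio = float(steps["cn_ratio"].iloc[i - 1])
            break
    return ScenarioResult(spec, steps, breakpoint_carbon, breakpoint_ratio)


def cn_sweep(model: MetabolicModel, spec: ScenarioSpec) -> ScenarioResult:
    """Biomass versus C/N uptake ratio at constant nitrogen supply."""
    if spec.nitrogen_rule != "constant":
        raise ValueError("cn_sweep requires a constant nitrogen supply")
    return run_scenario(model, spec)


def write_scenario_tsv(result: ScenarioResult, path) -> None:
    result.steps.to_csv(path, sep="\t", index=False, float_format="%.10g")


def scenario_summary(result: ScenarioResult) -> dict:
    return {
        "scenario": result.spec.scenario,
        "n_steps": int(len(result.steps)),
        "breakpoint_carbon": result.breakpoint_carbon,
        "breakpoint_cn_ratio": result.breakpoint_cn_ratio,
        "final_biomass": float(result.steps["biomass"].iloc[-1]),
    }
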