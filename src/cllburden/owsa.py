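"""One-way sensitivity analysis (tornado).

Each eligible parameter is varied to 0.75x and 1.25x its base value (one at
a time, baseline restored between parameters), the projection is re-run with
calibration frozen at its baseline values, and the total 2011-2025 cost for
the scenario is recorded; records are ordered by spread for a tornado
diagram.  Survival summaries, discontinuation probabilities and the
calibrated quantities (WW-exit probability, hazard multiplier) are excluded:
they are fixed by calibration, not free inputs.

Probabilities are clamped to [0, 1] when scaled.  Scaling one category of a
probability simplex (an age band, or mutated-IGHV share) renormalizes the
complementary categories proportionally so masses still sum to 1.
"""

from __future__ import annotations

import pandas as pd

from .config import ModelConfig
from .engine import Engine

__all__ = ["eligible_parameters", "get_path", "scale_path", "run_owsa", "total_cost"]

_STRAT_PROBS = ("p_ww", "p_del17p", "p_ighv_mut")
_COST_SCALARS = (
    "infusion_cost", "consult_hematology", "partial_assessment",
    "nurse_per_min", "pharmacist_per_min", "infusions_per_cycle",
    "nurse_min_per_infusion", "pharmacist_min_per_cycle", "ww_followup_per_year",
)
_COST_MAPS = ("lab_panel_costs", "ae_unit_costs", "monitoring_frequency_per_cycle",
              "start_panels")
_REGIMEN_COST_FIELDS = ("cost_cycle1", "cost_cycles_2_6", "cost_cycle2",
                        "cost_cycles_3_6", "cost_continuing")


def eligible_parameters(config: ModelConfig) -> list[str]:
    """Stable string paths of every parameter the tornado sweep varies."""
    paths: list[str] = [f"strat.{p}" for p in _STRAT_PROBS]
    paths += [f"strat.age_probs.{band}" for band in config.strat.age_probs]
    paths += [
        f"strat.fitness_probs.{band}"
        for band, v in config.strat.fitness_probs.items()
        if v > 0  # the >70 band is structurally unfit
    ]
    paths += [f"costs.{name}" for name in _COST_SCALARS]
    for mapping in _COST_MAPS:
        paths += [f"costs.{mapping}.{k}" for k in getattr(config.costs, mapping)]
    names: dict[str, None] = {}
    for line in ("first_line", "relapse"):
        for name in config.regimens.get(line, {}):
            names[name] = None
    for name in names:
        fields: dict[str, None] = {}
        aes: dict[str, None] = {}
        for line in ("first_line", "relapse"):
            spec = config.regimens.get(line, {}).get(name)
            if spec is None:
                continue
            for f in _REGIMEN_COST_FIELDS:
                if getattr(spec, f) is not None:
                    fields[f] = None
            for ae in spec.ae_profile:
                aes[ae] = None
        paths += [f"regimens.{name}.{f}" for f in fields]
        paths += [f"regimens.{name}.ae_profile.{ae}" for ae in aes]
    return paths


def get_path(config: ModelConfig, path: str) -> float:
    """Base value at a parameter path (first matching line entry for regimens)."""
    parts = path.split(".")
    if parts[0] == "strat":
        obj = getattr(config.strat, parts[1])
        return float(obj[parts[2]]) if len(parts) == 3 else float(obj)
    if parts[0] == "costs":
        obj = getattr(config.costs, parts[1])
        return float(obj[parts[2]]) if len(parts) == 3 else float(obj)
    if parts[0] == "regimens":
        name = parts[1]
        for line in ("first_line", "relapse"):
            spec = config.regimens.get(line, {}).get(name)
            if spec is None:
                continue
            if parts[2] == "ae_profile":
                if parts[3] in spec.ae_profile:
                    return float(spec.ae_profile[parts[3]])
            else:
                v = getattr(spec, parts[2])
                if v is not None:
                    return float(v)
        raise KeyError(path)
    raise KeyError(path)


def _clamp01(v: float) -> float:
    return min(1.0, max(0.0, v))


def scale_path(config: ModelConfig, path: str, factor: float) -> ModelConfig:
    """Return a new config with the parameter at ``path`` scaled by ``factor``.

    Pure with respect to the input config.  Regimen-level paths scale every
    line entry of that regimen name jointly (same drug, same price scaling).
    """
    data = config.model_dump()
    parts = path.split(".")
    if parts[0] == "strat":
        strat = data["strat"]
        if parts[1] == "age_probs":
            _scale_simplex(strat["age_probs"], parts[2], factor)
        elif parts[1] == "fitness_probs":
            strat["fitness_probs"][parts[2]] = _clamp01(
                strat["fitness_probs"][parts[2]] * factor
            )
        elif parts[1] == "p_ighv_mut":
            new = _clamp01(strat["p_ighv_mut"] * factor)
            strat["p_ighv_mut"] = new
            strat["p_ighv_unmut"] = 1.0 - new
        elif parts[1] in ("p_ww", "p_del17p", "p_ww_exit_cycle",
                          "p_discont_l1", "p_discont_rel"):
            strat[parts[1]] = _clamp01(strat[parts[1]] * factor)
        else:
            strat[parts[1]] = strat[parts[1]] * factor
    elif parts[0] == "costs":
        costs = data["costs"]
        if len(parts) == 3:
            costs[parts[1]][parts[2]] = costs[parts[1]][parts[2]] * factor
        else:
            costs[parts[1]] = costs[parts[1]] * factor
    elif parts[0] == "regimens":
        name = parts[1]
        applied = False
        for line in ("first_line", "relapse"):
            entry = data["regimens"].get(line, {}).get(name)
            if entry is None:
                continue
            if parts[2] == "ae_profile":
                if parts[3] in entry["ae_profile"]:
                    entry["ae_profile"][parts[3]] = _clamp01(
                        entry["ae_profile"][parts[3]] * factor
                    )
                    applied = True
            elif entry.get(parts[2]) is not None:
                entry[parts[2]] = entry[parts[2]] * factor
                applied = True
        if not applied:
            raise KeyError(path)
    else:
        raise KeyError(path)
    return ModelConfig.model_validate(data)


def _scale_simplex(mapping: dict[str, float], key: str, factor: float) -> None:
    old = mapping[key]
    total = sum(mapping.values())
    new = min(total, max(0.0, old * factor))
    rest = total - old
    for k in mapping:
        if k == key:
            mapping[k] = new
        elif rest > 0:
            mapping[k] *= (total - new) / rest
        else:
            mapping[k] = (total - new) / (len(mapping) - 1)


def total_cost(
    config: ModelConfig, scenario: str, mode: str = "cumulative"
) -> float:
    """Scenario outcome for the sweep: total reported cost (2011-2025 by default)."""
    out = Engine(config, scenario).run(collect_costs=True)
    ledger = out.ledger
    if mode == "annual":
        ledger = ledger[ledger["year"] == config.strat.report_end_year]
    elif mode != "cumulative":
        raise ValueError("mode must be 'cumulative' or 'annual'")
    return float(ledger["dollars"].sum())


def run_owsa(
    config: ModelConfig,
    scenario: str,
    parameters: list[str] | None = None,
    variation: float = 0.25,
    mode: str = "cumulative",
) -> pd.DataFrame:
    """Tornado records: one row per parameter, sorted by spread descending.

    A failed variation run is recorded in the ``error`` column for that
    parameter instead of aborting the sweep.
    """
    params = parameters if parameters is not None else eligible_parameters(config)
    base_total = total_cost(config, scenario, mode)
    rows = []
    for path in params:
        row = {
            "parameter": path,
            "base_value": float("nan"),
            "base_total": base_total,
            "low_total": float("nan"),
            "high_total": float("nan"),
            "spread": float("nan"),
            "scenario": scenario,
            "error": "",
        }
        try:
            row["base_value"] = get_path(config, path)
            low = total_cost(scale_path(config, path, 1.0 - variation), scenario, mode)
            high = total_cost(scale_path(config, path, 1.0 + variation), scenario, mode)
            row.update(low_total=low, high_total=high, spread=abs(high - low))
        except Exception as exc:  # noqa: BLE001 - per-parameter failures are data
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.sort_values("spread", ascending=False, kind="mergesort").reset_index(drop=True)
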