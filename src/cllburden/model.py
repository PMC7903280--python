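"""Model / Results interface.

``CLLBurdenModel`` wraps a validated configuration; ``fit`` runs the
(optionally calibrated) projection for one or both scenarios and returns a
``CLLBurdenResults`` carrying the annual censuses, the cost ledger, derived
report tables and a text ``summary()``.  Sensitivity analysis and plotting
hang off these two objects.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .calibration import CalibrationResult, calibrate_survival_adjustment
from .config import ModelConfig, default_config, load_config, validate_config
from .costs import aggregate
from .engine import Engine, ProjectionOutput
from .owsa import run_owsa

SCENARIO_ORDER = ("CIT", "OTT")

__all__ = ["CLLBurdenModel", "CLLBurdenResults", "ScenarioRun"]


@dataclass
class ScenarioRun:
    output: ProjectionOutput
    calibration: CalibrationResult | None = None


class CLLBurdenModel:
    """Markov cohort model of CLL prevalence and cost burden in Canada.

    Parameters
    ----------
    config
        A validated :class:`~cllburden.config.ModelConfig`; defaults to the
        shipped parameter set (all published model and cost parameters plus
        synthetic epidemiology settings).
    """

    def __init__(self, config: ModelConfig | None = None):
        self.config = config if config is not None else default_config()
        self.warnings = validate_config(self.config)

    @classmethod
    def from_yaml(cls, path) -> "CLLBurdenModel":
        return cls(load_config(path))

    def calibrate(
        self, scenario: str = "CIT", target: float | None = None
    ) -> CalibrationResult:
        """Fit the global hazard multiplier to a 2011 prevalence target."""
        if target is None:
            key = f"prevalence_2011_{scenario.lower()}"
            targets = self.config.scenario.calibration_targets
            if key not in targets:
                raise KeyError(f"no calibration target {key!r} in config")
            target = targets[key]
        return calibrate_survival_adjustment(self.config, target, scenario=scenario)

    def fit(
        self,
        scenario: str = "both",
        calibrate: bool = False,
        hazard_multiplier: float | None = None,
    ) -> "CLLBurdenResults":
        """Run the projection and return results.

        With ``calibrate=True`` the hazard multiplier is first fitted to the
        scenario's 2011 prevalence target; otherwise the configured (default
        1.0) or explicitly passed multiplier is used.
        """
        if scenario == "both":
            wanted = list(SCENARIO_ORDER)
        elif scenario.upper() in SCENARIO_ORDER:
            wanted = [scenario.upper()]
        else:
            raise ValueError("scenario must be 'OTT', 'CIT' or 'both'")
        runs: dict[str, ScenarioRun] = {}
        for sc in wanted:
            calib = None
            m = hazard_multiplier
            if calibrate:
                calib = self.calibrate(scenario=sc)
                m = calib.hazard_multiplier
            output = Engine(self.config, sc, m).run()
            runs[sc] = ScenarioRun(output=output, calibration=calib)
        return CLLBurdenResults(config=self.config, runs=runs)

    def sensitivity(
        self,
        scenario: str = "OTT",
        parameters: list[str] | None = None,
        variation: float = 0.25,
        mode: str = "cumulative",
    ) -> pd.DataFrame:
        """One-way sensitivity sweep; see :func:`cllburden.owsa.run_owsa`."""
        return run_owsa(
            self.config, scenario.upper(), parameters=parameters,
            variation=variation, mode=mode,
        )


@dataclass
class CLLBurdenResults:
    """Projection results for one or both scenarios."""

    config: ModelConfig
    runs: dict[str, ScenarioRun] = field(default_factory=dict)

    # ------------------------------------------------------------------ #
    # report tables

    def _report_years(self, df: pd.DataFrame) -> pd.DataFrame:
        strat = self.config.strat
        return df[
            (df["year"] >= strat.report_start_year) & (df["year"] <= strat.report_end_year)
        ].reset_index(drop=True)

    @property
    def censuses(self) -> pd.DataFrame:
        return self._report_years(
            pd.concat([r.output.censuses for r in self.runs.values()], ignore_index=True)
        )

    @property
    def prevalence(self) -> pd.DataFrame:
        """Annual prevalence per scenario (excluding and including WW)."""
        cols = ["year", "scenario", "alive_excl_ww", "alive_incl_ww"]
        return self.censuses[cols]

    @property
    def ledger(self) -> pd.DataFrame:
        return self._report_years(
            pd.concat([r.output.ledger for r in self.runs.values()], ignore_index=True)
        )

    @property
    def costs(self) -> pd.DataFrame:
        """Annual cost report: totals, by line, per patient."""
        return aggregate(self.ledger, self.censuses)

    @property
    def per_patient(self) -> pd.DataFrame:
        return self.costs[["scenario", "year", "total_cost", "alive_incl_ww",
                           "cost_per_patient"]]

    @property
    def scenario_diff(self) -> pd.DataFrame:
        """Annual and cumulative OTT - CIT total-cost difference."""
        if set(self.runs) < {"OTT", "CIT"}:
            raise ValueError("scenario_diff requires both scenarios")
        costs = self.costs.pivot(index="year", columns="scenario", values="total_cost")
        out = pd.DataFrame(
            {
                "year": costs.index,
                "cost_ott": costs["OTT"].to_numpy(),
                "cost_cit": costs["CIT"].to_numpy(),
            }
        )
        out["diff"] = out["cost_ott"] - out["cost_cit"]
        out["cumulative_diff"] = out["diff"].cumsum()
        return out.reset_index(drop=True)

    @property
    def stratum_census(self) -> pd.DataFrame:
        return self._report_years(
            pd.concat(
                [r.output.stratum_census for r in self.runs.values()], ignore_index=True
            )
        )

    # ------------------------------------------------------------------ #

    def summary(self) -> str:
        strat = self.config.strat
        y0, y1 = strat.report_start_year, strat.report_end_year
        lines = [
            "CLL burden projection (Markov cohort model)",
            "=" * 60,
            f"Report window: {y0}-{y1}   cycle: {strat.cycle_days:g} days",
        ]
        costs = self.costs
        for sc, run in self.runs.items():
            m = run.output.hazard_multiplier
            lines.append("")
            lines.append(f"Scenario {sc}   (hazard multiplier {m:.4g})")
            lines.append("-" * 60)
            sub = costs[costs["scenario"] == sc].set_index("year")
            p = self.prevalence.set_index(["scenario", "year"])
            for y in (y0, y1):
                r = sub.loc[y]
                lines.append(
                    f"  {y}: prevalence (excl. WW) {p.loc[(sc, y), 'alive_excl_ww']:,.0f}"
                    f" | total cost ${r['total_cost'] / 1e6:,.1f}M"
                    f" | per patient ${r['cost_per_patient']:,.0f}"
                )
            fold_prev = p.loc[(sc, y1), "alive_excl_ww"] / p.loc[(sc, y0), "alive_excl_ww"]
            fold_cost = sub.loc[y1, "total_cost"] / sub.loc[y0, "total_cost"]
            lines.append(
                f"  fold change {y0}->{y1}: prevalence {fold_prev:.2f}x, cost {fold_cost:.2f}x"
            )
        if set(self.runs) >= {"OTT", "CIT"}:
            diff = self.scenario_diff
            lines.append("")
            lines.append(
                f"Cumulative OTT-CIT cost difference {y0}-{y1}: "
                f"${diff['cumulative_diff'].iloc[-1] / 1e9:,.2f}B"
            )
        return "\n".join(lines)

    def save(self, outdir, seed: int | None = None) -> list[str]:
        """Write the report CSVs and a run manifest; returns written paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        files: list[str] = []

        def write(df: pd.DataFrame, name: str) -> None:
            path = outdir / name
            df.to_csv(path, index=False)
            files.append(str(path))

        write(self.prevalence, "prevalence.csv")
        write(self.ledger, "costs.csv")
        write(self.costs, "cost_report.csv")
        write(self.per_patient, "per_patient.csv")
        write(self.stratum_census, "stratum_census.csv")
        if set(self.runs) >= {"OTT", "CIT"}:
            write(self.scenario_diff, "scenario_diff.csv")
        config_yaml = yaml.safe_dump(self.config.model_dump(), sort_keys=True)
        manifest = {
            "package": "cllburden",
            "version": __version__,
            "config_sha256": hashlib.sha256(config_yaml.encode()).hexdigest(),
            "seed": seed if seed is not None else self.config.scenario.rng_seed,
            "scenarios": sorted(self.runs),
            "hazard_multipliers": {
                sc: run.output.hazard_multiplier for sc, run in self.runs.items()
            },
            "timestamp": datetime.now(timezone.utc).isoformat(),
            "outputs": [Path(f).name for f in files],
        }
        manifest_path = outdir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
        files.append(str(manifest_path))
        return files
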