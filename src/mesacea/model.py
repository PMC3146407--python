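"""Model and results objects for the mesalazine cost-effectiveness analysis.

:class:`MarkovCEModel` wraps a validated :class:`~mesacea.parameters.ParameterBundle`;
``fit()`` evaluates the deterministic Markov cohort model for both arms and
returns a :class:`MarkovCEResults` carrying traces, per-arm outcomes, the
incremental comparison and a formatted summary table.  Probabilistic and
one-way sensitivity analyses hang off the model.

Example
-------
>>> from mesacea import MarkovCEModel
>>> res = MarkovCEModel.base_case().fit()
>>> print(res.summary())            # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortTrace, run_cohort
from .costing import build_state_cost_table, discount_factors
from .outcomes import ArmResults, CEResult, arm_results, incremental_analysis
from .parameters import ASACOL, MEZAVANT, ParameterBundle


class MarkovCEModel:
    """Markov cohort cost-effectiveness model comparing two mesalazine arms."""

    def __init__(
        self,
        bundle: ParameterBundle,
        intervention: str = MEZAVANT,
        comparator: str = ASACOL,
    ) -> None:
        bundle.validate()
        self.bundle = bundle
        self.intervention = intervention
        self.comparator = comparator

    # -- constructors ------------------------------------------------------

    @classmethod
    def base_case(cls, **config_overrides) -> "MarkovCEModel":
        """Model on the bundled German SHI 2009 base case."""
        from .synthetic import make_base_case

        bundle = make_base_case()
        for key, value in config_overrides.items():
            if not hasattr(bundle.config, key):
                raise AttributeError(f"unknown config field {key!r}")
            setattr(bundle.config, key, value)
        return cls(bundle)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MarkovCEModel":
        return cls(ParameterBundle.from_yaml(path))

    # -- estimation --------------------------------------------------------

    def fit(self) -> "MarkovCEResults":
        """Run the deterministic cohort model for both arms."""
        traces: dict[str, CohortTrace] = {}
        results: dict[str, ArmResults] = {}
        for name in (self.intervention, self.comparator):
            trace = run_cohort(self.bundle, name)
            table = build_state_cost_table(
                self.bundle.arms[name], self.bundle.costs, self.bundle.config
            )
            traces[name] = trace
            results[name] = arm_results(
                trace, table, self.bundle.utilities, self.bundle.config
            )
            results[name].validate(
                trace.n_cycles * self.bundle.config.cycle_years
            )
        incremental = incremental_analysis(
            results[self.intervention], results[self.comparator]
        )
        return MarkovCEResults(
            model=self, traces=traces, arm_results=results, incremental=incremental
        )

    # -- sensitivity analyses ----------------------------------------------

    def run_psa(self, n_iter: int = 10_000, seed: int | None = None, **kwargs):
        """Probabilistic sensitivity analysis; see :func:`mesacea.sensitivity.run_psa`."""
        from .sensitivity import run_psa

        if seed is None:
            seed = self.bundle.config.random_seed
        return run_psa(self.bundle, n_iter=n_iter, seed=seed, **kwargs)

    def run_owsa(self, param_id: str, bounds: tuple[float, float], steps: int = 6):
        """One-way sensitivity analysis; see :func:`mesacea.sensitivity.run_owsa`."""
        from .sensitivity import run_owsa

        return run_owsa(self.bundle, param_id, bounds, steps)


@dataclass
class MarkovCEResults:
    """Deterministic results: traces, per-arm outcomes, incremental analysis."""

    model: MarkovCEModel
    traces: dict[str, CohortTrace]
    arm_results: dict[str, ArmResults]
    incremental: CEResult

    # -- views -------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Base-case summary table, one row per arm."""
        rows = []
        for name, res in self.arm_results.items():
            rows.append(
                {
                    "arm": name,
                    "cost_eur": res.discounted_cost,
                    "qalys": res.discounted_qalys,
                    "remission_days": res.remission_days,
                    "inpatient_episodes": res.inpatient_episodes,
                    "surgeries": res.surgeries,
                }
            )
        return pd.DataFrame(rows).set_index("arm")

    def summary(self) -> str:
        """Human-readable summary (costs to whole euros, QALYs to 3 d.p.)."""
        inc = self.incremental
        df = self.to_frame()
        lines = [
            "Markov cohort cost-effectiveness analysis "
            f"({self.model.bundle.config.horizon}, "
            f"{self.traces[inc.intervention].n_cycles} cycles of "
            f"{self.model.bundle.config.cycle_length_days:.0f} days, "
            f"discount {self.model.bundle.config.annual_discount_rate:.1%}/yr)",
            "",
            f"{'arm':<10}{'cost (EUR)':>12}{'QALYs':>9}{'rem. days':>11}"
            f"{'episodes':>10}{'surgeries':>11}",
        ]
        for name, row in df.iterrows():
            lines.append(
                f"{name:<10}{row.cost_eur:>12,.0f}{row.qalys:>9.3f}"
                f"{row.remission_days:>11.0f}{row.inpatient_episodes:>10.3f}"
                f"{row.surgeries:>11.4f}"
            )
        icer = "NA" if inc.icer is None else f"{inc.icer:,.0f} EUR/QALY"
        lines += [
            "",
            f"incremental ({inc.intervention} - {inc.comparator}): "
            f"cost {inc.incremental_cost:+,.0f} EUR, QALYs {inc.incremental_qalys:+.3f}",
            f"conclusion: {inc.label} (cost per QALY: {icer})",
        ]
        return "\n".join(lines)

    # -- exports -----------------------------------------------------------

    def trace_frame(self, arm: str) -> pd.DataFrame:
        """Logical-state trace with discounted per-cycle cost/QALY columns."""
        trace = self.traces[arm]
        bundle = self.model.bundle
        table = build_state_cost_table(bundle.arms[arm], bundle.costs, bundle.config)
        cvec = table.cost_vector(trace.space)
        from .outcomes import _accrual_occupancy, utility_vector

        uvec = utility_vector(bundle.utilities, trace)
        occ = _accrual_occupancy(trace, bundle.config)
        dfac = discount_factors(bundle.config, trace.n_cycles)
        frame = trace.to_frame()
        per_cost = np.zeros(trace.n_cycles + 1)
        per_q = np.zeros(trace.n_cycles + 1)
        per_cost[: trace.n_cycles] = (occ @ cvec) * dfac
        per_q[: trace.n_cycles] = (occ @ uvec) * dfac * bundle.config.cycle_years
        frame["discounted_cost_eur"] = per_cost
        frame["discounted_qalys"] = per_q
        return frame

    def export_traces(self, directory: str | Path) -> list[Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for arm in self.traces:
            path = directory / f"trace_{arm.lower()}.csv"
            self.trace_frame(arm).to_csv(path, index=False)
            paths.append(path)
        return paths
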