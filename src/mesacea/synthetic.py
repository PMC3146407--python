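"""Synthetic inputs: base-case bundle, pseudo-trials, life table, scenarios.

Everything the pipeline consumes can be generated here without any
download: the fully transcribed base-case parameter bundle, binomial
pseudo-trials with the statistical structure the PSA assumes for remission
rates, a synthetic Gompertz life table standing in for official
age-specific all-cause mortality, and seeded perturbed scenario sets for
stress testing.  Generated artifacts pass exactly the same validators as
user-supplied input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .parameters import LifeTable, ParameterBundle, ParameterError
from .sensitivity import apply_parameter, parameter_ids

log = logging.getLogger(__name__)


def make_base_case() -> ParameterBundle:
    """The German SHI 2009 base case (all printed inputs), validated."""
    bundle = ParameterBundle()
    bundle.validate()
    return bundle


@dataclass(frozen=True)
class PseudoTrial:
    """A simulated binomial remission trial arm with its beta posterior."""

    arm_label: str
    n_enrolled: int
    n_remission: int

    @property
    def posterior_alpha(self) -> float:
        return self.n_remission + 1.0

    @property
    def posterior_beta(self) -> float:
        return self.n_enrolled - self.n_remission + 1.0

    @property
    def posterior_mean(self) -> float:
        return self.posterior_alpha / (self.posterior_alpha + self.posterior_beta)


def simulate_trial(
    true_rate: float,
    n: int,
    seed: int | np.random.Generator | None = None,
    arm_label: str = "",
) -> PseudoTrial:
    """Simulate one binomial trial arm; posterior is beta(s+1, n-s+1)."""
    if not 0.0 <= true_rate <= 1.0:
        raise ParameterError("true_rate must be in [0, 1]")
    if n < 1:
        raise ParameterError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    successes = int(rng.binomial(n, true_rate))
    return PseudoTrial(arm_label=arm_label, n_enrolled=n, n_remission=successes)


# Gompertz defaults: a synthetic approximation to adult all-cause
# mortality in a high-income country, calibrated so the annual death
# probability at the cohort start age (43) is of order 2e-3.  NOT official
# national data; substitute a real life-table file for policy use.
GOMPERTZ_B = 4.2e-5
GOMPERTZ_C = 0.09


def make_life_table(
    b: float = GOMPERTZ_B,
    c: float = GOMPERTZ_C,
    age_min: int = 0,
    age_max: int = 110,
) -> LifeTable:
    """Synthetic Gompertz life table: q(a) = 1 - exp(-b * exp(c * a))."""
    if b < 0 or c <= 0:
        raise ParameterError("Gompertz parameters must be positive")
    ages = np.arange(age_min, age_max + 1)
    q = 1.0 - np.exp(-b * np.exp(c * ages))
    return LifeTable(ages, np.clip(q, 0.0, 1.0))


@dataclass
class Scenario:
    name: str
    bundle: ParameterBundle
    perturbation: dict[str, float]
    seed: int | None


def perturb_scenarios(
    base: ParameterBundle,
    relative_ranges: dict[str, float],
    count: int,
    seed: int | None = None,
) -> list[Scenario]:
    """Seeded uniform multiplicative perturbations of named parameters.

    ``relative_ranges`` maps parameter ids (see
    :func:`mesacea.sensitivity.parameter_ids`) to a +/- relative half-width;
    perturbed values escaping the parameter's support are clipped and
    logged.  Every returned bundle passes full validation.
    """
    base.validate()
    unknown = set(relative_ranges) - set(parameter_ids())
    if unknown:
        raise ParameterError(f"unknown parameter ids: {sorted(unknown)}")
    base_values = _current_values(base, relative_ranges)
    rng = np.random.default_rng(seed)
    scenarios: list[Scenario] = []
    for i in range(count):
        bundle = base.copy()
        applied: dict[str, float] = {}
        for pid, half_width in relative_ranges.items():
            factor = 1.0 + rng.uniform(-half_width, half_width)
            value = base_values[pid] * factor
            clipped = min(max(value, 0.0), 1.0) if _is_probability(pid) else max(value, 0.0)
            if clipped != value:
                log.warning("scenario %d: %s clipped to %g", i, pid, clipped)
            apply_parameter(bundle, pid, clipped)
            applied[pid] = clipped
        bundle.validate()
        scenarios.append(
            Scenario(name=f"perturbed_{i:04d}", bundle=bundle, perturbation=applied, seed=seed)
        )
    return scenarios


def _is_probability(pid: str) -> bool:
    return not (pid.startswith("cost.") or pid.startswith("price."))


def _current_values(bundle: ParameterBundle, ids) -> dict[str, float]:
    vals = {}
    for pid in ids:
        head, _, tail = pid.partition(".")
        if head in ("p_remit_1l", "p_remit_1l_high", "p_relapse") and tail in bundle.arms:
            vals[pid] = getattr(bundle.transitions, head)[tail]
        elif head == "p_relapse" and tail == "BOTH":
            vals[pid] = bundle.transitions.p_relapse["MEZAVANT"]
        elif head == "cost":
            vals[pid] = getattr(bundle.costs, tail)
        elif head == "price":
            vals[pid] = bundle.arms[tail].price_per_tablet_eur
        elif head == "utility":
            vals[pid] = getattr(bundle.utilities, tail)
        else:
            vals[pid] = getattr(bundle.transitions, head)
    return vals
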