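"""Parameter containers for the mesalazine cost-effectiveness model.

Every dataclass default is the German SHI 2009 base case: transition
probabilities from the pivotal induction trial and its open-label
extension, long-term maintenance from a one-year head-to-head maintenance
study with a 1 %/year relapse-probability decrement per additional year in
remission, utilities elicited by TTO/EQ-5D from 151 UC patients, and unit
costs (reference drug prices net of rebates and co-payments, EBM quarterly
lump sum, revalued outpatient procedures, DRG lump sums).

A :class:`ParameterBundle` groups everything, validates it, and round-trips
losslessly through YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .states import HealthState

MEZAVANT = "MEZAVANT"
ASACOL = "ASACOL"
ARM_NAMES = (MEZAVANT, ASACOL)


class ParameterError(ValueError):
    """A parameter value or combination is outside its support."""


def _check_prob(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ParameterError(f"{name} must be in [0, 1], got {value!r}")


def _check_arm_map(name: str, mapping: Mapping[str, float]) -> None:
    missing = set(ARM_NAMES) - set(mapping)
    if missing:
        raise ParameterError(f"{name} missing arms: {sorted(missing)}")
    for arm, v in mapping.items():
        _check_prob(f"{name}[{arm}]", v)


@dataclass
class TreatmentArm:
    """One mesalazine formulation with its dosing and net SHI price."""

    name: str
    tablet_strength_mg: int
    tablets_per_day_standard: int
    tablets_per_day_high: int
    price_per_tablet_eur: float
    #: maintenance dose during remission; both products' labelled standard
    #: maintenance is the 2,400 mg/day regimen.
    tablets_per_day_maintenance: int | None = None

    def __post_init__(self) -> None:
        if self.tablets_per_day_maintenance is None:
            self.tablets_per_day_maintenance = self.tablets_per_day_standard

    def validate(self) -> None:
        if self.tablets_per_day_standard * self.tablet_strength_mg != 2400:
            raise ParameterError(
                f"{self.name}: standard dose must total 2,400 mg/day"
            )
        if self.tablets_per_day_high * self.tablet_strength_mg != 4800:
            raise ParameterError(f"{self.name}: high dose must total 4,800 mg/day")
        if self.price_per_tablet_eur <= 0:
            raise ParameterError(f"{self.name}: tablet price must be positive")


def default_arms() -> dict[str, TreatmentArm]:
    return {
        MEZAVANT: TreatmentArm(MEZAVANT, 1200, 2, 4, 1.13),
        ASACOL: TreatmentArm(ASACOL, 400, 6, 12, 0.44),
    }


@dataclass
class TransitionParameters:
    """All arm-specific and shared transition probabilities.

    ``p_relapse`` holds the remission→relapse probabilities on the time
    basis declared by ``relapse_basis``:

    ``"annual"`` (default)
        the values are annual probabilities, converted internally to the
        8-week cycle — the reading of the source model that reproduces its
        reported incremental results;
    ``"per_cycle"``
        the values are used verbatim per cycle, matching a literal reading
        of the published transition table.
    """

    p_remit_1l: dict[str, float] = field(
        default_factory=lambda: {MEZAVANT: 0.405, ASACOL: 0.326}
    )
    p_remit_1l_high: dict[str, float] = field(
        default_factory=lambda: {MEZAVANT: 0.615, ASACOL: 0.600}
    )
    p_remit_2l: float = 0.68
    #: remission probability for hospitalised (non-surgical) patients
    p_remit_hosp: float = 0.891
    #: share of hospitalised UC patients requiring surgery (German hospital
    #: statistics; the UK-audit admission share 0.258 is a scenario value)
    p_surgery_hosp: float = 0.109
    p_death_surgery: float = 0.021
    p_relapse: dict[str, float] = field(
        default_factory=lambda: {MEZAVANT: 0.065, ASACOL: 0.092}
    )
    relapse_basis: str = "annual"
    #: one-year maintenance rates behind the relapse values (kept for
    #: scenario work and documentation; not used directly by the base case)
    annual_maintenance: dict[str, float] = field(
        default_factory=lambda: {MEZAVANT: 0.622, ASACOL: 0.515}
    )
    #: relative reduction of the relapse probability per completed year in
    #: remission
    langholz_decrement_per_year: float = 0.01
    max_tunnel_years: int = 5

    def validate(self) -> None:
        _check_arm_map("p_remit_1l", self.p_remit_1l)
        _check_arm_map("p_remit_1l_high", self.p_remit_1l_high)
        _check_arm_map("p_relapse", self.p_relapse)
        _check_arm_map("annual_maintenance", self.annual_maintenance)
        for name in ("p_remit_2l", "p_remit_hosp", "p_surgery_hosp", "p_death_surgery"):
            _check_prob(name, getattr(self, name))
        if not self.p_remit_hosp + self.p_surgery_hosp == 1.0:
            # outgoing probabilities of the hospitalisation state must be
            # complementary; tolerate rounding at the 1e-9 level
            if abs(self.p_remit_hosp + self.p_surgery_hosp - 1.0) > 1e-9:
                raise ParameterError(
                    "p_remit_hosp and p_surgery_hosp must sum to 1"
                )
        if self.relapse_basis not in ("annual", "per_cycle"):
            raise ParameterError(f"unknown relapse_basis {self.relapse_basis!r}")
        if not 0.0 <= self.langholz_decrement_per_year <= 1.0:
            raise ParameterError("langholz_decrement_per_year must be in [0, 1]")
        if self.max_tunnel_years < 1:
            raise ParameterError("max_tunnel_years must be >= 1")


FIVE_YEARS = "five_years"
LIFELONG = "lifelong"


@dataclass
class ModelConfig:
    """Run configuration: cycle structure, horizon, discounting, mortality."""

    cycle_length_days: float = 56.0
    days_per_year: float = 365.25
    horizon: str = FIVE_YEARS
    horizon_years: float = 5.0
    #: age at which a lifelong run is truncated (the cohort is essentially
    #: extinct there under any plausible life table)
    lifelong_max_age: float = 105.0
    start_age_years: float = 43.2
    annual_discount_rate: float = 0.05
    background_mortality: str = "off"  # "off" | "lifetable"
    half_cycle_correction: bool = False
    random_seed: int | None = None

    def validate(self) -> None:
        if self.cycle_length_days <= 0:
            raise ParameterError("cycle_length_days must be positive")
        if self.annual_discount_rate < 0:
            raise ParameterError("discount rate must be non-negative")
        if self.horizon not in (FIVE_YEARS, LIFELONG):
            raise ParameterError(f"unknown horizon {self.horizon!r}")
        if self.background_mortality not in ("off", "lifetable"):
            raise ParameterError(
                f"unknown background_mortality {self.background_mortality!r}"
            )

    @property
    def cycle_years(self) -> float:
        """Cycle length as a fraction of a year (56/365.25 by default)."""
        return self.cycle_length_days / self.days_per_year

    @property
    def n_cycles(self) -> int:
        if self.horizon == FIVE_YEARS:
            return int(self.horizon_years * self.days_per_year // self.cycle_length_days)
        span = max(self.lifelong_max_age - self.start_age_years, 0.0)
        return int(np.ceil(span / self.cycle_years))

    def age_at_cycle(self, cycle_index: int) -> float:
        return self.start_age_years + cycle_index * self.cycle_years


@dataclass
class CostParameters:
    """Unit prices and lump sums (EUR, SHI perspective, price year 2009)."""

    prednisolone_price_per_40mg: float = 0.25
    gastro_lump_sum_per_quarter: float = 18.90
    outpatient_procedures_per_6months: float = 115.63
    drg_inpatient_no_surgery: float = 1584.27
    drg_inpatient_surgery: float = 3812.55
    #: April-2010 net tablet prices, usable as an alternative price scenario
    alt_price_mezavant_tablet: float = 1.00
    alt_price_asacol_tablet: float = 0.39

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if v < 0:
                raise ParameterError(f"{f.name} must be non-negative, got {v!r}")


@dataclass
class UtilitySet:
    """State utilities with SDs (TTO/EQ-5D, n = 151 UC patients).

    The three active mesalazine states share the mild-to-moderate value;
    surgery is assumed equal to severe disease (relapse), post-surgery
    equal to remission.
    """

    active: float = 0.589
    active_sd: float = 0.269
    severe: float = 0.317
    severe_sd: float = 0.315
    remission: float = 0.845
    remission_sd: float = 0.195
    n_patients: int = 151

    def validate(self) -> None:
        for name in ("active", "severe", "remission"):
            _check_prob(f"utility {name}", getattr(self, name))
            if getattr(self, f"{name}_sd") < 0:
                raise ParameterError(f"utility {name}_sd must be non-negative")
        if self.n_patients < 2:
            raise ParameterError("n_patients must be >= 2")

    def for_state(self, state: HealthState) -> float:
        if state in (
            HealthState.ACTIVE_1L,
            HealthState.ACTIVE_1L_HIGH,
            HealthState.ACTIVE_2L,
        ):
            return self.active
        if state in (HealthState.FAILURE_RELAPSE, HealthState.SURGERY):
            return self.severe
        if state in (HealthState.POST_SURGERY, HealthState.REMISSION):
            return self.remission
        return 0.0


@dataclass
class PSASettings:
    """Dispersion assumptions for parameters without printed uncertainty."""

    cost_relative_se: float = 0.20
    n_trial_first_line: int = 170
    n_trial_extension: int = 85
    n_trial_second_line: int = 170
    n_trial_maintenance: int = 170
    #: health-state costs are drawn in the PSA including the drug
    #: acquisition component; set False to hold statutory reference prices
    #: fixed
    sample_drug_prices: bool = True
    drug_price_relative_se: float = 0.20

    def validate(self) -> None:
        for f in ("cost_relative_se", "drug_price_relative_se"):
            if getattr(self, f) < 0:
                raise ParameterError(f"{f} must be non-negative")
        for f in (
            "n_trial_first_line",
            "n_trial_extension",
            "n_trial_second_line",
            "n_trial_maintenance",
        ):
            if getattr(self, f) < 1:
                raise ParameterError(f"{f} must be >= 1")


class LifeTable:
    """Age → annual all-cause death probability, with clamped lookup."""

    def __init__(self, ages, annual_q) -> None:
        self.ages = np.asarray(ages, dtype=float)
        self.annual_q = np.asarray(annual_q, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.ages.ndim != 1 or self.ages.shape != self.annual_q.shape:
            raise ParameterError("life table must be two equal-length columns")
        if len(self.ages) == 0:
            raise ParameterError("life table is empty")
        if np.any(np.diff(self.ages) <= 0):
            raise ParameterError("life-table ages must be strictly increasing")
        if np.any((self.annual_q < 0) | (self.annual_q > 1)):
            raise ParameterError("death probabilities must be in [0, 1]")

    def annual_probability(self, age: float) -> float:
        """Annual death probability at integer age, clamped to coverage."""
        a = np.clip(np.floor(age), self.ages[0], self.ages[-1])
        idx = np.searchsorted(self.ages, a, side="right") - 1
        return float(self.annual_q[idx])

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        df = pd.read_csv(path)
        if df.shape[1] < 2:
            raise ParameterError("life-table file needs two columns with a header")
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy())

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"age": self.ages.astype(int), "annual_death_probability": self.annual_q}
        ).to_csv(path, index=False)

    def to_records(self) -> list[list[float]]:
        return [[int(a), float(q)] for a, q in zip(self.ages, self.annual_q)]


@dataclass
class ParameterBundle:
    """Complete, validated model input: arms, transitions, costs, utilities."""

    arms: dict[str, TreatmentArm] = field(default_factory=default_arms)
    transitions: TransitionParameters = field(default_factory=TransitionParameters)
    costs: CostParameters = field(default_factory=CostParameters)
    utilities: UtilitySet = field(default_factory=UtilitySet)
    config: ModelConfig = field(default_factory=ModelConfig)
    psa: PSASettings = field(default_factory=PSASettings)
    life_table: LifeTable | None = None

    def validate(self) -> None:
        missing = set(ARM_NAMES) - set(self.arms)
        if missing:
            raise ParameterError(f"missing treatment arms: {sorted(missing)}")
        for arm in self.arms.values():
            arm.validate()
        self.transitions.validate()
        self.costs.validate()
        self.utilities.validate()
        self.config.validate()
        self.psa.validate()
        if self.config.background_mortality == "lifetable" and self.life_table is None:
            raise ParameterError(
                "background_mortality='lifetable' requires a life table"
            )
        if self.life_table is not None:
            self.life_table.validate()

    def copy(self) -> "ParameterBundle":
        """Deep copy; scenario edits never alias the original bundle."""
        import copy as _copy

        return _copy.deepcopy(self)

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "arms": {k: dataclasses.asdict(v) for k, v in self.arms.items()},
            "transitions": dataclasses.asdict(self.transitions),
            "costs": dataclasses.asdict(self.costs),
            "utilities": dataclasses.asdict(self.utilities),
            "config": dataclasses.asdict(self.config),
            "psa": dataclasses.asdict(self.psa),
        }
        if self.life_table is not None:
            d["life_table"] = self.life_table.to_records()
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ParameterBundle":
        life = None
        if d.get("life_table"):
            rows = np.asarray(d["life_table"], dtype=float)
            life = LifeTable(rows[:, 0], rows[:, 1])
        bundle = cls(
            arms={k: TreatmentArm(**v) for k, v in d["arms"].items()},
            transitions=TransitionParameters(**d["transitions"]),
            costs=CostParameters(**d["costs"]),
            utilities=UtilitySet(**d["utilities"]),
            config=ModelConfig(**d["config"]),
            psa=PSASettings(**d.get("psa", {})),
            life_table=life,
        )
        bundle.validate()
        return bundle

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ParameterBundle":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
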