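"""One-way and probabilistic sensitivity analysis.

Probabilistic sensitivity analysis (PSA) samples utilities, remission
rates and resource-use costs from method-of-moments distributions — beta
for probabilities and utilities, gamma for costs — and re-evaluates both
arms on every draw (correlated comparison: shared parameters are drawn
once per draw).  Utilities with a printed SD use SE = SD/sqrt(n); remission
rates use binomial SEs implied by pseudo-trial sizes; resource-use costs
use an assumed relative SE.  Statutory drug reference prices are fixed by
default.

A single seeded generator with a fixed draw order makes every run
reproducible bit-for-bit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import run_cohort
from .costing import build_state_cost_table
from .outcomes import (
    DOMINANT,
    CEResult,
    arm_results,
    incremental_analysis,
)
from .parameters import ASACOL, MEZAVANT, ParameterBundle, ParameterError

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# distributions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DistributionSpec:
    """Sampling distribution of one parameter (method of moments)."""

    param_id: str
    family: str  # "beta" | "gamma" | "point"
    mean: float
    se: float
    a: float = 0.0  # beta alpha / gamma shape
    b: float = 0.0  # beta beta / gamma scale

    def sample(self, rng: np.random.Generator) -> float:
        if self.family == "point":
            return self.mean
        if self.family == "beta":
            return float(rng.beta(self.a, self.b))
        return float(rng.gamma(self.a, self.b))


def build_distribution(
    param_id: str,
    mean: float,
    family: str,
    se: float | None = None,
    sd: float | None = None,
    n: int | None = None,
    relative_se: float | None = None,
) -> DistributionSpec:
    """Method-of-moments spec from a mean and one dispersion source.

    Dispersion can be given directly (``se``), as a printed SD with sample
    size (``sd`` and ``n``, giving SE = sd/sqrt(n)), as a binomial trial
    size alone (``n``), or as a relative SE.
    """
    if se is None:
        if sd is not None and n is not None:
            se = sd / math.sqrt(n)
        elif relative_se is not None:
            se = mean * relative_se
        elif n is not None and family == "beta":
            se = math.sqrt(mean * (1.0 - mean) / n)
        else:
            raise ParameterError(f"{param_id}: no dispersion information given")
    if se < 0:
        raise ParameterError(f"{param_id}: SE must be non-negative")
    if se == 0.0:
        return DistributionSpec(param_id, "point", mean, 0.0)
    if family == "beta":
        if not 0.0 < mean < 1.0:
            raise ParameterError(
                f"{param_id}: beta mean must be strictly inside (0, 1) "
                "when the SE is positive"
            )
        var = se * se
        if var >= mean * (1.0 - mean):
            raise ParameterError(f"{param_id}: SE too large for a beta distribution")
        nu = mean * (1.0 - mean) / var - 1.0
        return DistributionSpec(param_id, "beta", mean, se, a=mean * nu, b=(1 - mean) * nu)
    if family == "gamma":
        if mean <= 0:
            raise ParameterError(f"{param_id}: gamma mean must be positive")
        return DistributionSpec(
            param_id, "gamma", mean, se, a=(mean / se) ** 2, b=se * se / mean
        )
    raise ParameterError(f"{param_id}: unknown family {family!r}")


def default_distributions(bundle: ParameterBundle) -> list[DistributionSpec]:
    """The declared PSA parameter set, in draw order.

    Order: utilities (active, severe, remission), first-line remission per
    arm, increased-dose remission per arm, second-line remission,
    hospitalisation remission, relapse per arm, then resource-use costs,
    then (only if enabled) drug prices.
    """
    u, t, c, s = bundle.utilities, bundle.transitions, bundle.costs, bundle.psa
    specs = [
        build_distribution("utility.active", u.active, "beta", sd=u.active_sd, n=u.n_patients),
        build_distribution("utility.severe", u.severe, "beta", sd=u.severe_sd, n=u.n_patients),
        build_distribution(
            "utility.remission", u.remission, "beta", sd=u.remission_sd, n=u.n_patients
        ),
        build_distribution(
            "p_remit_1l.MEZAVANT", t.p_remit_1l[MEZAVANT], "beta", n=s.n_trial_first_line
        ),
        build_distribution(
            "p_remit_1l.ASACOL", t.p_remit_1l[ASACOL], "beta", n=s.n_trial_first_line
        ),
        build_distribution(
            "p_remit_1l_high.MEZAVANT",
            t.p_remit_1l_high[MEZAVANT],
            "beta",
            n=s.n_trial_extension,
        ),
        build_distribution(
            "p_remit_1l_high.ASACOL",
            t.p_remit_1l_high[ASACOL],
            "beta",
            n=s.n_trial_extension,
        ),
        build_distribution("p_remit_2l", t.p_remit_2l, "beta", n=s.n_trial_second_line),
        build_distribution(
            "p_remit_hosp", t.p_remit_hosp, "beta", n=s.n_trial_second_line
        ),
        build_distribution(
            "p_relapse.MEZAVANT", t.p_relapse[MEZAVANT], "beta", n=s.n_trial_maintenance
        ),
        build_distribution(
            "p_relapse.ASACOL", t.p_relapse[ASACOL], "beta", n=s.n_trial_maintenance
        ),
        build_distribution(
            "cost.gastro_lump_sum_per_quarter",
            c.gastro_lump_sum_per_quarter,
            "gamma",
            relative_se=s.cost_relative_se,
        ),
        build_distribution(
            "cost.outpatient_procedures_per_6months",
            c.outpatient_procedures_per_6months,
            "gamma",
            relative_se=s.cost_relative_se,
        ),
        build_distribution(
            "cost.drg_inpatient_no_surgery",
            c.drg_inpatient_no_surgery,
            "gamma",
            relative_se=s.cost_relative_se,
        ),
        build_distribution(
            "cost.drg_inpatient_surgery",
            c.drg_inpatient_surgery,
            "gamma",
            relative_se=s.cost_relative_se,
        ),
    ]
    if s.sample_drug_prices:
        for arm in (MEZAVANT, ASACOL):
            specs.append(
                build_distribution(
                    f"price.{arm}",
                    bundle.arms[arm].price_per_tablet_eur,
                    "gamma",
                    relative_se=s.drug_price_relative_se,
                )
            )
    return specs


# ---------------------------------------------------------------------------
# applying named parameters to a bundle
# ---------------------------------------------------------------------------


def _set_surgery_share(bundle: ParameterBundle, v: float) -> None:
    bundle.transitions.p_surgery_hosp = v
    bundle.transitions.p_remit_hosp = 1.0 - v


def _setters() -> dict:
    """param_id -> (setter, (low, high) support)."""
    prob = (0.0, 1.0)
    pos = (0.0, math.inf)
    reg: dict = {
        "p_surgery_hosp": (_set_surgery_share, prob),
        "p_remit_2l": (
            lambda b, v: setattr(b.transitions, "p_remit_2l", v),
            prob,
        ),
        "p_remit_hosp": (
            lambda b, v: _set_surgery_share(b, 1.0 - v),
            prob,
        ),
        "p_relapse.BOTH": (
            lambda b, v: b.transitions.p_relapse.update({MEZAVANT: v, ASACOL: v}),
            prob,
        ),
        "utility.active": (lambda b, v: setattr(b.utilities, "active", v), prob),
        "utility.severe": (lambda b, v: setattr(b.utilities, "severe", v), prob),
        "utility.remission": (
            lambda b, v: setattr(b.utilities, "remission", v),
            prob,
        ),
    }
    for arm in (MEZAVANT, ASACOL):
        for attr in ("p_remit_1l", "p_remit_1l_high", "p_relapse"):
            reg[f"{attr}.{arm}"] = (
                lambda b, v, attr=attr, arm=arm: getattr(b.transitions, attr).__setitem__(arm, v),
                prob,
            )
        reg[f"price.{arm}"] = (
            lambda b, v, arm=arm: setattr(b.arms[arm], "price_per_tablet_eur", v),
            (1e-12, math.inf),
        )
    for attr in (
        "prednisolone_price_per_40mg",
        "gastro_lump_sum_per_quarter",
        "outpatient_procedures_per_6months",
        "drg_inpatient_no_surgery",
        "drg_inpatient_surgery",
    ):
        reg[f"cost.{attr}"] = (
            lambda b, v, attr=attr: setattr(b.costs, attr, v),
            pos,
        )
    return reg


_REGISTRY = _setters()


def parameter_ids() -> list[str]:
    """Recognised parameter identifiers for OWSA and scenario perturbation."""
    return sorted(_REGISTRY)


def apply_parameter(bundle: ParameterBundle, param_id: str, value: float) -> None:
    """Set a named parameter in place, checking its support."""
    try:
        setter, (lo, hi) = _REGISTRY[param_id]
    except KeyError:
        raise ParameterError(
            f"unknown parameter {param_id!r}; valid ids: {', '.join(parameter_ids())}"
        ) from None
    if not lo <= value <= hi:
        raise ParameterError(f"{param_id}={value!r} outside support [{lo}, {hi}]")
    setter(bundle, value)


def equalise_maintenance(bundle: ParameterBundle, annual_remission: float = 0.68) -> None:
    """Scenario: identical long-term maintenance in both arms.

    Sets both arms' relapse parameter to ``1 - annual_remission`` (on the
    bundle's declared relapse basis).
    """
    apply_parameter(bundle, "p_relapse.BOTH", 1.0 - annual_remission)


# ---------------------------------------------------------------------------
# PSA
# ---------------------------------------------------------------------------


@dataclass
class PSAResult:
    """Draw-level incremental pairs with summaries."""

    draws: pd.DataFrame  # columns: draw, inc_cost, inc_qaly, cost/qaly per arm
    n_iter: int
    seed: int | None
    n_rejected: int = 0
    deterministic: CEResult | None = None

    @property
    def probability_dominant(self) -> float:
        """Fraction of draws that are cost-saving with a QALY gain
        (south-east quadrant of the CE plane)."""
        d = self.draws
        return float(((d.inc_cost < 0) & (d.inc_qaly > 0)).mean())

    @property
    def mean_incremental_cost(self) -> float:
        return float(self.draws.inc_cost.mean())

    @property
    def mean_incremental_qalys(self) -> float:
        return float(self.draws.inc_qaly.mean())

    def arm_means(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cost_eur": {
                    MEZAVANT: self.draws.cost_mezavant.mean(),
                    ASACOL: self.draws.cost_asacol.mean(),
                },
                "qalys": {
                    MEZAVANT: self.draws.qaly_mezavant.mean(),
                    ASACOL: self.draws.qaly_asacol.mean(),
                },
            }
        )

    def ceac(self, thresholds: np.ndarray | None = None) -> pd.DataFrame:
        """Probability of positive net monetary benefit per WTP threshold."""
        if thresholds is None:
            thresholds = np.arange(0.0, 100_001.0, 2_500.0)
        dq = self.draws.inc_qaly.to_numpy()
        dc = self.draws.inc_cost.to_numpy()
        prob = [(lam * dq - dc > 0).mean() for lam in thresholds]
        return pd.DataFrame(
            {"threshold_eur_per_qaly": thresholds, "probability_cost_effective": prob}
        )

    def summary(self) -> str:
        return (
            f"PSA: {self.n_iter} draws (seed {self.seed}, {self.n_rejected} rejected)\n"
            f"mean incremental cost  {self.mean_incremental_cost:+,.0f} EUR\n"
            f"mean incremental QALYs {self.mean_incremental_qalys:+.3f}\n"
            f"P(cost-saving and QALY-gaining) = {self.probability_dominant:.1%}"
        )


def _evaluate(bundle: ParameterBundle, arm_name: str):
    """Deterministic outcomes of one arm (cost, qalys, days, events)."""
    trace = run_cohort(bundle, arm_name)
    table = build_state_cost_table(bundle.arms[arm_name], bundle.costs, bundle.config)
    return arm_results(trace, table, bundle.utilities, bundle.config)


def run_psa(
    bundle: ParameterBundle,
    n_iter: int = 10_000,
    seed: int | None = None,
    specs: list[DistributionSpec] | None = None,
) -> PSAResult:
    """Monte-Carlo PSA: sample every parameter, evaluate both arms per draw.

    Both arms are evaluated on the *same* draw (correlated comparison);
    draws that fail parameter validation are rejected, logged and counted.
    """
    if n_iter < 1:
        raise ParameterError("n_iter must be >= 1")
    bundle.validate()
    if specs is None:
        specs = default_distributions(bundle)
    rng = np.random.default_rng(seed)
    records = []
    n_rejected = 0
    for i in range(n_iter):
        values = {spec.param_id: spec.sample(rng) for spec in specs}
        draw_bundle = bundle.copy()
        try:
            for pid, v in values.items():
                apply_parameter(draw_bundle, pid, v)
            draw_bundle.validate()
            mez = _evaluate(draw_bundle, MEZAVANT)
            asa = _evaluate(draw_bundle, ASACOL)
        except (ParameterError, RuntimeError) as exc:
            n_rejected += 1
            log.warning("draw %d rejected: %s", i, exc)
            continue
        records.append(
            {
                "draw": i,
                "inc_cost": mez.discounted_cost - asa.discounted_cost,
                "inc_qaly": mez.discounted_qalys - asa.discounted_qalys,
                "cost_mezavant": mez.discounted_cost,
                "cost_asacol": asa.discounted_cost,
                "qaly_mezavant": mez.discounted_qalys,
                "qaly_asacol": asa.discounted_qalys,
            }
        )
    draws = pd.DataFrame.from_records(records)
    det = incremental_analysis(_evaluate(bundle, MEZAVANT), _evaluate(bundle, ASACOL))
    return PSAResult(
        draws=draws, n_iter=n_iter, seed=seed, n_rejected=n_rejected, deterministic=det
    )


# ---------------------------------------------------------------------------
# OWSA
# ---------------------------------------------------------------------------


@dataclass
class OWSAResult:
    """Incremental results along a one-parameter grid."""

    param_id: str
    values: np.ndarray
    inc_cost: np.ndarray
    inc_qalys: np.ndarray
    labels: list[str]
    base: CEResult

    @property
    def max_abs_cost_deviation(self) -> float:
        """Largest |change| of the incremental cost relative to base case."""
        return float(np.abs(self.inc_cost - self.base.incremental_cost).max())

    @property
    def always_dominant(self) -> bool:
        return all(lab == DOMINANT for lab in self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": self.param_id,
                "value": self.values,
                "inc_cost_eur": self.inc_cost,
                "inc_qalys": self.inc_qalys,
                "label": self.labels,
            }
        )


def run_owsa(
    bundle: ParameterBundle,
    param_id: str,
    bounds: tuple[float, float],
    steps: int = 6,
) -> OWSAResult:
    """Deterministic re-run over an evenly spaced one-parameter grid."""
    if steps < 1:
        raise ParameterError("steps must be >= 1")
    lo, hi = bounds
    if param_id not in _REGISTRY:
        raise ParameterError(
            f"unknown parameter {param_id!r}; valid ids: {', '.join(parameter_ids())}"
        )
    _, (slo, shi) = _REGISTRY[param_id]
    if not (slo <= lo <= shi and slo <= hi <= shi):
        raise ParameterError(f"bounds {bounds!r} outside support of {param_id}")
    values = np.linspace(lo, hi, steps) if steps > 1 else np.array([lo])
    base = incremental_analysis(_evaluate(bundle, MEZAVANT), _evaluate(bundle, ASACOL))
    inc_cost, inc_q, labels = [], [], []
    for v in values:
        b = bundle.copy()
        apply_parameter(b, param_id, float(v))
        res = incremental_analysis(_evaluate(b, MEZAVANT), _evaluate(b, ASACOL))
        inc_cost.append(res.incremental_cost)
        inc_q.append(res.incremental_qalys)
        labels.append(res.label)
    return OWSAResult(
        param_id=param_id,
        values=values,
        inc_cost=np.array(inc_cost),
        inc_qalys=np.array(inc_q),
        labels=labels,
        base=base,
    )
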