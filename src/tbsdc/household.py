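"""The household estimation model.

From annual counts of people with TB and their household contacts, the
pipeline builds, stratum by stratum:

1. people with TB living with HIV, via the country's TB-HIV pathway;
2. household contacts living with HIV, as contacts x national prevalence x
   the pooled household-contact prevalence ratio (capped at the contact
   count so no stratum exceeds 100% prevalence);
3. household HIV prevalence = (1 + 2) / all adults 15-49 in TB-affected
   households;
4. partnered individuals (stable-partnership proportions applied cellwise)
   and couples (partnered / 2, real-valued);
5. serodifferent couples: P_SDC back-calculated from household prevalence
   via the fitted serodifference curve, times HIV-positive partnered
   individuals — or an externally supplied couple count (the published
   table values), which isolates the P_SDC back-calculation from everything
   downstream;
6. PrEP-averted acquisitions at each eligibility scenario.

:class:`HouseholdSdcModel` is the model object; ``fit()`` runs the pipeline
deterministically, ``fit(draws=1000, seed=...)`` runs it draw-wise with
every uncertain input expanded to aligned Monte Carlo draws and reports
means with 2.5/97.5-percentile uncertainty intervals.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .draws import DEFAULT_N_DRAWS, Summary, UncertainValue, make_draws, substream, summarize
from .prep import ELIGIBILITY_SCENARIOS, PrepParams, averted
from .psdc import PsdcFit, backcalc_psdc, fixed_alpha_fit
from .scenarios import CountryScenario, published_n_sdc, total_adults
from .strata import AGE_BANDS, SEXES, AgeSexTable, ValidationError

#: posterior mean of the homogeneity parameter reported for the reference
#: DHS fit; used when no freshly fitted curve is supplied.
REFERENCE_ALPHA = 0.829


def _ratio_value(x):
    return x.mean if isinstance(x, UncertainValue) else x


def tbhiv_count(scenario) -> AgeSexTable:
    """People with TB who are living with HIV, per stratum, via the
    scenario's TB-HIV pathway. Capped cellwise at the TB count."""
    pathway = scenario.tbhiv_pathway
    if pathway == "age_sex_proportion":
        out = scenario.tb_counts * scenario.tbhiv_agesex_prop
    elif pathway == "overall_proportion":
        out = scenario.tb_counts * scenario.tbhiv_overall_prop
    elif pathway == "notified_times_ratio":
        prop = scenario.notified_hiv_prev * _ratio_value(scenario.prev_to_notified_ratio)
        out = scenario.tb_counts * prop
    elif pathway == "direct_counts":
        out = scenario.tbhiv_direct_counts
    else:  # pragma: no cover - rejected at construction
        raise ValidationError(f"unknown pathway {pathway!r}")
    return out.minimum(scenario.tb_counts)


def hhc_hiv_count(scenario) -> AgeSexTable:
    """Household contacts living with HIV, per stratum: contacts x national
    prevalence x pooled prevalence ratio, capped at the contact count."""
    pr = _ratio_value(scenario.hhc_prevalence_ratio)
    raw = scenario.hhc_counts * scenario.national_hiv_prev * pr
    return raw.minimum(scenario.hhc_counts)


def partnered(table: AgeSexTable, partnership_prop: AgeSexTable):
    """People from ``table`` who are engaged in stable partnerships."""
    return (table * partnership_prop).total()


def couples(n_partnered):
    """Couples among partnered individuals: n/2, real-valued (fractional
    couples are carried internally and rounded only on report)."""
    return n_partnered / 2


@dataclass
class HouseholdEstimate:
    """Point (or draw-wise) outputs of the household pipeline."""

    country: str
    scenario: str
    n_people: Union[float, np.ndarray]
    n_hivpos: Union[float, np.ndarray]
    hh_prevalence: Union[float, np.ndarray]
    n_partnered: Union[float, np.ndarray]
    n_couples: Union[float, np.ndarray]
    n_hivpos_partnered: Union[float, np.ndarray]
    p_sdc_used: Union[float, np.ndarray]
    n_sdc: Union[float, np.ndarray]
    prop_sdc_hh: Union[float, np.ndarray]
    prop_sdc_pop: Optional[float] = None

    _FIELDS = (
        "n_people", "n_hivpos", "hh_prevalence", "n_partnered", "n_couples",
        "n_hivpos_partnered", "p_sdc_used", "n_sdc", "prop_sdc_hh",
    )


def estimate_household(
    scenario,
    fit: PsdcFit,
    prop_sdc_pop: Optional[float] = None,
    n_sdc_override=None,
) -> HouseholdEstimate:
    """Run the estimation pipeline on one (possibly draw-expanded) scenario.

    ``n_sdc_override`` substitutes an external serodifferent-couple count
    (scalar or draw vector) for the P_SDC back-calculation.
    """
    tbhiv = tbhiv_count(scenario)
    hhc_hiv = hhc_hiv_count(scenario)
    hivpos = tbhiv + hhc_hiv
    n_hivpos = hivpos.total()
    n_people = total_adults(scenario)
    hh_prev = np.asarray(n_hivpos / n_people)
    if np.any(hh_prev >= 1):
        raise ValidationError("household HIV prevalence reached 1")

    all_adults = scenario.tb_counts + scenario.hhc_counts
    n_partnered = partnered(all_adults, scenario.partnership_prop)
    n_couples = couples(n_partnered)
    n_hivpos_partnered = partnered(hivpos, scenario.partnership_prop)

    # zero-prevalence strata are legal: P_SDC is only evaluated where there
    # is anyone living with HIV
    positive = hh_prev > 0
    safe_prev = np.where(positive, hh_prev, 0.5)
    p_sdc = np.where(positive, backcalc_psdc(safe_prev, fit), 0.0)
    if p_sdc.ndim == 0:
        p_sdc = float(p_sdc)
        hh_prev = float(hh_prev)

    n_sdc = n_sdc_override if n_sdc_override is not None else n_hivpos_partnered * p_sdc
    return HouseholdEstimate(
        country=scenario.country, scenario=scenario.scenario,
        n_people=n_people, n_hivpos=n_hivpos, hh_prevalence=hh_prev,
        n_partnered=n_partnered, n_couples=n_couples,
        n_hivpos_partnered=n_hivpos_partnered, p_sdc_used=p_sdc,
        n_sdc=n_sdc, prop_sdc_hh=n_sdc / n_couples,
        prop_sdc_pop=prop_sdc_pop,
    )


# ---------------------------------------------------------------------------
# Monte Carlo expansion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MonteCarloSpreads:
    """Default uncertainty levels for inputs whose spread is not published.

    ``count_rel``/``prop_rel``/``partnership_rel`` are half-widths of a 95%
    relative interval per cell (counts drawn lognormal, proportions
    truncated normal). ``include_param_uncertainty`` toggles the published
    intervals on the prevalence ratios.
    """

    count_rel: float = 0.20
    prop_rel: float = 0.10
    partnership_rel: float = 0.05
    include_param_uncertainty: bool = True

    @classmethod
    def zero(cls) -> "MonteCarloSpreads":
        return cls(0.0, 0.0, 0.0, include_param_uncertainty=False)


@dataclass
class _ScenarioDraws:
    """Draw-expanded pipeline inputs (already validated upstream)."""

    country: str
    scenario: str
    tb_counts: AgeSexTable
    hhc_counts: AgeSexTable
    national_hiv_prev: AgeSexTable
    partnership_prop: AgeSexTable
    tbhiv_pathway: str
    hhc_prevalence_ratio: np.ndarray
    tbhiv_agesex_prop: Optional[AgeSexTable] = None
    tbhiv_overall_prop: Optional[np.ndarray] = None
    notified_hiv_prev: Optional[np.ndarray] = None
    prev_to_notified_ratio: Optional[np.ndarray] = None
    tbhiv_direct_counts: Optional[AgeSexTable] = None


def _expand_table(
    table: AgeSexTable, rel: float, kind: str, dist: str,
    n: int, seed: int, label: str,
) -> AgeSexTable:
    if rel == 0.0 or n == 1:
        return AgeSexTable(np.repeat(table.values[:, :, None], n, axis=2))
    out = np.empty((2, 4, n))
    for i, sex in enumerate(SEXES):
        for j, band in enumerate(AGE_BANDS):
            mean = float(table.values[i, j])
            cell_label = f"{label}/{sex}/{band}"
            if mean == 0.0:
                out[i, j] = 0.0
                continue
            if dist == "lognormal":
                uv = UncertainValue(mean=mean, se=rel / 1.96, distribution="lognormal")
            else:
                uv = UncertainValue(mean=mean, se=rel * mean / 1.96, distribution="normal")
            out[i, j] = make_draws(uv, n, seed=substream(seed, cell_label),
                                   kind=kind, label=cell_label).values
    return AgeSexTable(out)


def _expand_scalar(value, n: int, seed: int, label: str, kind: str,
                   include_uncertainty: bool) -> np.ndarray:
    uv = value if isinstance(value, UncertainValue) else UncertainValue.exact(float(value))
    if not include_uncertainty or n == 1:
        return np.full(n, uv.mean)
    return make_draws(uv, n, seed=substream(seed, label), kind=kind, label=label).values


def expand_scenario(
    scenario: CountryScenario,
    n_draws: int = DEFAULT_N_DRAWS,
    seed: int = 0,
    spreads: MonteCarloSpreads = MonteCarloSpreads(),
) -> _ScenarioDraws:
    """Expand every uncertain input of a scenario into aligned draw vectors.

    Cells of one parameter block are sampled independently, each from its
    own label-derived substream of the master seed. With ``n_draws=1`` the
    expansion is exactly the point scenario, so a 1-draw Monte Carlo run
    reproduces the deterministic pipeline.
    """
    lab = f"{scenario.country}/{scenario.scenario}"
    tab = lambda t, rel, kind, dist, name: _expand_table(
        t, rel, kind, dist, n_draws, seed, f"{lab}/{name}")
    out = _ScenarioDraws(
        country=scenario.country, scenario=scenario.scenario,
        tb_counts=tab(scenario.tb_counts, spreads.count_rel, "count", "lognormal", "tb_counts"),
        hhc_counts=tab(scenario.hhc_counts, spreads.count_rel, "count", "lognormal", "hhc_counts"),
        national_hiv_prev=tab(scenario.national_hiv_prev, spreads.prop_rel,
                              "proportion", "normal", "national_hiv_prev"),
        partnership_prop=tab(scenario.partnership_prop, spreads.partnership_rel,
                             "proportion", "normal", "partnership_prop"),
        tbhiv_pathway=scenario.tbhiv_pathway,
        hhc_prevalence_ratio=_expand_scalar(
            scenario.hhc_prevalence_ratio, n_draws, seed, f"{lab}/hhc_prevalence_ratio",
            "count", spreads.include_param_uncertainty),
    )
    if scenario.tbhiv_agesex_prop is not None:
        out.tbhiv_agesex_prop = tab(scenario.tbhiv_agesex_prop, spreads.prop_rel,
                                    "proportion", "normal", "tbhiv_agesex_prop")
    if scenario.tbhiv_overall_prop is not None:
        out.tbhiv_overall_prop = _expand_scalar(
            UncertainValue(mean=scenario.tbhiv_overall_prop,
                           se=spreads.prop_rel * scenario.tbhiv_overall_prop / 1.96),
            n_draws, seed, f"{lab}/tbhiv_overall_prop", "proportion", True)
    if scenario.notified_hiv_prev is not None:
        out.notified_hiv_prev = _expand_scalar(
            UncertainValue(mean=scenario.notified_hiv_prev,
                           se=spreads.prop_rel * scenario.notified_hiv_prev / 1.96),
            n_draws, seed, f"{lab}/notified_hiv_prev", "proportion", True)
    if scenario.prev_to_notified_ratio is not None:
        out.prev_to_notified_ratio = _expand_scalar(
            scenario.prev_to_notified_ratio, n_draws, seed,
            f"{lab}/prev_to_notified_ratio", "count", spreads.include_param_uncertainty)
    if scenario.tbhiv_direct_counts is not None:
        out.tbhiv_direct_counts = tab(scenario.tbhiv_direct_counts, spreads.count_rel,
                                      "count", "lognormal", "tbhiv_direct_counts")
    return out


# ---------------------------------------------------------------------------
# model object
# ---------------------------------------------------------------------------

@dataclass
class HouseholdResults:
    """Fitted household model: point estimates or Monte Carlo summaries.

    ``estimate`` holds scalars after a deterministic fit and draw vectors
    after a Monte Carlo fit; ``summaries`` (Monte Carlo only) maps each
    output to its mean and 95% uncertainty interval. ``averted`` maps each
    eligibility scenario to the annual HIV acquisitions averted by PrEP.
    """

    model: "HouseholdSdcModel"
    estimate: HouseholdEstimate
    averted: Mapping[float, Union[float, Summary]]
    n_draws: Optional[int] = None
    seed: Optional[int] = None
    summaries: Optional[dict[str, Summary]] = None

    @property
    def is_monte_carlo(self) -> bool:
        return self.n_draws is not None

    def _value(self, name: str) -> float:
        if self.summaries is not None:
            return self.summaries[name].mean
        return float(getattr(self.estimate, name))

    def to_frame(self) -> pd.DataFrame:
        """One row mirroring the published per-country layout (counts and
        percentages as point values / draw means)."""
        row = {
            "country": self.estimate.country,
            "scenario": self.estimate.scenario,
            "n_hivpos": self._value("n_hivpos"),
            "n_people": self._value("n_people"),
            "hh_prevalence_pct": 100 * self._value("hh_prevalence"),
            "n_sdc": self._value("n_sdc"),
            "prop_sdc_hh_pct": 100 * self._value("prop_sdc_hh"),
            "prop_sdc_pop_pct": (
                100 * self.estimate.prop_sdc_pop
                if self.estimate.prop_sdc_pop is not None else np.nan
            ),
        }
        return pd.DataFrame([row])

    def averted_frame(self) -> pd.DataFrame:
        """Averted acquisitions by eligibility scenario (columns 100%..25%)."""
        row = {"country": self.estimate.country, "scenario": self.estimate.scenario}
        for e in sorted(self.averted, reverse=True):
            v = self.averted[e]
            row[f"averted_{int(100 * e)}pct"] = v.mean if isinstance(v, Summary) else v
        return pd.DataFrame([row])

    def summary(self) -> str:
        e = self.estimate
        kind = (f"Monte Carlo ({self.n_draws} draws, seed {self.seed})"
                if self.is_monte_carlo else "deterministic")
        def fmt(name, scale=1.0, pct=False):
            if self.summaries is not None:
                s = self.summaries[name]
                if pct:
                    return f"{100 * s.mean:.2f}% ({100 * s.lower:.2f}-{100 * s.upper:.2f})"
                return f"{s.mean:,.0f} ({s.lower:,.0f}-{s.upper:,.0f})"
            v = float(getattr(e, name))
            return f"{100 * v:.2f}%" if pct else f"{v:,.0f}"
        lines = [
            f"Serodifferent couples in TB-affected households — {e.country}, "
            f"{e.scenario} scenario [{kind}]",
            "-" * 72,
            f"adults 15-49 in TB-affected households : {fmt('n_people')}",
            f"  of whom living with HIV              : {fmt('n_hivpos')}",
            f"household HIV prevalence               : {fmt('hh_prevalence', pct=True)}",
            f"couples in TB-affected households      : {fmt('n_couples')}",
            f"serodifferent couples (SDCs)           : {fmt('n_sdc')}",
            f"proportion of couples serodifferent    : {fmt('prop_sdc_hh', pct=True)}",
            "",
            "HIV acquisitions averted per year by PrEP, by eligibility:",
        ]
        for eligibility in sorted(self.averted, reverse=True):
            v = self.averted[eligibility]
            if isinstance(v, Summary):
                lines.append(f"  {int(100 * eligibility):>3}% : "
                             f"{v.mean:,.0f} ({v.lower:,.0f}-{v.upper:,.0f})")
            else:
                lines.append(f"  {int(100 * eligibility):>3}% : {v:,.0f}")
        return "\n".join(lines)


class HouseholdSdcModel:
    """Estimate serodifferent couples in TB-affected households and the HIV
    acquisitions PrEP would avert among them.

    Parameters
    ----------
    scenario
        A validated :class:`~tbsdc.scenarios.CountryScenario`.
    curve
        A :class:`~tbsdc.psdc.PsdcFit` (fitted serodifference curve) or a
        plain alpha value; defaults to the reference alpha 0.829.
    prep
        PrEP parameters (uptake/effectiveness/incidence).
    eligibilities
        PrEP eligibility scenarios to report.
    n_sdc
        ``None`` to back-calculate the couple count from the curve,
        ``"published"`` to take it (with its uncertainty interval) from the
        packaged published estimates, or an explicit scalar /
        :class:`UncertainValue`.
    prop_sdc_pop
        General-population share of couples that are serodifferent
        (reporting comparator only).
    """

    def __init__(
        self,
        scenario: CountryScenario,
        curve: Union[PsdcFit, float] = REFERENCE_ALPHA,
        prep: PrepParams = PrepParams(),
        eligibilities: Sequence[float] = ELIGIBILITY_SCENARIOS,
        n_sdc: Union[None, str, float, UncertainValue] = None,
        prop_sdc_pop: Optional[float] = None,
        fixtures_dir=None,
    ):
        self.scenario = scenario
        self.curve = curve if isinstance(curve, PsdcFit) else fixed_alpha_fit(curve)
        self.prep = prep
        self.eligibilities = tuple(eligibilities)
        if isinstance(n_sdc, str):
            if n_sdc != "published":
                raise ValueError(f"unknown n_sdc source {n_sdc!r}")
            n_sdc = published_n_sdc(scenario.country, scenario.scenario, fixtures_dir)
        elif isinstance(n_sdc, (int, float)):
            n_sdc = UncertainValue.exact(float(n_sdc))
        self.n_sdc_override: Optional[UncertainValue] = n_sdc
        self.prop_sdc_pop = prop_sdc_pop

    # -- fitting ------------------------------------------------------
    def fit(
        self,
        draws: Optional[int] = None,
        seed: int = 0,
        spreads: MonteCarloSpreads = MonteCarloSpreads(),
    ) -> HouseholdResults:
        if draws is None:
            est = estimate_household(
                self.scenario, self.curve, self.prop_sdc_pop,
                n_sdc_override=(None if self.n_sdc_override is None
                                else self.n_sdc_override.mean),
            )
            av = {
                e: float(averted(est.n_sdc, self.prep.at_eligibility(e)))
                for e in self.eligibilities
            }
            return HouseholdResults(model=self, estimate=est, averted=av)

        if draws < 1:
            raise ValueError("draws must be >= 1")
        expanded = expand_scenario(self.scenario, draws, seed, spreads)
        curve = self.curve
        if (draws > 1 and spreads.include_param_uncertainty
                and curve.chain is not None and curve.burn_in is not None):
            # propagate posterior uncertainty in alpha by resampling the chain
            rng = substream(seed, f"{self.scenario.country}/{self.scenario.scenario}/alpha")
            alpha_draws = rng.choice(curve.chain[curve.burn_in:], size=draws)
            curve = fixed_alpha_fit(alpha_draws, form=curve.form)
        override = None
        if self.n_sdc_override is not None:
            override = _expand_scalar(
                self.n_sdc_override, draws, seed,
                f"{self.scenario.country}/{self.scenario.scenario}/n_sdc",
                "count", spreads.include_param_uncertainty)
        est = estimate_household(expanded, curve, self.prop_sdc_pop,
                                 n_sdc_override=override)
        av = {
            e: summarize(averted(np.asarray(est.n_sdc), self.prep.at_eligibility(e)))
            for e in self.eligibilities
        }
        summaries = {
            name: summarize(np.atleast_1d(np.asarray(getattr(est, name))))
            for name in HouseholdEstimate._FIELDS
        }
        return HouseholdResults(model=self, estimate=est, averted=av,
                                n_draws=draws, seed=seed, summaries=summaries)


def propagate(
    scenario: CountryScenario,
    fit: Union[PsdcFit, float] = REFERENCE_ALPHA,
    prep: PrepParams = PrepParams(),
    n_draws: int = DEFAULT_N_DRAWS,
    seed: int = 0,
    **kwargs,
) -> HouseholdResults:
    """Monte Carlo propagation of input uncertainty through the full
    pipeline (convenience wrapper over :class:`HouseholdSdcModel`)."""
    return HouseholdSdcModel(scenario, curve=fit, prep=prep, **kwargs).fit(
        draws=n_draws, seed=seed)
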