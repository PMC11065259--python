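"""Report assembly: per-country tables and the end-to-end run.

Counts are rendered rounded half-away-from-zero to whole persons and
proportions to two decimals in percent, matching the published table
formatting; full precision is kept in the JSON outputs.
"""
from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .draws import Summary
from .household import HouseholdResults, HouseholdSdcModel, MonteCarloSpreads
from .prep import ELIGIBILITY_SCENARIOS, PrepParams
from .psdc import PsdcFit
from .scenarios import COUNTRIES, SCENARIOS, load_published_estimates, load_scenario


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention used in the reports)."""
    factor = 10**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


@dataclass
class RunConfig:
    """Configuration of a full model run."""

    fixtures_dir: Optional[str] = None
    countries: Sequence[str] = COUNTRIES
    scenarios: Sequence[str] = SCENARIOS
    eligibilities: Sequence[float] = ELIGIBILITY_SCENARIOS
    draws: int = 1000
    seed: int = 0
    n_sdc_source: str = "published"  # "published" | "modeled"
    alpha: float = 0.829
    prep: PrepParams = field(default_factory=PrepParams)
    spreads: MonteCarloSpreads = field(default_factory=MonteCarloSpreads)

    def __post_init__(self) -> None:
        if self.draws < 1:
            raise ValueError("draws must be >= 1")
        for e in self.eligibilities:
            if not 0 <= e <= 1:
                raise ValueError(f"eligibility {e} outside [0, 1]")

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: str(v) for k, v in sorted(self.__dict__.items())}, sort_keys=True
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def fit_country(
    config: RunConfig, country: str, scenario: str,
    curve: Optional[PsdcFit] = None,
) -> HouseholdResults:
    scen = load_scenario(config.fixtures_dir, country, scenario)
    pub = load_published_estimates(config.fixtures_dir)
    row = pub[(pub["country"] == country) & (pub["scenario"] == scenario)]
    prop_pop = float(row.iloc[0]["p_sdc_pop_pct"]) / 100 if not row.empty else None
    model = HouseholdSdcModel(
        scen,
        curve=curve if curve is not None else config.alpha,
        prep=config.prep,
        eligibilities=config.eligibilities,
        n_sdc=("published" if config.n_sdc_source == "published" else None),
        prop_sdc_pop=prop_pop,
        fixtures_dir=config.fixtures_dir,
    )
    draws = None if config.draws == 1 else config.draws
    return model.fit(draws=draws, seed=config.seed, spreads=config.spreads) \
        if draws else model.fit()


def household_table(results: Sequence[HouseholdResults]) -> pd.DataFrame:
    """Per-country household estimates in the published column order."""
    return pd.concat([r.to_frame() for r in results], ignore_index=True)


def averted_table(results: Sequence[HouseholdResults]) -> pd.DataFrame:
    """Averted acquisitions by eligibility, one row per country."""
    return pd.concat([r.averted_frame() for r in results], ignore_index=True)


def _json_ready(r: HouseholdResults) -> dict:
    est = r.estimate
    out = {"country": est.country, "scenario": est.scenario}
    if r.summaries is not None:
        out["outputs"] = {
            k: {"mean": s.mean, "lower": s.lower, "upper": s.upper}
            for k, s in r.summaries.items()
        }
        out["averted"] = {
            str(e): {"mean": v.mean, "lower": v.lower, "upper": v.upper}
            for e, v in r.averted.items()
        }
    else:
        out["outputs"] = {
            k: float(getattr(est, k)) for k in type(est)._FIELDS
        }
        out["averted"] = {str(e): float(v) for e, v in r.averted.items()}
    return out


def run_all(config: RunConfig, out_dir: str | Path) -> dict[str, Path]:
    """Run every requested country/scenario and write the report files.

    Emits, per scenario, a household-estimates CSV and an averted-
    acquisitions CSV (rounded, mirroring the published table layouts), a
    full-precision JSON, and a run log with seed, version and config hash.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    payload = []
    for scenario in config.scenarios:
        results = [fit_country(config, c, scenario) for c in config.countries]
        hh = household_table(results)
        for col in ("n_hivpos", "n_people", "n_sdc"):
            hh[col] = hh[col].map(round_half_up)
        for col in ("hh_prevalence_pct", "prop_sdc_hh_pct", "prop_sdc_pop_pct"):
            hh[col] = hh[col].map(lambda v: round_half_up(v, 2) if np.isfinite(v) else v)
        av = averted_table(results)
        for col in av.columns:
            if col.startswith("averted_"):
                av[col] = av[col].map(round_half_up)
        hh_path = out_dir / f"households_{scenario}.csv"
        av_path = out_dir / f"averted_{scenario}.csv"
        hh.to_csv(hh_path, index=False)
        av.to_csv(av_path, index=False)
        written[f"households_{scenario}"] = hh_path
        written[f"averted_{scenario}"] = av_path
        payload.extend(_json_ready(r) for r in results)

    json_path = out_dir / "estimates.json"
    with open(json_path, "w") as f:
        json.dump(payload, f, indent=2)
    written["estimates"] = json_path

    log_path = out_dir / "run_log.json"
    with open(log_path, "w") as f:
        json.dump(
            {
                "package_version": __version__,
                "seed": config.seed,
                "draws": config.draws,
                "n_sdc_source": config.n_sdc_source,
                "alpha": config.alpha,
                "config_hash": config.config_hash(),
            },
            f, indent=2,
        )
    written["run_log"] = log_path
    return written


def plot_curve(fit: PsdcFit, alphas: Sequence[float] = (0.7, 0.75, 0.8, 0.85, 0.9),
               out_path: Optional[str] = None):
    """Simulated serodifference curves over a prevalence grid for a band of
    alpha values, with the fitted curve highlighted."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .psdc import psdc

    grid = np.linspace(0.005, 0.35, 200)
    fig, ax = plt.subplots(figsize=(6, 4))
    for a in alphas:
        ax.plot(grid, psdc(grid, a, fit.form), lw=0.8, alpha=0.6, label=f"alpha={a}")
    ax.plot(grid, fit.predict(grid), lw=2, color="black",
            label=f"fitted alpha={fit.alpha_hat:.3f}")
    ax.set_xlabel("national HIV prevalence, ages 15-49")
    ax.set_ylabel("P_SDC")
    ax.legend(fontsize=7)
    fig.tight_layout()
    if out_path:
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
        return out_path
    return fig
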