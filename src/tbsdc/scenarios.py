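"""Country parameter model and fixture I/O.

A :class:`CountryScenario` bundles every input the household pipeline needs
for one country under one index-population definition ("incidence" uses
people with incident TB as the index cases, "prevalence" uses people with
prevalent TB). Inputs are shipped as plain CSV fixtures — one row per
(country, scenario, parameter, sex, age band) cell — plus a YAML manifest
naming each country's TB-HIV pathway and scalar parameters.

All proportions are stored as values in [0, 1]; rendering to percent happens
only in reports. Age bands are closed categorical labels.
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
import yaml

from .draws import UncertainValue
from .strata import AGE_BANDS, SEXES, AgeSexTable, ValidationError

COUNTRIES = ("Ethiopia", "Kenya", "South Africa", "Uganda")
SCENARIOS = ("incidence", "prevalence")
Pathway = Literal[
    "age_sex_proportion", "overall_proportion", "notified_times_ratio", "direct_counts"
]

#: which optional fields each TB-HIV pathway requires
_PATHWAY_FIELDS = {
    "age_sex_proportion": ("tbhiv_agesex_prop",),
    "overall_proportion": ("tbhiv_overall_prop",),
    "notified_times_ratio": ("notified_hiv_prev", "prev_to_notified_ratio"),
    "direct_counts": ("tbhiv_direct_counts",),
}


@dataclass(frozen=True)
class CountryScenario:
    """All inputs for one country under one modeling scenario."""

    country: str
    scenario: str
    tb_counts: AgeSexTable
    hhc_counts: AgeSexTable
    national_hiv_prev: AgeSexTable
    partnership_prop: AgeSexTable
    tbhiv_pathway: Pathway
    hhc_prevalence_ratio: UncertainValue
    tbhiv_agesex_prop: Optional[AgeSexTable] = None
    tbhiv_overall_prop: Optional[float] = None
    notified_hiv_prev: Optional[float] = None
    prev_to_notified_ratio: Optional[UncertainValue] = None
    tbhiv_direct_counts: Optional[AgeSexTable] = None

    def __post_init__(self) -> None:
        if self.country not in COUNTRIES:
            raise ValidationError(f"unknown country {self.country!r}")
        if self.scenario not in SCENARIOS:
            raise ValidationError(f"unknown scenario {self.scenario!r}")
        if self.tbhiv_pathway not in _PATHWAY_FIELDS:
            raise ValidationError(f"unknown TB-HIV pathway {self.tbhiv_pathway!r}")
        for f in _PATHWAY_FIELDS[self.tbhiv_pathway]:
            if getattr(self, f) is None:
                raise ValidationError(
                    f"pathway {self.tbhiv_pathway!r} requires field {f!r}"
                )
        self.national_hiv_prev.require_proportion("national_hiv_prev")
        self.partnership_prop.require_proportion("partnership_prop")
        if self.tbhiv_agesex_prop is not None:
            self.tbhiv_agesex_prop.require_proportion("tbhiv_agesex_prop")
        for name in ("tbhiv_overall_prop", "notified_hiv_prev"):
            v = getattr(self, name)
            if v is not None and not (0 <= v <= 1):
                raise ValidationError(f"{name} outside [0, 1]: {v}")
        if self.hhc_prevalence_ratio.mean <= 0:
            raise ValidationError("hhc_prevalence_ratio must be > 0")


def total_adults(scenario: CountryScenario) -> float:
    """Adults aged 15-49 in TB-affected households: index TB cases plus
    their household contacts, summed over all strata."""
    return (scenario.tb_counts + scenario.hhc_counts).total()


# ---------------------------------------------------------------------------
# fixture I/O
# ---------------------------------------------------------------------------

def default_fixtures_dir() -> Path:
    return Path(importlib.resources.files("tbsdc") / "data")


def _table_from_rows(rows: pd.DataFrame, param: str, country: str) -> AgeSexTable:
    cells = {}
    for _, r in rows.iterrows():
        cells[(r["sex"], str(r["age_band"]))] = float(r["value"])
    try:
        return AgeSexTable.from_dict(cells)
    except ValidationError as e:
        raise ValidationError(f"{country}/{param}: {e}") from e


def _load_cell_tables(path: Path, country: str, scenario: str) -> dict[str, AgeSexTable]:
    frames = []
    for name in ("table1.csv", "tbhiv_incident_synthetic.csv"):
        f = path / name
        if f.exists():
            frames.append(pd.read_csv(f, dtype={"age_band": str}))
    if not frames:
        raise FileNotFoundError(f"no fixture tables under {path}")
    df = pd.concat(frames, ignore_index=True)
    df = df[(df["country"] == country) & (df["scenario"].isin([scenario, "both"]))]
    out = {}
    for param, rows in df.groupby("parameter"):
        out[param] = _table_from_rows(rows, param, country)
    return out


def _uncertain_from_manifest(node) -> UncertainValue:
    if isinstance(node, (int, float)):
        return UncertainValue.exact(float(node))
    return UncertainValue(
        mean=float(node["mean"]),
        lower=float(node["lower"]) if "lower" in node else None,
        upper=float(node["upper"]) if "upper" in node else None,
        distribution=node.get("distribution", "normal"),
    )


def load_scenario(
    path: str | Path | None,
    country: str,
    scenario: str,
    hhc_prevalence_ratio: UncertainValue | float | None = None,
) -> CountryScenario:
    """Load and validate one country/scenario from a fixtures directory.

    ``path=None`` uses the fixtures packaged with the library (the published
    country parameter tables). ``hhc_prevalence_ratio`` overrides the pooled
    prevalence ratio from the manifest (e.g. for sensitivity analyses on the
    Ethiopia default of 1.0).
    """
    path = default_fixtures_dir() if path is None else Path(path)
    if country not in COUNTRIES:
        raise ValidationError(f"unknown country {country!r}")
    if scenario not in SCENARIOS:
        raise ValidationError(f"unknown scenario {scenario!r}")

    tables = _load_cell_tables(path, country, scenario)
    with open(path / "manifest.yaml") as f:
        manifest = yaml.safe_load(f)
    m_country = manifest[country]
    m_scen = m_country[scenario]

    for required in ("tb_counts", "hhc_counts", "national_hiv_prev", "partnership_prop"):
        if required not in tables:
            raise ValidationError(f"{country}/{scenario}: missing parameter {required!r}")

    pr = m_country.get("hhc_prevalence_ratio", 1.0)
    if hhc_prevalence_ratio is not None:
        pr = hhc_prevalence_ratio
    if not isinstance(pr, UncertainValue):
        pr = _uncertain_from_manifest(pr)

    ratio = m_scen.get("prev_to_notified_ratio")
    return CountryScenario(
        country=country,
        scenario=scenario,
        tb_counts=tables["tb_counts"],
        hhc_counts=tables["hhc_counts"],
        national_hiv_prev=tables["national_hiv_prev"],
        partnership_prop=tables["partnership_prop"],
        tbhiv_pathway=m_scen["tbhiv_pathway"],
        hhc_prevalence_ratio=pr,
        tbhiv_agesex_prop=tables.get("tbhiv_agesex_prop"),
        tbhiv_overall_prop=m_scen.get("tbhiv_overall_prop"),
        notified_hiv_prev=m_scen.get("notified_hiv_prev"),
        prev_to_notified_ratio=_uncertain_from_manifest(ratio) if ratio is not None else None,
        tbhiv_direct_counts=tables.get("tbhiv_direct_counts"),
    )


def write_scenario(scenario: CountryScenario, path: str | Path) -> None:
    """Write a scenario back out in the fixture CSV + manifest dialect.

    ``load_scenario(write_scenario(s)) == s`` cell-for-cell (round-trip).
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rows = []

    def emit(param: str, table: AgeSexTable, scen: str) -> None:
        for i, sex in enumerate(SEXES):
            for j, band in enumerate(AGE_BANDS):
                rows.append(
                    dict(country=scenario.country, scenario=scen, parameter=param,
                         sex=sex, age_band=band, value=table.values[i, j],
                         lower="", upper="")
                )

    emit("national_hiv_prev", scenario.national_hiv_prev, "both")
    emit("partnership_prop", scenario.partnership_prop, "both")
    emit("tb_counts", scenario.tb_counts, scenario.scenario)
    emit("hhc_counts", scenario.hhc_counts, scenario.scenario)
    if scenario.tbhiv_agesex_prop is not None:
        emit("tbhiv_agesex_prop", scenario.tbhiv_agesex_prop, scenario.scenario)
    if scenario.tbhiv_direct_counts is not None:
        emit("tbhiv_direct_counts", scenario.tbhiv_direct_counts, scenario.scenario)
    pd.DataFrame(rows).to_csv(path / "table1.csv", index=False)

    def unc_node(u: UncertainValue):
        if u.scale_se() == 0 and u.lower is None:
            return dict(mean=u.mean, distribution=u.distribution)
        node = dict(mean=u.mean, distribution=u.distribution)
        if u.lower is not None:
            node.update(lower=u.lower, upper=u.upper)
        if u.se is not None:
            node.update(se=u.se)
        return node

    scen_node: dict = {"tbhiv_pathway": scenario.tbhiv_pathway}
    if scenario.tbhiv_overall_prop is not None:
        scen_node["tbhiv_overall_prop"] = scenario.tbhiv_overall_prop
    if scenario.notified_hiv_prev is not None:
        scen_node["notified_hiv_prev"] = scenario.notified_hiv_prev
    if scenario.prev_to_notified_ratio is not None:
        scen_node["prev_to_notified_ratio"] = unc_node(scenario.prev_to_notified_ratio)
    manifest = {
        scenario.country: {
            scenario.scenario: scen_node,
            "hhc_prevalence_ratio": unc_node(scenario.hhc_prevalence_ratio),
        }
    }
    with open(path / "manifest.yaml", "w") as f:
        yaml.safe_dump(manifest, f)


def load_published_estimates(path: str | Path | None = None) -> pd.DataFrame:
    """The published per-country household estimates (point values and the
    serodifferent-couple counts with their 95% uncertainty intervals), used
    as inputs to the PrEP-impact step."""
    path = default_fixtures_dir() if path is None else Path(path)
    return pd.read_csv(path / "published_estimates.csv")


def published_n_sdc(country: str, scenario: str, path=None) -> UncertainValue:
    df = load_published_estimates(path)
    row = df[(df["country"] == country) & (df["scenario"] == scenario)]
    if row.empty:
        raise ValidationError(f"no published estimate for {country}/{scenario}")
    r = row.iloc[0]
    return UncertainValue(
        mean=float(r["n_sdc"]), lower=float(r["n_sdc_lower"]),
        upper=float(r["n_sdc_upper"]), distribution="normal",
    )
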