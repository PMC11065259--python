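"""Synthetic data generators for fitting and pooling experiments.

The package's statistical machinery (curve fitting, meta-analysis) was
developed against survey microdata that is not redistributable, so tests
and examples run on synthetic stand-ins:

* DHS-like survey points — (prevalence, P_SDC) pairs on a known curve plus
  Gaussian noise, prevalences drawn log-uniformly to mirror the skew of
  sub-Saharan national prevalences (roughly 0.5%-30%);
* couple serostatus tables under a single-factor assortative mixing model;
* household-contact study sets with lognormal between-study heterogeneity.

All generators are bit-reproducible under a fixed seed.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .meta import StudyRecord
from .psdc import DEFAULT_FORM, Form, SurveyPoint, psdc


def gen_survey_points(
    alpha_true: float,
    n_surveys: int = 19,
    prev_range: tuple[float, float] = (0.005, 0.30),
    noise_sd: float = 0.0,
    seed: int = 0,
    form: Form = DEFAULT_FORM,
) -> list[SurveyPoint]:
    """Survey points on the serodifference curve at ``alpha_true``.

    Prevalences are log-uniform on ``prev_range``; observed P_SDC is the
    curve value plus Normal(0, noise_sd) noise, truncated to [0, 1].
    """
    low, high = prev_range
    if not 0 < low < high < 1:
        raise ValueError(f"invalid prevalence range {prev_range}")
    if n_surveys < 2:
        raise ValueError("need at least 2 surveys")
    rng = np.random.default_rng(seed)
    prev = np.exp(rng.uniform(np.log(low), np.log(high), n_surveys))
    y = psdc(prev, alpha_true, form) + rng.normal(0.0, noise_sd, n_surveys)
    y = np.clip(y, 0.0, 1.0)
    return [SurveyPoint(float(p), float(q)) for p, q in zip(prev, y)]


@dataclass(frozen=True)
class CoupleTable:
    """Couple counts by (male, female) serostatus; p = positive, n = negative."""

    n_pp: int
    n_pn: int
    n_np: int
    n_nn: int

    def __post_init__(self) -> None:
        if min(self.n_pp, self.n_pn, self.n_np, self.n_nn) < 0:
            raise ValueError("negative couple count")
        if self.total < 1:
            raise ValueError("need at least one couple")

    @property
    def total(self) -> int:
        return self.n_pp + self.n_pn + self.n_np + self.n_nn

    @property
    def empirical_p_sdc(self) -> float:
        """Serodifferent couples as a share of partnered people living with
        HIV: discordant couples hold one such person each, concordant-
        positive couples hold two."""
        disc = self.n_pn + self.n_np
        denom = disc + 2 * self.n_pp
        return disc / denom if denom else 0.0


def couple_cell_probs(prevalence: float, assortativity: float) -> np.ndarray:
    """Closed-form cell probabilities [pp, pn, np, nn] under the
    single-factor concordance model: each partner is marginally positive
    with probability ``prevalence``; the concordant-positive cell is
    multiplied by ``assortativity`` and the off-diagonal cells rebalanced
    to preserve both margins."""
    if not 0 <= prevalence < 1:
        raise ValueError("prevalence must be in [0, 1)")
    if assortativity < 1:
        raise ValueError("assortativity must be >= 1")
    p = prevalence
    pp = assortativity * p * p
    pn = p - pp
    nn = 1 - 2 * p + pp
    probs = np.array([pp, pn, pn, nn])
    if np.any(probs < 0) or np.any(probs > 1):
        raise ValueError(
            f"assortativity {assortativity} infeasible at prevalence {p}")
    return probs


def gen_couple_table(
    prevalence: float, assortativity: float = 1.0,
    n_couples: int = 1000, seed: int = 0,
) -> CoupleTable:
    """Multinomial sample of couple serostatus under assortative mixing."""
    probs = couple_cell_probs(prevalence, assortativity)
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_couples, probs)
    return CoupleTable(*(int(c) for c in counts))


def gen_study_set(
    pr_true: float,
    n_studies: int,
    sizes: list[int],
    ref_prevalence: float,
    tau: float = 0.0,
    seed: int = 0,
) -> list[StudyRecord]:
    """Household-contact studies with lognormal heterogeneity around a true
    prevalence ratio. Study contact prevalences implied above 1 are capped
    (and the cap is recorded on the record's study_id suffix '!capped')."""
    if len(sizes) != n_studies:
        raise ValueError("need one size per study")
    if any(s < 10 for s in sizes):
        raise ValueError("study sizes must be >= 10")
    rng = np.random.default_rng(seed)
    log_prs = rng.normal(np.log(pr_true), tau, n_studies)
    out = []
    for i, (lpr, n) in enumerate(zip(log_prs, sizes)):
        p = ref_prevalence * np.exp(lpr)
        capped = p > 1
        p = min(p, 1.0)
        cases = int(rng.binomial(n, p))
        out.append(
            StudyRecord(
                study_id=f"synthetic-{i}" + ("!capped" if capped else ""),
                hhc_cases=cases, hhc_n=int(n), ref_prevalence=ref_prevalence,
            )
        )
    return out
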