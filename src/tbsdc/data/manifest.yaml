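# TB-HIV pathway and scalar parameters per country/scenario.
# hhc_prevalence_ratio: pooled random-effects prevalence ratio of HIV among
# household TB contacts vs the general adult population (Ethiopia: no eligible
# studies; defaults to 1.0 and is a config knob).
Ethiopia:
  incidence:
    tbhiv_pathway: direct_counts
  prevalence:
    tbhiv_pathway: notified_times_ratio
    notified_hiv_prev: 0.0538
    prev_to_notified_ratio: {mean: 0.47, lower: 0.34, upper: 0.65, distribution: lognormal}
  hhc_prevalence_ratio: {mean: 1.0, distribution: lognormal}
Kenya:
  incidence:
    tbhiv_pathway: direct_counts
  prevalence:
    tbhiv_pathway: age_sex_proportion
  hhc_prevalence_ratio: {mean: 4.12, lower: 1.50, upper: 11.31, distribution: lognormal}
South Africa:
  incidence:
    tbhiv_pathway: direct_counts
  prevalence:
    tbhiv_pathway: overall_proportion
    tbhiv_overall_prop: 0.288
  hhc_prevalence_ratio: {mean: 1.11, lower: 0.75, upper: 1.64, distribution: lognormal}
Uganda:
  incidence:
    tbhiv_pathway: direct_counts
  prevalence:
    tbhiv_pathway: age_sex_proportion
  hhc_prevalence_ratio: {mean: 1.86, lower: 1.54, upper: 2.23, distribution: lognormal}
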