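country,scenario,parameter,sex,age_band,value,lower,upper
Ethiopia,incidence,tbhiv_direct_counts,male,15-24,389.4,,
Ethiopia,incidence,tbhiv_direct_counts,male,25-34,1383.0,,
Ethiopia,incidence,tbhiv_direct_counts,male,35-44,2676.3,,
Ethiopia,incidence,tbhiv_direct_counts,male,45-49,1547.8,,
Ethiopia,incidence,tbhiv_direct_counts,female,15-24,1194.2,,
Ethiopia,incidence,tbhiv_direct_counts,female,25-34,5051.9,,
Ethiopia,incidence,tbhiv_direct_counts,female,35-44,5780.1,,
Ethiopia,incidence,tbhiv_direct_counts,female,45-49,1371.9,,
Kenya,incidence,tbhiv_direct_counts,male,15-24,533.4,,
Kenya,incidence,tbhiv_direct_counts,male,25-34,2371.2,,
Kenya,incidence,tbhiv_direct_counts,male,35-44,4492.7,,
Kenya,incidence,tbhiv_direct_counts,male,45-49,2916.1,,
Kenya,incidence,tbhiv_direct_counts,female,15-24,2140.7,,
Kenya,incidence,tbhiv_direct_counts,female,25-34,7951.9,,
Kenya,incidence,tbhiv_direct_counts,female,35-44,8596.1,,
Kenya,incidence,tbhiv_direct_counts,female,45-49,2658.4,,
South Africa,incidence,tbhiv_direct_counts,male,15-24,2083.4,,
South Africa,incidence,tbhiv_direct_counts,male,25-34,18624.2,,
South Africa,incidence,tbhiv_direct_counts,male,35-44,23273.9,,
South Africa,incidence,tbhiv_direct_counts,male,45-49,5298.5,,
South Africa,incidence,tbhiv_direct_counts,female,15-24,15547.1,,
South Africa,incidence,tbhiv_direct_counts,female,25-34,61421.5,,
South Africa,incidence,tbhiv_direct_counts,female,35-44,35754.3,,
South Africa,incidence,tbhiv_direct_counts,female,45-49,4549.3,,
Uganda,incidence,tbhiv_direct_counts,male,15-24,799.5,,
Uganda,incidence,tbhiv_direct_counts,male,25-34,3610.2,,
Uganda,incidence,tbhiv_direct_counts,male,35-44,5959.1,,
Uganda,incidence,tbhiv_direct_counts,male,45-49,3408.5,,
Uganda,incidence,tbhiv_direct_counts,female,15-24,3485.3,,
Uganda,incidence,tbhiv_direct_counts,female,25-34,7726.4,,
Uganda,incidence,tbhiv_direct_counts,female,35-44,5122.9,,
Uganda,incidence,tbhiv_direct_counts,female,45-49,1670.6,,
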