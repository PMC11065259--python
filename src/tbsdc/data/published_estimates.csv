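country,scenario,n_hivpos,n_people,hh_prev_pct,n_sdc,n_sdc_lower,n_sdc_upper,p_sdc_hh_pct,p_sdc_pop_pct
Kenya,incidence,100963,508403,19.85,21004,9482,31279,15.73,5.7
Uganda,incidence,66000,390743,16.9,15683,13651,17862,14.53,6.0
Ethiopia,incidence,24595,799198,3.08,9327,7988,10790,4.1,0.8
South Africa,incidence,311163,944835,32.96,41099,33957,48299,20.68,15.7
Kenya,prevalence,154026,835048,18.45,32775,12317,50639,14.93,5.7
Uganda,prevalence,88312,616268,14.34,22137,18631,25723,13.0,6.0
Ethiopia,prevalence,14901,1252461,1.19,6744,5440,8244,1.89,0.8
South Africa,prevalence,424211,1465888,28.95,60038,47043,71865,19.38,15.7
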