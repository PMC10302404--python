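class,n_wetlands,total_area_km2,mean_area_km2,pct_of_domain
Riparian,1,0.0018,0.0018,1.3888888888888888
NRShw,1,0.0018,0.0018,1.3888888888888888
NRMid,2,0.0027,0.00135,2.0833333333333335
NRDeep,1,0.0018,0.0018,1.3888888888888888
Unclassified,1,0.0018,0.0018,1.3888888888888888
Total,6,0.009899999999999999,0.0016499999999999998,7.638888888888888
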