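catchment_id,local_area_km2,area_Riparian,pct_Riparian,area_NRShw,pct_NRShw,area_NRMid,pct_NRMid,area_NRDeep,pct_NRDeep,area_Unclassified,pct_Unclassified,dominant_class
1,0.054,0.0,0.0,0.0018,3.333333333333333,0.0018,3.333333333333333,0.0018,3.333333333333333,0.0018,3.333333333333333,NRShw
2,0.0756,0.0018,2.380952380952381,0.0,0.0,0.0009,1.1904761904761905,0.0,0.0,0.0,0.0,Riparian
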