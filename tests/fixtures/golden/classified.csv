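wet_id,patch_id,catchment_id,pixel_count,area_km2,adjacent,connectivity_class,terminal,min_ksat,drainage_majority,path_length_m,n_path_cells,downstream_wet_ids,flag_reason
1,1,2,2,0.0018,True,Riparian,not_traced,,,,0,,
2,2,1,2,0.0018,False,NRShw,reached_stream,10.0,poorly_drained,150.0,6,,
3,3,1,2,0.0018,False,NRMid,reached_stream,10.0,well_drained,120.0,5,4,
4,3,2,1,0.0009,False,NRMid,reached_stream,10.0,well_drained,90.0,4,,
5,4,1,2,0.0018,False,NRDeep,reached_stream,1.0,well_drained,150.0,6,,
6,5,1,2,0.0018,False,Unclassified,reached_stream,,,150.0,6,,
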