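anchor_row,anchor_col,expected_class
2,8,Riparian
4,3,NRShw
6,4,NRMid
6,5,NRMid
8,3,NRDeep
10,3,Unclassified
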