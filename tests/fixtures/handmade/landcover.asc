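ncols 12
nrows 12
xllcorner 0
yllcorner 0
cellsize 30
NODATA_value 0
41 41 41 41 41 41 41 41 41 11 41 41
41 41 41 41 41 41 41 41 41 11 41 41
41 41 41 41 41 41 41 95 95 11 41 41
41 41 41 41 41 41 41 41 41 41 41 41
41 41 95 95 41 41 41 41 41 41 41 41
41 41 41 41 41 41 41 41 41 41 41 41
41 41 41 95 95 95 41 41 41 41 41 41
41 41 41 41 41 41 41 41 41 41 41 41
41 41 95 95 41 41 41 41 41 41 41 41
41 41 41 41 41 41 41 41 41 41 41 41
41 41 95 95 41 41 41 41 41 41 41 41
41 41 41 41 41 41 41 41 41 41 41 41
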