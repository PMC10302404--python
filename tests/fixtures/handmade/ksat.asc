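ncols 12
nrows 12
xllcorner 0
yllcorner 0
cellsize 30
NODATA_value -9999
10 10 10 10 10 10 10 10 10 10 10 10
10 10 10 10 10 10 10 10 10 10 10 10
10 10 10 10 10 10 10 10 10 10 10 10
10 10 10 10 10 10 10 10 10 10 10 10
10 10 10 10 10 10 10 10 10 10 10 10
10 10 10 10 10 10 10 10 10 10 10 10
10 10 10 10 10 10 10 10 10 10 10 10
10 10 10 10 10 10 10 10 10 10 10 10
10 10 10 10 10 1 10 10 10 10 10 10
10 10 10 10 10 10 10 10 10 10 10 10
10 10 10 -9999 -9999 -9999 -9999 -9999 -9999 10 10 10
10 10 10 10 10 10 10 10 10 10 10 10
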