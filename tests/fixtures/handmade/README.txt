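Hand-written 12x12 fixture family
=================================

A fully explicit, human-auditable landscape holding one wetland per
connectivity class plus an engineered Unclassified case, independent of
the synthetic generator.  Grid frame: 12x12 cells, 30 m cells, origin
(0, 360), so each cell is 900 m^2.

Layers (ESRI ASCII grids):
  landcover.asc    41 upland, 95 wetland, 11 open water
  fdr.asc          D8 flow direction, all cells code 1 (due east)
  streamlines.asc  rasterized stream line down column 9
  catchments.asc   catchment 1 = columns 0-4, catchment 2 = columns 5-11
  ksat.asc         10 cm/h everywhere except 1 cm/h at (row 8, col 5)
                   and nodata (-9999) at (10, 3)..(10, 8)
  drainage.asc     NRCS code 3 (well drained) everywhere except code 6
                   (poorly drained) at (4, 4)..(4, 8) and nodata (-1)
                   at (10, 3)..(10, 8)

Flow accumulation is derived from fdr.asc at test time (value = col + 1).

Wetlands and their engineered classes (truth.csv, anchored on the cell
holding each wetland's pour point):

  (2,7)-(2,8)        pour (2,8), one cell from the stream  -> Riparian
  (4,2)-(4,3)        path (4,3)..(4,8): Ksat 10, drainage majority
                     poorly drained (150 m poor vs 30 m well) -> NRShw
  (6,3)-(6,5)        straddles the catchment boundary, so it splits into
                     two units: (6,3)-(6,4) and (6,5); both paths are
                     permeable and well drained               -> NRMid x2
  (8,2)-(8,3)        path (8,3)..(8,8) crosses the 1 cm/h cell -> NRDeep
  (10,2)-(10,3)      path (10,3)..(10,8) has nodata soils  -> Unclassified
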