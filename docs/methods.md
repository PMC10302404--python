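# Methods

This note documents the models and procedures `wetconnect` implements,
the choices made where the design was genuinely open, and what the
synthetic test data do and do not establish about behaviour on real
landscapes.

## Raster model and D8 hydrology

All layers are single-band rasters on one shared frame (shape, cell size,
upper-left origin); alignment is verified before any computation and a
mismatch is a hard error. The default cell size is 30 m (900 m² pixels),
matching the national land-cover and hydrography grids the classification
was designed around, but nothing depends on that value.

Flow routing is single-direction D8 with the powers-of-two code table
(1 = E, 2 = SE, 4 = S, 8 = SW, 16 = W, 32 = NW, 64 = N, 128 = NE),
defined once in `wetconnect.d8`. Choices within the D8 primitives:

* **Flow accumulation counts the cell itself** (minimum value 1). Only
  the *rank* of accumulation is consumed downstream (pour points are
  argmaxes), and any constant offset is rank-preserving, so the
  convention is benign; self-counting keeps "the pixel with the highest
  accumulation" well defined on one-pixel wetlands.
* **Sink cells accumulate.** A cell with a nodata direction code (pit,
  outlet) receives inflow and passes nothing on. This makes accumulation
  exactly the graph-reachability count (ancestors + self) for every
  cell, which is what the brute-force oracle computes.
* **Acyclicity is validated up front.** A direction cycle raises an
  error naming a cell on the cycle rather than silently truncating.
* **`d8_from_dem`** sends each cell to its steepest-descent neighbour
  (drop ÷ distance, diagonal distance cell·√2), ties broken in fixed
  code order 1, 2, 4, …, 128. Pits and flats become nodata — there is no
  DEM conditioning (breaching/filling) in this package; the synthetic
  generator is responsible for pit-free terrain.
* **Patch connectivity defaults to 8** (ordinal + cardinal neighbours),
  consistent with the riparian adjacency rule; 4-connectivity is an
  option.

## Wetland units

Wetland pixels are land-cover codes 90 (woody) and 95 (emergent
herbaceous), merged; the distinction is discarded after masking.
Contiguous patches are labelled, then subdivided wherever they cross
catchment boundaries, making each (patch, catchment) piece a
hydrologically distinct unit with a dense WetId. Conventions:

* Pour-point ties (equal accumulation) break to the smallest (row, col)
  in row-major order, making delineation deterministic across runs and
  iteration orders.
* WetIds are unique only within one processing run; outputs are
  namespaced by run.
* Wetland pixels over a nodata catchment (e.g. at the grid margin) are
  kept as a unit flagged straight to Unclassified rather than dropped,
  so area accounting stays complete.

## Streams and adjacency

Receiving waters are the union of open-water land-cover pixels (code 11)
and a rasterized stream-line grid ("buffered streams"); per-cell
provenance (water / line / both) is retained for diagnostics. A wetland
is riparian when its pour point is within Chebyshev distance 1 of a
buffered-stream cell; distance 0 (the outlet lies on mapped water)
counts as riparian — a wetland overlapping the channel is maximally
connected. The test conditions on the outlet only, not on arbitrary
wetland pixels. No attempt is made to separate rivers from lakes or
estuaries among water pixels.

## Flowpaths and classification

Flowpaths walk the D8 grid from the pour point and stop *before*
stepping onto a stream cell, so paths contain land cells only (the pour
point is always included, even when the stream is one step away).
Paths cross catchment boundaries freely and may pass through downstream
wetlands; cells inside intermediate wetlands are included in the soil
aggregation, and the WetIds crossed are recorded per path for
transparency. Every failure mode is encoded in a terminal status
(`exited_grid`, `hit_nodata`, `loop_detected`, `max_steps`) rather than
raised, and any non-`reached_stream` terminal yields Unclassified. The
default step budget equals the grid cell count, making non-termination
impossible. This is pure steepest-descent routing; tools that route
cost-paths around obstacles could differ, and no travel-time or distance
metric is computed.

Soil aggregation along the path:

* **K<sub>sat</sub>** (cm h⁻¹): minimum over non-nodata path cells; the least
  permeable cell limits flow. The permeability threshold defaults to
  5.08 cm h⁻¹. Equality counts as permeable: the source rules state
  strict inequalities on both sides and leave the boundary open, so it
  is resolved here (configurable via the threshold argument).
* **Drainage**: each cell contributes its step length (cell size for
  cardinal steps, cell·√2 for diagonal; the pour-point cell contributes
  one cell size). NRCS codes 1–4 count as well drained, 5–7 as poorly
  drained; the group with greater total length wins, and an exact tie
  goes to poorly drained (conservative toward the class with more
  frequent surface connection). Unknown codes are data errors.
* Nodata soil cells are skipped rather than poisoning the path; a path
  with no valid K<sub>sat</sub> (or a permeable path with no valid drainage) is
  Unclassified. The package defines this explicit failure taxonomy
  rather than reverse-engineering the causes of unclassified wetlands in
  any particular national dataset.

Decision order: adjacency → path success → K<sub>sat</sub> branch → drainage
branch. Raising the threshold can only move wetlands from NRShw/NRMid
toward NRDeep (monotonicity, tested), and riparian assignments are
invariant to the soil grids (tested).

## Watershed summaries

Class extent per catchment is 100 × (class wetland area ÷ catchment
area). Watershed (accumulated) percentages sum *areas* over the
upstream tree before dividing — averaging percentages would weight small
catchments incorrectly. Dominant class is by area (not count), with
ties broken by decreasing connectivity (Riparian > NRShw > NRMid >
NRDeep > Unclassified). The domain area for percent-of-domain
statistics is an explicit input. Per-class statistics (count, total
area, mean area, percent of domain) carry a totals row that must equal
the column sums.

## Synthetic landscapes

The generator builds internally consistent bundles so every spatial
module is testable without downloads. Terrain is a V-shaped valley —
an eastward tilt plus a cross-slope toward a central row, scaled to a
relief (default 60 m on a 40×60 grid), plus bounded uniform noise
(default half-range 0.2% of relief) — regenerated with fresh noise until
the interior is pit-free, raising after bounded retries. This
guarantees D8 validity without implementing DEM conditioning. The
valley concentrates flow into a single eastward channel; stream cells
are accumulation ≥ threshold (default 4× the row count, high enough that
hillslope cells never qualify). Catchments are built by chunking the
channel into segments along flow order and walking every cell to the
first stream cell it reaches; the segment topology is acyclic by
construction.

Wetlands are grown 8-connected from anchors (riparian intents inside the
one-pixel stream buffer, non-riparian intents at least two cells away),
and soils along each traced flowpath are painted per recipe: NRShw —
poorly drained path; NRMid — well drained path; NRDeep — one mid-path
cell at K<sub>sat</sub> 1 cm h⁻¹; Unclassified — path soils nodata. Background
soils are neutral (K<sub>sat</sub> 10 cm h⁻¹, well drained) so each wetland's
class is controlled by its own recipe, and a claimed-cell registry makes
recipe collisions impossible (a colliding placement raises). The
generator's postcondition — running the real pipeline reproduces the
intended classes exactly — is checked at build time and again in the
test battery.

What passing these tests shows: the pipeline implements the decision
rules exactly, end to end, on hydrologically consistent inputs. What it
does not show: behaviour under real-data pathologies — misregistered
layers, land-cover classification error, braided or disconnected
hydrography, soil polygons rasterized at coarser support. A separate
hand-written 12×12 fixture family (every grid value printed in the
repository) provides human-auditable ground truth independent of the
generator.

## Water-quality assessment

Preparation runs in a fixed order: censored-row removal → transform →
standardization → collinearity screen. TSS, Al and NO₃ rows at zero or
at a *declared* detection limit are removed (limits are configuration;
there is no automatic detection of censoring). Responses are
ln-transformed except pH, which is raised to the fourth power and is
exempt from the positivity requirement. Response and predictors are
standardized to mean 0, SD 1 on the modelling subset, with the
(mean, SD) ledger retained. Variance inflation factors
(VIF<sub>j</sub> = 1/(1−R²<sub>j</sub>)) are reported with a non-fatal flag at VIF ≥ 2.

The model is a linear mixed-effects regression fitted by REML
(statsmodels `MixedLM`): fixed effects for the four class percentages
(always) and covariates; a random intercept by region; and independent
random slopes, one variance component per predictor. Independent
components (rather than an unstructured covariance with the intercept)
keep the maximal model identifiable and fast; this matches the
simulator's generating process.

Backward selection removes random slopes first, via likelihood-ratio
tests between REML fits (valid because the fixed structure is held
constant), then non-class fixed covariates via ML refits (REML
likelihoods are not comparable across fixed structures). One
least-significant term is removed per round at α = 0.05. The four class
fixed effects are never candidates, so their slopes are extractable even
when non-significant; the random intercept is also always retained —
removing it would change estimator class mid-selection. Random-effect
LRT p-values carry no boundary correction; since the boundary-corrected
p-value would be smaller, this makes random-slope *removal* slightly
easier, a documented simplification. Terms whose reduced fit fails to
converge are skipped and noted in the selection trace. Grouping-variable
choice (`select_grouping`) compares ML AIC across candidate groupings.

A slope of 0.5 reads as: the response rises half a standard deviation
per one-standard-deviation increase in that class's watershed
percentage. Significance is `|slope| > 2·se`.

### Simulator and calibration

`simulate_wq` draws right-skewed class percentages (beta-distributed,
scaled to 0–100) and log-normal covariates, standardizes them, and forms
the response from fixed slopes, a region random intercept, independent
region random slopes and Gaussian residual. Defaults mirror the
recovery study design: 1,500 sites, 9 regions, slopes (0.4, 0.2, 0.1,
−0.2), one covariate at 0.3, random intercept SD 0.3, class random-slope
SD 0.1, residual SD 0.7. The analytic response SD (predictors
independent and standardized, so var(y) = Σβ² + σ<sub>u</sub>² + Σσ<sub>c</sub>² + σ<sub>ε</sub>²)
converts generating slopes to the standardized-response scale the
pipeline estimates.

Calibration facts the tests establish: estimates fall within 2 se of
truth in ≥ 90% of replicates per class, and with a true-zero slope the
2-se rule fires at roughly the nominal 5% (band 2–9% at 200
replicates). Wald 2-se intervals do not propagate variance-component
uncertainty, so with only 9 regions their true coverage is ≈ 92–94%
rather than 95.4% — the same property holds for the usual mixed-model
software; worst-class coverage at 100 replicates can therefore brush
the 90% line depending on the random draw.

## Numerical and scale choices

* Optimizers for the mixed fits are tried in order lbfgs → bfgs →
  powell, accepting the first finite likelihood (lbfgs can report an
  infinite likelihood at the zero-variance boundary).
* Test batteries use small grids (≤ 20×20 for oracles, 40×60 scenarios)
  and 100–200 Monte-Carlo replicates; these sizes give the oracle
  comparisons full coverage and the statistical checks ±2–3% resolution,
  and a full run of suite plus acceptance script completes in a few
  minutes on one CPU.
* All randomness is seeded; scenario bundles are bit-identical for
  identical specs, and the pipeline's CSV outputs are byte-identical
  across reruns.

## Known limitations

* Pure D8 routing: no multiple-flow-direction or cost-path routing, no
  DEM conditioning, no travel times or distances.
* Structural connectivity only: no climate-driven (functional)
  connectivity, no hydrologic alterations (ditches, tile drains).
* The censored-data handling is row removal, not a censored likelihood;
  spatial autocorrelation beyond the regional grouping is not modelled.
* The synthetic generator makes idealized geomorphology and error-free
  layers; see above for what that implies about real-data claims.
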