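# Methods

## Model

Habitat quality for a bird group on a 30 m cell is
`Q = H * (1 - D^z / (D^z + k^z))` with scaling constant `z = 2.5` and
half-saturation constant `k = 0.5`. `H` is the class-level habitat
suitability (0 / 0.5 / 1), and `D` is the combined degradation — a
weight-normalized, sensitivity-scaled sum of threat exposures. Because the
weights are divided by their sum and every exposure and sensitivity lies in
[0, 1], `D` is bounded in [0, 1]; the fixed `k = 0.5` therefore marks the
exposure level at which quality is halved under any weight setting, and
scaling all weights by a common factor leaves `D` (and `Q`) unchanged.
This normalization is a deliberate design choice: it is the only reading
under which additive multi-threat degradation keeps `D` on the scale that
a fixed half-saturation constant presumes.

Threat exposures come in two kinds. *In-place* threats (dryness, wetland
size class) apply the raster value at the cell. *Proximity* threats (crop,
corn, road, roost densities) are first computed as focal densities over a
circular window (cell centers within the radius, normalized by the window
cells inside the grid so constant fields are preserved at edges), then
smoothed with a linear distance-decay kernel (weight `1 - d/d_max`,
normalized to unit sum, edge-renormalized the same way). Whether the focal
window itself or an additional decay pass represents distance attenuation
is genuinely ambiguous in this model family; both are implemented
(`QualityParams.decay_enabled`), with decay-on as the default.

Corn, roost and dryness are *scarcity* threats: the density (or water
frequency) is subtracted from one, so well-provisioned neighborhoods carry
low threat.

### Bird groups

| group | roost radius | window | threats |
|---|---|---|---|
| field-foraging dabblers | 18.5 km | Mar–Apr | dry, crop, roost, road, corn |
| wetland-foraging dabblers | 5 km | Mar–Apr | dry, crop, roost, road |
| diving ducks | 4 km | Mar–Apr | dry, crop, roost, road, wetarea |
| shorebirds | 10 km | Apr–May | dry, crop, roost, road |

Suitability defaults encode the qualitative rules of the source model
family: drained depressional crops are fully suitable for all groups
except diving ducks; constructed water-quality pools are treated as
semipermanent wetlands (suitable for ducks, unsuitable for shorebirds
unless the one-pixel shallow shoreline ring is mapped); easement buffers
are upland and unsuitable. The exact per-class values are expert-elicited
in the underlying studies and are fully overridable from a YAML codebook;
per-(class, threat) sensitivities default to 1 on suitable classes and 0
elsewhere, also overridable.

### Wetland size classes

Wetland components are grouped with 8-neighbor connectivity; component
area is pixel count × 0.09 ha. Threat 0 for areas strictly above 4 ha, 0.5
for 0.4–4 ha inclusive, 1.0 below 0.4 ha. The boundary cases (exactly 4 ha
and exactly 0.4 ha) both score 0.5, following the strict-inequality
reading of the size rules; neither area is attainable exactly on a 30 m
grid anyway.

### Hydroperiod summarization

Scene codes 1 (open water, high confidence), 2 (open water, moderate
confidence) and 3 (partial surface water, conservative) are water; all
other codes are not; clouded pixels are unobserved. Two summarizations of
a multi-year scene stack produce the *dry* threat for a seasonal window:

* **presence/absence** — scenes are composited per year by per-pixel
  maximum; `dry = 1 - years_wet / years_observed`. A year enters a pixel's
  denominator only if the pixel had at least one cloud-free observation
  that year, the per-pixel analogue of selecting years with usable
  coverage.
* **all measurements** — `dry = 1 - wet_obs / total_obs` over every
  cloud-free observation.

The two agree exactly when each year contributes one cloud-free scene.
Pixels never observed cloud-free are nodata, *not* dry = 1: the post-model
filter removes depressions with no records instead of penalizing them.
When such pixels must still enter a degradation computation (the
unfiltered variant), they are filled with dryness 1.0, the conservative
reading for a pixel with no evidence of water.

### Scenarios and post-model filtering

Baseline mosaic order (later overrides earlier): crop base → depressional
classes (each depression takes its patch-majority crop, depressional
variant) → NWI wetlands → 30 m interior littoral edge of lacustrine
patches → roads. Drainage modernization converts every depression pixel —
including wetland cover inside depressions — to the patch's majority
non-depressional crop class; majority ties break to the lowest class code
(deterministic and order-independent). Water-quality wetlands stamp pool,
easement and (optionally) a one-pixel interior shoreline ring over
whatever they land on; construction replaces prior cover. All interior
rings use binary erosion with the 4-connected cross element, which yields
uniform single-pixel rings on axis-aligned shapes.

The *active-only* filter zeroes Q inside depressions with no surface-water
record in any composite for the group's window. Pixels are zeroed rather
than excised so bin areas remain comparable across filters.

Percent change is `100 (scenario - baseline) / baseline`, always within
the same weight preset and filter. Quality bins partition Q > 0 into
≤ 0.01 / (0.01, 0.05] / (0.05, 0.15] / > 0.15; the published bin
descriptions overlap at the top end, so this partition is fixed here and
used consistently.

### Sensitivity grid

One preset per threat elevates that threat's weight (3× with the others at
1/3 for four-threat groups; 4× with the others at 0.25 where a fifth
threat exists, except the field-forager grid which uses 3×/0.25), plus an
all-equal preset that reproduces the base run bit-for-bit. Threat rasters
and decay-smoothed exposures are preset-independent, so the grid re-weights
cached exposures rather than re-running convolutions.

## Synthetic landscapes

The generator emulates the structure the analysis assumes, not any real
watershed:

* **Crop mosaic** — ~400 m blocky fields; a field is cropland with
  probability `crop_fraction` (default 0.85), corn vs soy split 0.55, 10%
  of cropland in other crops; non-crop fields are grassland with a 12%
  developed share. Roads are a regular 1-pixel grid at 1,600 m spacing (a
  section-road default; no published road geometry exists for this model).
* **Depressions** — random ellipses with log-normal areas anchored to the
  published inventory quantiles (min 0.04, median 0.47, max 50.15 ha;
  sigma set so the extremes sit near ±3σ of log-area), placed on cropland
  inside the watershed, non-overlapping. Requesting more depression area
  than cropland fails explicitly.
* **Watershed mask** — full grid by default; for published catchment
  presets, a centered disc of exactly `round(area_ha / 0.09)` pixels so
  the mask area reproduces the printed hectares at printed precision.
* **Water-quality wetland** — one elliptical pool near the lower
  ("outlet") third of the grid sized to `wq_wetland_fraction` of the mask
  (presets span the published 0.4–6.4%), with a 90 m easement ring
  (published easements follow a 1.2 m elevation rule that has no analogue
  on a synthetic flat grid; a fixed-width ring stands in, width
  configurable).
* **Ponding** — each depression ponds in a given spring with a per-patch
  probability drawn from 0.14–0.47 (the span of published ponding-frequency
  estimates for drained depressions in this landscape); semipermanent
  wetlands pond with probability 0.95. Within a ponding patch the wet
  extent is the deepest fraction of cells by distance-to-edge rank (a
  depth proxy — only the ordering matters), so wet extents are nested
  across realizations. The within-patch ponded-area fraction
  (uniform 0.4–1.0 per scene) is an assumption; no published
  within-depression ponded-fraction model exists.
* **Scenes** — three acquisitions per seasonal window per year (seven
  years by default), dated through March–May so the April overlap serves
  both windows; deepest 70% of wet cells code 1 (15% speckled to 2),
  shallow margin code 3 with occasional low-confidence code 4 (treated as
  not water); block-shaped cloud masks with per-scene cover drawn up to
  twice the nominal 0.3 cloud probability.

All randomness flows from one integer seed; identical configs produce
bit-identical rasters.

What the generator does **not** emulate: real hydrology (no water-balance
or depth-in-mm model), spatially correlated weather between patches and
years, real road networks or field boundaries, scene-footprint geometry,
or the empirical covariance between depression size and ponding
frequency. Passing tests therefore demonstrate that the *machinery* —
overlay rules, summarizations, index arithmetic, filters, comparisons —
behaves correctly and that directional scenario effects (dabbler/shorebird
losses under drainage, diver gains from pools, shoreline benefits for
shorebirds) emerge from the encoded suitability structure; they say
nothing quantitative about any real watershed, and the published Iowa
percent changes are not a target.

## Numerical choices

* Convolutions (focal density, decay smoothing) run direct (`scipy.ndimage`)
  when `grid cells × kernel cells ≤ 4·10^7`, FFT otherwise; direct is exact
  against a per-pixel loop, FFT agrees to ~1e-12 relative. Edge handling
  renormalizes by in-grid kernel mass, never pads.
* Circular window membership: cell center within the radius (inclusive).
* Depth ranks carry a deterministic (row, col) tie-break so ponding order
  is unique and reproducible.
* Degradation on unsuitable cells is 0 by the default sensitivity rule;
  their Q is 0 through H anyway.
* Problem sizes: the shipped reference landscape is 200×200 (360 ha) with
  60 depressions and seven years × six scenes — large enough for every
  threat radius to exceed the grid (the 18.5 km roost kernel) while a full
  four-group, four-scenario evaluation completes in seconds.

## Known limitations

* The suitability/sensitivity defaults are a qualitative reconstruction;
  quantitative expert-elicited tables should be supplied via the codebook
  YAML for any real application.
* Aggregation is an unweighted pixel sum of Q over the watershed mask;
  published totals for the real landscape may use a different aggregation
  and are not reproducible here.
* Drainage modernization is modelled as total loss of depressional
  ponding; partial-loss scenarios are out of scope.
* The scene model treats cloud cover as independent blocks and scene dates
  as independent draws; real acquisition geometry is more structured.
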