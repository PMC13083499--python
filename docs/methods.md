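# Methods

## Scope and data model

The package assesses potentially toxic elements (PTEs) in a paired survey:
muscle tissue of farmed fish and the surface water of the ponds they were
raised in, sampled at a set of stations. The canonical container is a
station × element matrix per medium (fish in mg/kg wet weight, water in
µg/L) with optional planar station coordinates. Station identifiers are
opaque strings and every output preserves input order — surveys number
their stations meaningfully and alphabetical sorting would scramble maps
and digests. Units are handled in two dimension classes (mass/mass,
mass/volume) with exact power-of-ten factors; conversions never cross
classes, so a tissue level can never silently be compared to a water
standard.

Below-detection entries (`<LOD` or blank cells) are substituted at read
time under a configurable policy — `lod_half` (the common censored-data
convention, LOD/2), `zero`, or `drop` (NaN, handled downstream by pairwise
deletion) — and flagged in a censoring mask so reports can distinguish
measured zeros from substituted ones.

## Dietary risk chain

For each station and element:

* **BCF** = C_fish / C_water with the water term converted to mg/L, giving
  L/kg. Undefined (an error, not 0) when the water term is non-positive;
  a zero tissue level is a legitimate BCF of 0.
* **EDI** = C·IR/BW by default. IR = 0.055 kg/day and BW = 70 kg — a
  standard adult fish-consumption scenario. The chronic form
  C·IR·EF·ED/(BW·AT) activates only when all three extra terms are given;
  with EF·ED = AT/365·365 it reduces to the simple form, which the tests
  verify. The two-parameter default was chosen because published surveys
  frequently leave EF/ED/AT implicit; the parameters are data (scenario
  config), not code.
* **THQ** = EDI/RfD, **HI** = Σ THQ. HI is constrained to equal the sum of
  its THQ components to 10⁻¹² — a conservation check the report container
  enforces.
* **CR** = EDI·CSF over the tracked carcinogen panel {As, Cr, Ni, Cd, Pb};
  **TCR** = Σ CR. Risk bands use half-open intervals: [0, 10⁻⁶) negligible,
  [10⁻⁶, 10⁻⁴) acceptable, [10⁻⁴, ∞) significant — both boundaries belong
  to the upper band. Elements lacking a slope factor are excluded with an
  explicit warning and listed in the report metadata, never silently
  treated as zero risk.
* **MPI** = exp(mean ln Cᵢ), the geometric mean over the panel. It is
  scale-equivariant and bounded by the min/max concentration. Since the
  geometric mean is undefined at 0, the default policy is strict (error
  naming the element); `drop` removes zeros with a warning.

Toxicological constants ship as an editable CSV of literature-style
defaults (e.g. RfD As 3×10⁻⁴ mg/kg-bw/day, CSF As 1.5 (mg/kg-bw/day)⁻¹,
WHO-style drinking-water standards Sᵢ and HEI-style MACᵢ). They are
deliberately data, not constants in code: any study comparing against its
own regulatory context must swap the CSV, and the per-authority maximum
permissible limit (MPL) columns are exactly such a context.

## Water indices

* **WQI**: sub-index qᵢ = 100·Cᵢ/Sᵢ, weights wᵢ ∝ 1/Sᵢ normalized to sum
  to 1, WQI = Σ wᵢqᵢ. Among the several published WQI variants this is the
  weighted-arithmetic one; the variant name is recorded in the output
  metadata so downstream readers know which convention produced the
  number. Classes: < 50 excellent, 50–100 good, 100–200 poor, 200–300 very
  poor, ≥ 300 unfit.
* **HPI**: Qᵢ = 100·|Cᵢ−Iᵢ|/(Sᵢ−Iᵢ) with ideal values Iᵢ (default 0),
  weights Wᵢ ∝ 1/Sᵢ, HPI = ΣWᵢQᵢ/ΣWᵢ, critical value 100. With Iᵢ = 0 the
  HPI formula reduces to the WQI one — the tests assert this equivalence
  rather than treating it as a coincidence.
* **HEI** = Σ Cᵢ/MACᵢ; < 10 low, 10–20 medium, > 20 high.

All three are monotone non-decreasing in every concentration, and elements
without a defined standard are excluded with a notice rather than
defaulted. Anomalously high single-element water means (mercury in some
surveys) are not special-cased; the standards table governs.

## IDW surfaces

The geochemical maps are built by inverse-distance weighting,
ẑ(q) = Σ dᵢ⁻ᵖ zᵢ / Σ dᵢ⁻ᵖ, default power p = 2 with all stations as
neighbors (the common GIS defaults; both configurable, since survey
reports rarely state them). A query within ε = 10⁻¹² coordinate units of a
station returns that station's value exactly, making the method an exact
interpolator; every estimate is a convex combination of station values and
therefore bounded by their range, and the field converges to
nearest-neighbor as p grows. Distances are planar Euclidean on the given
coordinates — for geographic lon/lat input the surface is method-faithful
but not geodesic, an accepted limitation at the ~100 km extent of a
coastal survey. Rasters are written in the ESRI ASCII dialect
(ncols/nrows/xllcorner/yllcorner/cellsize/NODATA_value) with `repr`-exact
floats so write→read round-trips are bit-identical.

## Source apportionment

Pearson correlations use pairwise deletion and require ≥ 3 complete
observations per pair; a zero-variance element yields an undefined (NaN)
correlation, never 0. The PCA adequacy gate computes

* **KMO** = Σr²ᵢⱼ / (Σr²ᵢⱼ + Σa²ᵢⱼ) over i≠j, with anti-image partial
  correlations aᵢⱼ = −sᵢⱼ/√(sᵢᵢsⱼⱼ) from S = R⁻¹ (an optional 10⁻⁸ ridge
  handles singular R), and
* **Bartlett's sphericity** χ² = −[(n−1) − (2p+5)/6]·ln det R with
  df = p(p−1)/2, n = number of stations;

the gate passes iff KMO > 0.5 and p < 0.001. When R is exactly the
identity KMO is a 0/0 form; it is reported as 0 (no shared variance, fail)
and the decision record documents both numbers either way.

PCA standardizes columns and eigendecomposes the correlation matrix, so
eigenvalues sum to the number of variables and all results are invariant
to per-element affine rescaling (units cannot change conclusions). Kaiser
retention keeps components with eigenvalue > 1. No rotation is applied by
default — rotation changes loadings and per-component variance shares, and
an unrotated solution is the reproducible baseline. The sign of each
component is fixed by making its largest-magnitude loading positive.

Clustering is agglomerative Ward linkage on Euclidean distances of
z-scored data (scipy's implementation), applied two-way: element profiles
across stations, and stations across elements. Merge heights are
non-decreasing by the Ward property; a cut at k yields exactly k groups.

## Synthetic generator

The generator draws multivariate lognormal concentrations: per-element
log-means anchored so the geometric median equals a stated survey mean
(fish Fe 55.2 … Cd 0.02 mg/kg; water Zn 113.7 … Cd 0.05 µg/L; boron, which
appears in the statistical panel without a published mean, carries
documented placeholder anchors of 0.5 mg/kg and 5 µg/L), a default log-sd
of 0.5 (geometric sd ≈ 1.65, typical between-station spread), block
correlations on the log scale (fish As–B–Zn–Se–Al at 0.7; water
Al–Fe–Cu–Pb at 0.7; cross-block 0), and mining-hotspot stations S3–S5 with
×1.5–×2.5 enrichment of As, Zn, Se, Cu, Pb applied post-draw. Lognormality
is an assumption — concentrations are positive and right-skewed, but no
distribution is claimed by survey data themselves.

Fish and water are coupled through a shared latent field: the water log
draws use ρ·u + √(1−ρ²)·v with ρ = 0.5, which leaves each medium's
marginal correlation matrix exact while giving the same element a ρ-scaled
association across media, so BCF behaves plausibly. User-supplied block
structures that are not positive definite are repaired by eigenvalue
clipping at 10⁻⁸ with rescaling to unit diagonal.

What the generator does **not** emulate: spatial autocorrelation (IDW is
validated against analytic fixtures and a brute-force oracle instead),
mechanistic bioaccumulation kinetics, seasonal or depth structure, and
measurement censoring. Tests passing on synthetic data therefore
demonstrate the correctness of the index arithmetic, the statistical
machinery and the pipeline plumbing — not field validity of any specific
survey's numbers.

## Problem sizes and numerical choices

The test suite runs the full pipeline at the survey scale (15 stations ×
14 elements) and uses larger draws only where a statistical property needs
them: n = 500 for recovering a block correlation to ±0.05, n = 2000 for
anchoring geometric means to 5%. IDW grids in tests are ≤ 16 cells per
fixture with a brute-force per-cell oracle at 10⁻¹⁰. Ties in clustering
are resolved by scipy's deterministic ordering; all stochastic tests use
fixed seeds. The whole suite completes in a few seconds.

## Known limitations

* The per-authority MPL table and the toxicological defaults are starting
  points, not regulatory advice; both are data files meant to be edited.
* HPI/WQI element panels follow the standards table: an element without a
  standard simply does not enter the index, which can make indices from
  differently-curated standards tables non-comparable.
* The exposure model is a single deterministic adult scenario; no
  age-stratified or probabilistic (Monte-Carlo) exposure, and no dermal or
  inhalation routes.
* PCA is unrotated; surveys post-processed with varimax in other software
  will show different loadings and component variance shares even on
  identical data.
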