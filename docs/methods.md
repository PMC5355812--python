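# Methods

## Fractionation models

The inversion assumes a steady-state *open* surface pool: silicic acid of
fixed composition δ_src is supplied continuously, a fraction 1 − f is
consumed, and the instantaneous opal product sits at δ_src + ε·f. Both
constants are scalars: δ_src = +1.4‰ and ε = −1.2‰ (±0.1‰) by default, the
values constrained for the Southern Ocean south of the Antarctic
Circumpolar Current. ε is stored *signed*; every formula is written for
negative ε, which keeps the admissible measurement band
[δ_src + ε, δ_src] = [+0.2, +1.4]‰ explicit. Measurements outside the band
raise by default; an opt-in clamp maps them to utilization 0/1 with a
logged warning, since replicate noise (1σ = 0.03‰) can overshoot the band
edges by less than one sigma. The closed-system Rayleigh accumulated
product δ_src − ε·f·ln f/(1−f) is provided for comparison only. Note its
gap to the open model is *not* monotone over the whole range: mass balance
forces the accumulated product back to δ_src at complete consumption, so
the two curves coincide at both ends and diverge most around 60–80 %
utilization.

Uncertainty treats the measurement, ε and δ_src as independent normals —
only marginal uncertainties are available for the region — and propagates
them either to first order (delta method) or by seeded Monte Carlo; the two
agree within ~10 % relative in the regimes that matter here. The dominant
term is σ_δ/|ε|: a 0.03‰ replicate sigma maps to 2.5 points of
utilization.

Limitations: δ_src is a scalar parameter, so spatial fields of seawater
δ³⁰Si(OH)₄ and glacially derived Si inputs are outside the model; if the
source composition drifted through time, the inferred utilization absorbs
that drift.

## Cryophilic mass balance

The bulk opal measurement is treated as a two-end-member mixture of a
cryophilic (sea-ice brine) component, present at relative abundance p, and
the open-water component of interest. The cryophilic end member has never
been measured directly; it is only known to be heavier. The sensitivity
sweep therefore brackets it with a configurable offset grid (0–2‰ above
the measured value by default) rather than fixing a value. At the observed
mean abundance p = 0.006 the worst-case shift over that grid is ≈ 0.012‰,
inside the 0.03‰ analytical sigma — the "negligible impact" claim is
checked as an inequality, not assumed. The packaged taxonomy maps the six
named cryophilic taxa, the two sea-ice-associated *Fragilariopsis* species
and the dominant *Hyalochaete Chaetoceros* bloom taxon; a user CSV can
override any assignment.

## Constrained zonation and the broken stick

Zones must be stratigraphically contiguous, so agglomeration only ever
merges adjacent blocks, choosing at each step the merge with the smallest
increase in pooled within-block sum of squares. The increase is computed
with the exact Ward identity ΔSS = n_A·n_B/(n_A+n_B)·(m_A − m_B)², making
the dendrogram O(n²); the test suite verifies every merge against a
brute-force recomputation of pooled SS on raw blocks. Values are
square-root transformed before distances by default (`none` available);
the transform is applied to the utilization fractions, the single variable
being zoned. Ties between equal-increase merges go to the
stratigraphically oldest pair, for determinism.

Significance: the expected variance share of the k-th of n randomly broken
segments is Pr(k) = (1/n)·Σ_{i=k..n} 1/i. The split taking the partition
from k−1 to k zones is accepted while its observed share of the total
dispersion exceeds the expectation for the smallest piece of a k-piece
stick, Pr(k | n=k) = 1/k² (0.25 for the first split, 1/9 for the second,
…); testing proceeds in dendrogram order and stops at the first failure.
This sequential form was chosen over a fixed-n comparison because it is
the reading consistent with treating "n zones" as the current candidate
count, and it calibrates well: on white noise (n = 50) a single zone is
returned in ~98 % of replicates, while a two-regime series with a
14-point utilization contrast is split exactly once essentially always.
The reported broken-stick table uses a fixed table size (default 10) with
the k = 1 row holding the residual within-zone share, so both the observed
and expected columns sum to one.

Zone summaries report both median and mean with type-7 (linearly
interpolated) quartiles, since published central values are not always
explicit about which statistic they are. The between-zone comparison is a
two-sided Mann–Whitney rank-sum test — chosen to match median/IQR
reporting; the exact null is enumerated when both zones have ≤ 10 samples
and no cross-group ties, otherwise the tie-corrected normal approximation
is used.

## Alignment

The isotope ages are the master grid; covariates keep their native
sampling and are linearly interpolated, never extrapolated. The age gap of
a target is its distance to the *nearest original observation* of the
covariate (simplest reading, monotone in the tolerance); a bracket-based
alternative is selectable. The tolerance is quoted in years and converted
once to kyr (50 yr = 0.05 kyr) to avoid unit bugs. By default a row is
dropped when *any* non-exempt covariate over-gaps (joint rule; a cell-wise
mode is available), and every drop is logged with the triggering gap.
Coarse series — the clay/silt westerly-wind proxy here — can be declared
exempt: they are interpolated across larger gaps but flagged in the
output, and toggling them changes only their own column, never row
membership.

## Ordination

Screening follows the standard convention: detrended correspondence
analysis first, and if the axis-1 gradient length is below 1.5 SD the
response is treated as linear and PCA is used. Axis 1 of DCA equals axis 1
of plain correspondence analysis — detrending-by-segments only reshapes
higher axes — so the screen computes the CA axis (SVD of the standardized
contingency residuals, with optional down-weighting of rare columns) and
rescales it to SD units by dividing by the square root of the mean
within-sample variance of column scores. This is the linearized form of
Hill's rescaling; the full segment-wise nonlinear stretch changes lengths
by far less than the decision margin in the regimes screened here
(environment-style matrices score ≈ 0.03–0.1 SD, simulated unimodal
coenoclines ≫ 2 SD). Columns containing negative values are shifted up by
their minimum (logged); already-positive columns keep their baselines,
because removing a large positive baseline (e.g. an irradiance of
~1365 W m⁻²) would manufacture compositional turnover the data do not
have. Screening is run per zone/subzone matrix, not globally.

PCA standardizes every variable (unit variance, ddof = 1) and
eigen-decomposes the correlation matrix, so the eigenvalues of k variables
sum to k; each axis is flipped so its largest-magnitude loading is
positive, which fixes signs across platforms. No multiple-testing
correction is applied anywhere; raw p-values are reported and documented
as such.

## Synthetic records

The generator emulates the structure the pipeline assumes, not ocean
physics:

* **Ages** — a jittered regular grid (±40 % of the step) over
  0.2–12.6 kyr BP, 80 samples: irregular but gap-free sampling.
* **Utilization** — regime means 0.342 (younger than 5.45 kyr) and 0.483
  (older), the two-regime geometry of the motivating record, with AR(1)
  deviations (φ = 0.3, stationary SD 0.04) that restart at the boundary.
  The SD is set so the regime contrast is ≈ 3× the total per-sample noise
  after measurement error — a clearly-separated two-level record.
  Published within-zone interquartile ranges are wider than this because
  real records carry century-scale trends and excursions inside each
  regime; the generator deliberately omits that structure, so passing
  recovery tests demonstrate change-point and level recovery under the
  stated noise model, not under every real-data pathology. Latent values
  are clipped to (0.01, 0.99), logged when it happens.
* **Isotopes** — forward open-system model plus N(0, 0.03‰) measurement
  noise; the noise-free values always lie inside the admissible band.
* **Covariates** — generated conditionally on the *latent* utilization
  (so configured correlations are structural, not attenuated): per regime,
  value = ρ·z(u) + √(1−ρ²)·ε on the covariate's own jittered grid. The
  preset ships a sea-ice taxon series (ρ = 0.7 in the older regime), a
  glacial-discharge δ¹⁸O series, a solar-irradiance series that
  anticorrelates with utilization only in the older regime (ρ = −0.8),
  and a coarse, gap-exempt clay/silt series. Covariate grids are finer
  than the isotope grid (20–80 yr vs ~157 yr), as their real counterparts
  are, which yields a handful (~2–10) of 50-year-rule exclusions per
  record.
* **Assemblage** — per-sample relative abundances with the bloom taxon
  near 60 %, sea-ice-associated taxa near 13 %, and a cryophilic fraction
  drawn around 0.6 % and capped at 2 %.
* **Seeding** — each stream derives its generator from
  `default_rng([seed, crc32(stream_name)])`, so adding a covariate never
  perturbs existing streams and records are bit-reproducible.

## Problem sizes used in validation

The shipped checks run the full chain on 80-sample records; recovery rates
use 100 seeded replicates, null-calibration checks 200–500 replicates, and
the clustering oracle compares full dendrograms on 200 random series of
n ≤ 8 where exhaustive recomputation is cheap. The round-trip identity is
checked on 10⁶ random points at 1e−12.

## Manual recipe: utilization vs solar forcing regression

The published early-Holocene regression of utilization on total solar
irradiance (adjusted R² = 0.91, P < 0.01, n = 5) needs two third-party
inputs that are not redistributable here: the record's supplementary
δ³⁰Si/utilization table and the combined TSI reconstruction. To reproduce
it:

1. Save the supplementary table as `isotopes.csv` with columns
   `depth_mcd, age_kyr, d30si_permil, sigma_permil`, and the TSI record as
   `tsi.csv` with columns `age_kyr, value`.
2. `silutil convert --input isotopes.csv --output util.csv`
3. `silutil zones --input util.csv --output zones.json` — identify the
   older significant zone and its early subzone (8.9–5.6 kyr).
4. `silutil align --isotopes util.csv --covariate tsi=tsi.csv --output aligned.csv`
   (the 50-year rule applies; expect a handful of exclusions).
5. Average the aligned rows of the subzone into the five multi-centennial
   bins used for the published comparison, then:

   ```python
   from silutil import regress_adjusted_r2
   res = regress_adjusted_r2(tsi_binned, utilization_binned)
   print(res.adjusted_r2, res.p_value, res.n)
   ```

The regression helper itself is unit-tested (exact-line, orthogonal-
residual and zero-variance cases); only the external inputs keep this
recipe manual.

## Known limitations

* δ_src is constant in time; no glacial end-member mixing.
* CONISS here is univariate (the utilization series); multivariate
  assemblage zonation is out of scope.
* DCA rescaling is linearized (see above); gradient lengths near the 1.5
  threshold should be interpreted cautiously.
* The generator's regime structure is piecewise-constant; it does not
  emulate within-regime trends, outliers, or age-model uncertainty.
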