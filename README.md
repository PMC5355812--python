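# silutil

Photic-zone silicic-acid utilization from diatom silicon isotopes, with the
downstream stratigraphic statistics used to interpret coastal Antarctic
records: constrained zonation, broken-stick significance, proxy alignment
and ordination.

## Who this is for

Palaeoceanographers working with δ³⁰Si_diatom records (‰ vs NBS28) who want
a tested, scriptable version of the standard inference chain:

1. **Fractionation inversion.** During biomineralization diatoms prefer
   light ²⁸Si with enrichment factor ε (≈ −1.2‰ in the Southern Ocean, and
   insensitive to temperature and growth conditions). In an *open* system
   with continuous resupply of silicic acid of composition δ³⁰Si(OH)₄ = δ_src,
   the opal composition is linear in the unconsumed fraction *f*:

   δ³⁰Si_diatom = δ_src + ε·f,  utilization = 1 − f = 1 − (δ³⁰Si_diatom − δ_src)/ε

   The closed-system (Rayleigh) accumulated product
   δ = δ_src − ε·f·ln f/(1−f) is included as the rejected baseline.
   First-order and Monte-Carlo error propagation cover replicate noise and
   the ε uncertainty.
2. **Cryophilic mass balance.** Sea-ice brine-channel diatoms are
   isotopically heavy; the two-end-member inversion
   δ_open = (δ_meas − p·δ_cryo)/(1−p) and a (p, offset) grid sweep bound
   their worst-case effect on the record.
3. **Zonation.** Constrained incremental sum-of-squares agglomeration
   (CONISS) on the square-root-transformed utilization series, with zone
   significance from a broken-stick null, Pr(k) = (1/n)·Σᵢ₌ₖⁿ 1/i, plus
   per-zone medians/quartiles and a Mann–Whitney between-zone test.
4. **Alignment.** Covariates (sea-ice taxon %, δ¹⁸O_diatom, westerly-wind
   clay/silt, solar irradiance) linearly interpolated onto the isotope
   ages; targets farther than 50 years from the nearest covariate
   observation are excluded, never extrapolated.
5. **Ordination.** Detrended-correspondence-analysis gradient-length screen
   (< 1.5 SD ⇒ linear response), then PCA on standardized variables.

A seeded synthetic-record generator reproduces the statistical structure of
a two-regime Holocene record (irregular ages, AR(1) within-regime noise,
0.03‰ measurement reproducibility, regime-correlated covariates) so the
whole chain can be exercised and validated without any external data.

## Worked example

```python
import silutil as s

record = s.generate_record(s.holocene_preset(seed=1))   # synthetic record
report = s.run_all(s.RunConfig(seed=1, output_dir="out"),
                   isotopes=record.isotopes, covariates=record.covariates)

z = report["zonation"]
print(z["n_significant"], z["boundary_ages_kyr"])
for zone in z["zones"]:
    print(zone["zone"], round(zone["median"], 1), zone["n"])
```

prints

```
2 [5.471296988008634]
Zone 1 33.9 34
Zone 2 47.9 46
```

i.e. the zonation recovers exactly two significant zones with the boundary
at 5.47 kyr BP — inside the generator's true regime change at 5.45 kyr —
and per-zone median utilizations of 33.9 % (late Holocene) and 47.9 %
(early/mid Holocene), within 0.5 points of the configured regime means of
34.2 % and 48.3 %. The report also carries the between-zone rank-sum
p-value (≪ 0.001), the long-term δ³⁰Si trend test, the age-gap exclusion
log and the per-zone DCA gradient lengths (≈ 0.03–0.05 SD here, far below
the 1.5 SD linearity threshold) with PCA eigenvalues.

The same chain is available from the shell:

```sh
silutil simulate --seed 1 --outdir sim
silutil convert --input sim/isotopes.csv --output util.csv --clamp
silutil zones --input util.csv --output zones.json
silutil run-all --seed 1 --outdir out
```

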