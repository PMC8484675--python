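# qmiseq

Quantitative eDNA metabarcoding analysis with spike-in internal-standard
calibration, built around a reef-transect survey design that combines
filtered-seawater eDNA samples with echo-sounder backscatter and a set-net
catch record.

Ordinary metabarcoding read counts are not comparable across libraries:
amplification efficiency and library purification vary sample by sample.
The quantitative MiSeq approach (qMiSeq) fixes this by spiking every
library with a ladder of synthetic standard DNAs at known concentrations
(here 100, 50, 25, 12.5 and 2.5 copies/µl). Because standard reads are
proportional to standard copies *within* a library, a per-sample regression
through the origin,

    reads = slope × copies,    slopê = Σxy / Σx²,

yields that library's reads-per-copy slope, and any fish OTU's reads
convert to a concentration: copies/µl = reads / slopê, then
copies/ml water = copies/µl × elution volume (µl) / filtered volume (ml).
Goodness of fit is the uncentered R² = 1 − RSS/Σy², the appropriate
convention for zero-intercept regression.

On top of that core, the package implements the rest of the survey
analysis:

- **`qmiseq.filtering`** — post-assignment screens (non-fish, identity
  < 98.5 %, alignment ≤ 150 bp), taxonomy collapsing with a regional
  checklist (congeneric hits → "Genus spp.", rescued to species rank when
  the genus has one local member), the per-sample 0.05 % noise filter, and
  contaminant removal.
- **`qmiseq.catch`** — detection-rate accounting against a set-net catch
  record, excluding above-species-rank records and marker-indistinguishable
  pairs, with an optional biomass floor.
- **`qmiseq.acoustics`** — echogram processing: bottom dead-zone and
  instrument masks, a −70 dB noise threshold (sub-threshold cells count as
  linear zero), and 10-minute means of *linear* S_V per station.
- **`qmiseq.models`** — Poisson / gamma GLMs (log link) and a gamma hurdle
  model, station likelihood-ratio tests, Tukey-type single-step max-|z|
  contrasts, and BIC selection over the hierarchical candidate set in
  log(distance + 0.1) or log10(S_V) and depth layer.
- **`qmiseq.community`** — Bray–Curtis dissimilarity on copy numbers, 2-D
  non-metric MDS with Kruskal stress-1, and seeded free-permutation
  PERMANOVA.
- **`qmiseq.synthio`** — a synthetic survey generator (8 stations × 2
  depth layers × 2 replicates + 1 field blank = 33 libraries) whose forward
  model matches the assumptions above, so the whole pipeline can be
  exercised and validated without field data.

## Worked example

The `analysis/` scripts run the whole pipeline on the synthetic survey
(seed 42) and write tables under `results/`:

```sh
python analysis/01_simulate_survey.py      # survey bundle → results/bundle/
python analysis/02_calibrate_quantify.py   # calibration + copy numbers
python analysis/03_filter_otus.py          # OTU screens + audit trail
python analysis/04_compare_catch.py        # detection rates
python analysis/05_acoustics.py            # station echo summaries
python analysis/06_spatial_models.py       # LRT, contrasts, BIC models
python analysis/07_community.py            # NMDS + PERMANOVA
```

Printed output (seed 42):

```
calibrated 33 libraries (R² median 1.000, range 1.000–1.000)
mean total fish eDNA: 58.9 copies/ml water (max 171.8 at AR1_bottom_r1)
field-blank contamination: 0.00% of mean positive copies
published accounting (≥0 kg): 21/36 = 58.3%
published accounting (≥10 kg): 17/22 = 77.3%
distance model: best terms ('cov', 'depth'), BIC 236.3, pseudo-R² 0.90
NMDS stress = 0.142 (50 starts, seed 42)
PERMANOVA ARs_vs_surrounding: F = 3.568, p = 0.007
PERMANOVA middle_vs_bottom: F = 14.558, p = 0.001
```

Reading this: every library's standard ladder fit almost perfectly (R² ≈ 1
under Poisson read noise), total eDNA averages ~59 copies/ml and peaks at
the reef's bottom layer, the detection-rate arithmetic reproduces the
published 58.3 % / 77.3 % accounting, BIC picks distance + depth for total
eDNA, and community structure separates both reef vs surrounding stations
and depth layers.

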