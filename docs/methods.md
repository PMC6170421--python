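# Methods

## Quantification model

Within one sequencing replicate, clonal (micelle) amplification makes read
counts proportional to input template molecules: each template is
amplified in its own compartment, so there is no PCR competition and no
amplification-efficiency bias term in the model. With a known quantity of
internal-calibrator (IC) DNA spiked into the reaction, the absolute
abundance of OTU *o* is

    copies_o = reads_o / reads_IC · IC_copies · volume_scale

in 16S gene copies/100 µL. Consequences the pipeline relies on:

* **Linearity** — scaling `IC_copies` by *c* scales every estimate and the
  LOD by *c*.
* **Read-depth invariance** — multiplying all counts in a replicate by a
  constant leaves estimates unchanged; depth only moves the detection
  limit.
* **LOD** — the copies-equivalent of one read,
  `IC_copies · volume_scale / reads_IC`, the smallest observable signal in
  that replicate. A replicate whose calibrator received zero reads is
  invalid: quantification is undefined there and is never imputed. A
  sample needs ≥ 2 valid replicates to be quantifiable.

`volume_scale` (default 1) maps per-reaction copies to copies per 100 µL
of source water. The field protocol filters 1 L and elutes into an
unspecified volume, so this mapping is the configuration's responsibility;
with the default, per-reaction copies are reported directly. IC copies are
16S gene copies, not genome equivalents — operon multiplicity is the
config provider's problem.

## Decontamination

Negative extraction controls (one blank per monthly extraction batch,
processed in triplicate) are calibrated onto the same copies scale and
averaged into a per-OTU contamination load `c_o`; the load is subtracted
from every sample replicate and clipped at zero. Subtraction operates on
copies, not raw reads, because copies are the only scale on which sample
and NEC are commensurable.

Plain subtract-and-clip cannot drive contamination-only OTUs to exactly
zero: the residual of two noisy counts is positive about half the time.
The pipeline therefore clears an OTU in a replicate unless its raw copies
exceed

    c_o + z · sqrt(c_o · (LOD_rep + LOD_NEC / n_NEC))

the Poisson counting noise of the contamination estimate (variance of a
copy estimate ≈ copies × copies-per-read), with `z = nec_margin_z`
(default 3; 0 disables the margin and leaves the bare clip). The margin
only affects OTUs with nonzero NEC signal; genuine water OTUs without
contamination are untouched. The price is that a real OTU sitting at or
below the contamination level is also cleared — the unavoidable cost of
background subtraction.

Replicate consensus: an OTU must be nonzero (post-subtraction) in
≥ `consensus_min_replicates` (default 2) replicates, else it is zeroed;
surviving values are averaged (median optional — with three replicates the
two differ little and the mean preserves totals). The profile LOD is the
worst replicate LOD. The 2-of-3 rule is an assumption, not a
reconstruction of the original laboratory's exact triplicate rule, and is
configurable off.

## Dynamics

* **Location medians** of copies per OTU over the campaign months; missing
  samples are excluded, never imputed.
* **Dominance**: median relative abundance strictly > 5 % at a location.
* **Consecutive-location fold changes** on medians:
  `(down + f)/(up + f)` with a shared pseudo-floor `f` = half the smallest
  positive LOD in the dataset, so zero medians cannot produce infinite
  ratios and log2 ratios stay antisymmetric under pair reversal. A change
  is significant only strictly beyond 2-fold in either direction; how the
  original analysis handled zeros is unstated, so the floor is configurable.
* **Trends**: per-OTU Spearman R_s of copies against location order,
  pooled across months (n = 30 at the default design) for power; a
  per-month mode is available. Mid-ranks handle ties; p-values are exact
  (full n! permutation enumeration) for n ≤ 9 and use the t-approximation
  with n − 2 df otherwise, two-sided. A zero-variance series has an
  undefined correlation and is reported as NaN, never as 0.
* **Anomaly screen**: for each month and consecutive location pair, the
  fraction of detected OTUs with a per-month fold ≥ 2. "Detected" means
  nonzero at the downstream location that month — an OTU that increased
  ≥ 2-fold is by definition present downstream, and this reference set
  keeps the fraction comparable to the injected boost fraction. A (month,
  pair) is flagged when the fraction reaches 30 % *and* the pair's
  cross-month median fold is below 1, i.e. a mass increase across a step
  that normally shows a decrease. The direction-reversal condition is this
  package's formalisation of the observed warm-month event; without it,
  the ordinary regrowth step (B→C) would trigger in every month.

Thresholds (5 %, 2-fold, 30 %) are strict inequalities where the boundary
semantics were unstated.

## Concordance

Methods measuring total biomass in different units are compared with the
≥1-oriented per-sample fold `max(a,b)/min(a,b)` (mean ± SD, SD assumed as
the dispersion measure; the fraction of samples where one method reads
higher is reported separately) and with per-month Spearman correlations
across the locations (months with < 3 paired locations are skipped).
Culture/ATP series (`hpc`, `batp`) are ingested but get no concordance
statistic — they are known to miss these dynamics.

## Synthetic campaigns

`simulate_truth` draws expected copies per (OTU, location, month):

* **Community**: 143 water OTUs. Three front-dominants hold ~23/9/7 % of
  location A (the observed head-of-system pattern), three back-dominants
  ~4.5/3.2/2.2 %; the rare flora follow a fixed lognormal rank-abundance
  curve (σ = 6.0 quantiles, per-OTU jitter, random identity assignment,
  shares capped at 1.8 % so no undeclared OTU can reach dominance
  anywhere). The quantile construction keeps per-campaign detectable
  richness stable — repeated campaigns of one system share an abundance
  curve — and centres observed richness near the study scale of ~69
  OTUs/sample (median).
* **Spatial structure**: kill-off A→B divides each OTU by
  `killoff_factor^(u·w)` (u ~ U(0.75, 1.25) per OTU; back-dominants
  partially resist with a 0.7 exponent factor); regrowth B→C multiplies
  back-dominants by `regrowth_factor^(u·w)` and 70 % of the rare flora by
  half that exponent; front-dominants never recover. Beyond C the system
  is stable — all folds well within [½, 2] — with a gentle monotone drift
  for the dominants (±0.1/0.08 exponents per step) so their along-system
  trend is rankable, exactly as the monitored system showed continued
  fading/gaining of the dominant taxa. Defaults `killoff_factor = 8`,
  `regrowth_factor = 6` reproduce the observed ~4-fold total-biomass drop
  A→B and recovery by C.
* **Season**: water temperature is a cosine over calendar months peaking
  in campaign month 3 (September), shared across locations and used as
  metadata; `seasonal_amplitude` (default 0.3) scales total biomass up in
  warm months and weakens the spatial fold exponents in cold months
  (weight w). Setting kill/regrowth factors to 1 and amplitude to 0 yields
  exactly flat profiles — the degenerate case used in tests.
* **Anomaly** (default month 3, location B): round(0.30 × 143) = 43
  randomly chosen OTUs are raised at B to `g` times their location-A level,
  g ~ U(5, 20); the first back-dominant OTU instead surges by
  `anomaly_spike_fold` (default 138). Boosted OTUs do not die off
  downstream that month (C–F take the max of their normal value and the
  boosted B value), reproducing the flat-biomass-but-reshuffled-community
  signature. Non-boosted OTUs keep B/A < 1, so the ≥2-fold count is exact
  in truth.
* **Contamination**: 5 reagent OTUs (`CONT_*`) at exactly 200 copies/100 µL
  in every extract, samples and NECs alike — the assumption implicit in
  NEC subtraction — and absent from the water.
* **Reads**: per replicate one multinomial draw of `read_depth` reads over
  {water copies + contamination} ∪ {IC_copies}; NEC reactions contain only
  contamination + calibrator. No sequence-level error model, chimeras or
  taxonomy: read processing is upstream of this pipeline's scope.
* **Companion series**: FCM = true totals × 4.9, qPCR = × 1.3 (the
  systematic offsets reported for the field system), each with mean-one
  multiplicative lognormal noise (cv 0.25, echoing the reported fold SDs).

The study did not state replicate read depths or the IC copy number;
`read_depth = 15 000` and `IC_copies = 10 000` are assumptions chosen so
the calibrator draws a meaningful but not dominant read share and the
detection limit lands where roughly half the simulated community is
observable per sample, matching the study's richness scale. All
randomness flows from a single seed through fixed named streams, so equal
config + seed gives byte-identical outputs.

**What passing tests show — and don't.** The generator realises exactly
the structures the analyses look for (multinomial counting noise, shared
contamination, engineered dominance/kill-off/regrowth/anomaly). Passing
tests therefore demonstrate the pipeline's correctness and statistical
power *under the stated generative model*; they cannot certify behaviour
under real-data pathologies that are deliberately out of scope —
amplification bias, chimeras, OTU-clustering artefacts, taxon-specific
extraction efficiency, or contamination that differs between sample and
blank extracts.

## Numerical and design choices

* Fold pseudo-floor = min positive LOD / 2; thresholds strict at their
  boundaries; relative abundances of an all-zero location are 0, not NaN.
* Spearman exact-p enumeration caps at n = 9 (9! = 362 880 orderings,
  vectorised); above that the t-approximation is standard practice and
  matches reference implementations to ~1e-9.
* One NEC set per month (batch = month); samples in a month without a NEC
  are an error, not silently unsubtracted.
* Problem sizes in the test suite: recovery checks use 100–200 simulated
  campaigns at the default design (30 samples × 3 replicates), with
  depth 10⁵ for calibration-accuracy checks and single-month campaigns
  where the spatial dimension is irrelevant.
* Output tables are TSV with `#` header comments carrying the tool version
  and a SHA-256 config fingerprint; nested results are JSON; the run log
  contains no timestamps so repeated runs are byte-identical.

## Known limitations

* Whether "copies/100 µL" refers to source water or DNA extract cannot be
  resolved without the elution/template volumes; `volume_scale` carries
  that mapping and defaults to reporting per-reaction copies.
* The NEC clearance margin assumes Poisson counting noise; pipetting or
  batch variation between blank and sample extracts would need a larger
  `nec_margin_z`.
* The anomaly screen is tuned to direction-reversal events at one location
  pair; diffuse community shifts spread across the system would not be
  flagged.
* Fold changes use medians of copies per the analysis design; per-month
  ratios averaged afterwards would weight months differently.
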