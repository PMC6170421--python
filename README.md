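# micquant

Absolute quantification and dynamics analysis of 16S rRNA gene profiles for
drinking-water distribution system (DWDS) monitoring.

## The problem

Drinking-water utilities monitor microbial quality with culture counts
(HPC), ATP assays and flow cytometry, none of which identifies *which*
bacteria change along a distribution network. 16S amplicon sequencing does,
but ordinary amplicon data are compositional — read counts only give
relative abundances — and are blurred by reagent DNA contamination, which
dominates in ultra-low-biomass samples like treated water.

`micquant` implements the quantitative monitoring analysis that fixes both
problems at once:

1. **Internal-calibrator (IC) quantification.** A known quantity of foreign
   genomic DNA (e.g. *C. jejuni*) is spiked into every reaction before
   clonal (micelle) amplification. Reads are then proportional to input
   template molecules, so for each OTU *o* in a replicate

   ```
   copies_o = (reads_o / reads_IC) × IC_copies × volume_scale      [copies/100 µL]
   ```

   and the copies-equivalent of a single read,
   `LOD = IC_copies × volume_scale / reads_IC`, is that replicate's
   detection limit.

2. **Negative-extraction-control (NEC) decontamination.** A blank extract
   is processed in triplicate alongside each monthly batch. Its calibrated
   per-OTU copy load is subtracted from every sample replicate (clipped at
   zero, with a Poisson-scaled clearance margin so contamination-only OTUs
   land at exactly zero), and a ≥2-of-3 replicate consensus removes
   irreproducible detections before replicates are averaged.

3. **Dynamics analyses** on the resulting absolute profiles: per-location
   medians over the campaign months, the >5 % median-relative-abundance
   dominance rule, consecutive-location fold changes with a 2-fold
   significance rule (ratios within [½, 2] are attributed to technical
   variation), per-OTU Spearman trends R_s along the system (exact
   permutation p-values for n ≤ 9, t-approximation above), and screening
   for anomalous months in which a large fraction of OTUs reverses a
   location pair's usual fold direction.

4. **Cross-method concordance**: per-sample fold differences
   (max(a,b)/min(a,b), mean ± SD plus direction) and per-month Spearman
   trend agreement between the pipeline's total 16S copies and companion
   flow-cytometry / qPCR biomass series.

Because the original field campaign's raw data are not required here, the
package ships a first-class synthetic-data module
(`micquant.simulate`) that generates campaigns with known ground truth —
a six-location, five-month, triplicate design with disinfection kill-off
between locations A and B, regrowth B→C, stability C→F, six engineered
dominant OTUs whose dominance shifts along the system, seasonal
temperature modulation, one anomalous warm month, reagent contamination,
and multinomial read sampling that includes the spiked calibrator — so
every downstream stage is testable against truth.

## Worked example

The `analysis/` scripts run the whole study on one simulated campaign
(seed 1), writing all tables under `results/`:

```
python analysis/01_simulate.py
python analysis/02_quantify.py
python analysis/03_dynamics.py
python analysis/04_concordance.py
```

which prints, among other things:

```
quantified 30 samples (0 flagged) -> results/profiles
  observed richness: median 68 OTUs/sample (range 51-75) of 143 simulated
  total 16S copies/100 uL, month 1: A=3.72e+04, B=9.77e+03, C=1.62e+04, ...
dynamics tables -> results/dynamics
  dominant OTUs (>5% median relative abundance somewhere): OTU_001 ... OTU_006
  A->B: 76 OTUs significantly down, 0 significantly up (>2-fold rule)
  B->C: 2 OTUs significantly down, 29 significantly up (>2-fold rule)
  ANOMALY: month 3 A->B: 21/54 detected OTUs >=2-fold up (typical fold 0.22)
concordance vs pipeline 16S totals -> results/concordance
  fcm_intact: 5.1-fold (+/-1.4) difference, higher in 30/30 samples
  qpcr_16s: 1.4-fold (+/-0.4) difference, higher in 26/30 samples
```

Reading: the disinfection step between A and B knocks most OTUs down
(total copies drop ~4-fold), regrowth restores biomass by C, exactly the
six engineered OTUs are classified dominant, the injected month-3 surge at
location B is flagged as an anomaly, and the companion flow-cytometry
series sits a systematic ~5-fold above the sequencing-derived copy numbers
while agreeing on the spatial trends — the qPCR series agrees to ~1.4-fold.

The same stages are available as a CLI (`micquant simulate | quantify |
dynamics | concordance | run`, each with `--help`).

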