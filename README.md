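# chronofly

Analysis toolkit for fly chronobiology experiments: beam-break locomotor
activity, circadian qPCR time courses, splice-isoform quantification, and
promoter cis-motif enrichment.  It targets the standard experimental design
used to characterize the circadian clock of dipterans such as the housefly
*Musca domestica* — individual flies in TriKinetics-style infrared monitors
under light:dark (LD) and constant-dark (DD) regimes at several constant
temperatures, head-RNA qPCR sampled every 2 h against a flat reference gene,
and species comparisons of clock-gene promoters.

Every analysis stage has a matching synthetic-data generator with the same
statistical structure (Poisson beam-break counts, cosine transcript
oscillations, log-normal isoform noise, i.i.d. promoter background with
planted motifs), so the whole pipeline runs and is tested without any
external downloads.

## What it computes

**Locomotor activity** (`chronofly.locomotor`). Monitor files are parsed
into per-fly count matrices on a uniform 5-min grid anchored at lights-on
(Zeitgeber time, ZT 0).  Daily profiles are centered moving averages
(smoothing factor *f* = window of 2*f*+1 bins) folded by day with mean ± SEM;
activity levels are mean beam breaks per 24 h.  Free-running period and
rhythmicity use the Sokolove–Bushell chi-square periodogram: for a candidate
period of P bins the series is folded into P columns with means M_h, and the
statistic N·ΣₕKₕ(M_h − M̄)²/Σᵢ(xᵢ − M̄)² is compared with the χ²(P−1)
quantile, Bonferroni-corrected across the scanned candidates (16–32 h by
default).  The normalized folded-variance ratio Qp (equal to P for a
noiseless P-periodic series) is reported alongside.

**qPCR** (`chronofly.qpcr`). Technical triplicates are averaged (with a
spread-based QC flag), relative expression is the classic ΔCq quantity
E^−(Cq_gene − Cq_ref) with E = 2 by default, and each gene is normalized to
the sample with the highest expression across conditions so temperature
curves share one relative axis.  Peak phase comes from the argmax of the
mean series or a cosinor fit m + a·cos(2π(t − φ)/24); phase shifts are
minimal signed circular differences in (−12, +12] h.  Splicing efficiency
of an isoform pair is spliced/(spliced+unspliced), with Welch tests on the
log isoform ratio for condition contrasts and a one-way F test of timepoint
effect (BH-corrected across genes) for rhythmic expression.

**Motif enrichment** (`chronofly.motifscan`). IUPAC consensus motifs
(E-box CACGTG and variants, D-box TTATGTAA, ...) are counted on both strands
of promoter regions, overlapping matches included, and compared with the
expectation in random DNA: strands · (L − k + 1) · Σ_words Π p(base).  Fold
enrichment is observed/expected; 1 means chance level.  Position maps give
BED-style 0-based half-open intervals for promoter drawings.

## Worked example

```python
import numpy as np
from chronofly import locomotor as loco, motifscan as ms, qpcr, synthetic_data as sd
from chronofly.schedules import LightSchedule

# 16 free-running flies (tau = 23.5 h), a quarter arrhythmic, 10 DD days
dd = LightSchedule(0, 24, regime_label="DD")
cfg = sd.ActivitySimConfig(n_flies=16, n_days=10, schedule=dd, period_tau=23.5,
                           peaks=[sd.ActivityPeak(10.0, 2.0, 10.0)], baseline=2.0,
                           arrhythmic_fraction=0.25, seed=1)
ds = sd.simulate_activity(cfg)
calls = [loco.classify_rhythmicity(
             loco.chi_square_periodogram(ds.series(f), (16, 32), 0.05, 5.0),
             ds.fly_ids[f])
         for f in range(ds.n_flies)]
print(loco.free_running_summary(calls, ["DD_25C"] * len(calls)).to_string(index=False))

# circadian qPCR: one cycling gene peaking at ZT 14, realistic noise
cq = sd.simulate_qpcr(sd.QpcrSimConfig(genes=[sd.GeneSpec("per", 1.0, 0.5, 14.0)], seed=2))
series = qpcr.relative_expression(qpcr.collapse_technical(cq, ref_gene="rp49"),
                                  "per", "rp49")
est = qpcr.peak_phase(series, "cosinor")
print(f"per peak phase (cosinor): ZT {est.peak_zt:.2f}")

# promoter worked example: 4 D-box sites in 5 kb vs the random expectation
motif = ms.Motif("D-box", "TTATGTAA")
expected = ms.expected_count(5000, motif)
print(f"fold enrichment: {ms.fold_enrichment(4, expected):.1f}")
```

prints

```
 group  n  percent_rhythmic  mean_period  sd_period
DD_25C 16              75.0         23.5        0.0
per peak phase (cosinor): ZT 13.55
fold enrichment: 26.3
```

The cohort summary recovers the simulated design: 75% rhythmic
(12 rhythmic + 4 shuffled-arrhythmic flies) at exactly the planted 23.5-h
free-running period.  The cosinor acrophase lands within half an hour of the
true ZT 14 peak despite replicate noise.  Four D-box sites in 5 kb are a
26-fold excess over the ~0.15 sites expected in random DNA of that length.

## Command line

```bash
chronofly run --config run.yaml           # simulate -> analyze -> report, with manifest
chronofly simulate activity --seed 1 --out sim/
chronofly activity --monitor sim/monitor.txt --days 1-10 --out results/
chronofly qpcr --cq sim/cq_table.tsv --ref rp49 --out results/
chronofly motifs --fasta promoters.fasta --out results/
```

All outputs are tab-delimited tables plus a `manifest.json` with config
hash, seed and per-file checksums; reruns with the same config and seed
reproduce identical checksums.

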