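# tadpersist

Chromatin domains (TADs) are called from Hi-C contact maps, yet a small
subset of CTCF binding sites resists even deep CTCF depletion — and those
*persistent* sites sit precisely at the domain boundaries that survive
the perturbation.  `tadpersist` is a reusable, fully tested pipeline for
that style of analysis: it calls TADs from binned contact matrices with
the directionality-index HMM, classifies ChIP-seq peaks as persistent /
lost / gained across knockdown replicates, compares boundaries between
conditions (including merged-domain detection), stratifies boundaries by
cell-type conservation, and quantifies where the persistent sites sit
with permutation, positional and gene-set enrichment statistics.  A
planted-truth synthetic-genome generator makes every stage verifiable
end to end without sequencing data.

It is aimed at computational genomicists who want the analysis logic of
a boundary-persistence study as a library (plain BED / chrom.sizes /
sparse-triple text formats) rather than as a collection of one-off
scripts.

## The statistics at the core

For each 40-kb bin, with `A`/`B` the upstream/downstream contact sums in
a 2-Mb window and `E = (A+B)/2`, the directionality index is

    DI = sign(B − A) · ( (A − E)²/E + (B − E)²/E )

Domain starts are strongly downstream-biased (DI ≫ 0), domain ends
upstream-biased (DI ≪ 0).  A 3-state Gaussian HMM (Downstream / None /
Upstream) segments the DI track; a TAD opens at the first bin of a
downstream run and closes at the last bin of the next upstream run, and
boundaries are the ±100-kb regions around TAD termini.  Persistence is a
set-theoretic definition over replicates: present in all replicate sets
(persistent), present in all baseline but no knockdown sets (lost),
knockdown-only (gained).  Enrichment of site classes over boundary sets
is observed/expected against 1000 length-preserving non-overlapping
interval shuffles; housekeeping-gene enrichment near boundary strata is
an exact hypergeometric test with Bonferroni correction.

## Worked example

Run the bundled synthetic study — simulate a 112-Mb genome with planted
domains, a knockdown that dissolves unprotected boundaries, labelled
peaks, an 8-member cell-type panel and flagged genes, then run every
analysis stage against the planted truth:

```python
from tadpersist import StudyConfig, run_study

report = run_study(StudyConfig().with_seed(1), "study_out")
for key in (
    "tads.control.called.count", "tads.control.called.median_bp",
    "recovery.control.recovery_rate",
    "boundaries.called.maintained_fraction",
    "merges.recall", "peaks.label_accuracy",
    "constitutive.persistent.percent", "constitutive.lost.percent",
    "obsexp.persistent.ratio", "obsexp.lost.ratio",
):
    print(key, report[key])
```

prints (seed 1):

```
tads.control.called.count 137
tads.control.called.median_bp 720000
recovery.control.recovery_rate 0.9883720930232558
boundaries.called.maintained_fraction 0.8561151079136691
merges.recall 1.0
peaks.label_accuracy 1.0
constitutive.persistent.percent 98.27586206896551
constitutive.lost.percent 69.38775510204081
obsexp.persistent.ratio 4.4684129429892145
obsexp.lost.ratio 1.0479672468114503
```

Reading: the caller finds 137 domains (median 720 kb, matching the
planted length law) and recovers 98.8% of planted boundaries within one
bin; ~86% of boundaries survive the simulated knockdown and every planted
merge event is detected; peak labels are recovered perfectly; ~98% of
persistent sites are constitutively bound across the panel versus ~69%
of lost sites; and persistent sites are ~4.5-fold enriched over
maintained boundaries while lost sites are at background.  `study_out/`
holds all intermediates (truth tables, called TADs/boundaries, DI
bedGraph, labelled peaks, enrichment tables) plus `report.txt`.

The same stages are scriptable from the shell (`tadpersist run`,
`call-tads`, `classify-peaks`, `compare-boundaries`, `stratify`,
`enrich`, `profile`, `hk-enrich`); see `tadpersist --help`.

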