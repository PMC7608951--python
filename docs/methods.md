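# Methods

## The window model

The pre-MBT cleavage cycles of the syncytial embryo are alternations of S
phase and mitosis with no gap phases, so interphase duration is identified
with S-phase duration. Mitosis aborts all nascent transcripts; after each
mitosis, initiation resumes only after a lag, and a transcript is complete
only once the polymerase has traversed the whole primary transcription
unit (the eclipse time, proportional to TU length). The model's
parameters, all in minutes:

| parameter | default | meaning |
|---|---|---|
| `lag_min` | 4 | post-mitotic delay before initiation resumes |
| `elongation_min_per_kb` | 0.7 | eclipse time per kb of primary TU |
| `mitosis_min` | 5 | mitosis duration (per cycle in the schedule) |
| `terminal_cycle` | 14 | cycle with open-ended interphase (100% efficiency) |

The shipped schedule covers cycles 8–14. Its interphases for cycles 10
and 13 are measured S-phase durations (7 and 15 min); cycle 8 is set to
4.2 min so its transcriptional window is 12 s; cycles 9, 11 and 12 (4.2,
5.5, 9.5, 12.5 min) are a monotone reconstruction, because only the
anchor values are known. The schedule lives in a TSV data file and is the
single point of truth: analyses with better measurements should override
it via `load_schedule`. Efficiency uses `interphase + mitosis` as the
denominator and clamps the productive window at zero before dividing, so
it is always in [0, 100]; the terminal-cycle override to exactly 100% can
be disabled (`terminal_override=False`) for sensitivity analyses. Whether
the 12-s cycle-8 window was originally computed with the full 4-min lag
is not knowable from the anchors alone; the schedule file makes that
assumption explicit and editable.

## The abortion simulator

Initiation is modeled as a homogeneous Poisson process per nucleus over
`(lag, interphase]`; an initiation at time *t* completes iff
`t + eclipse ≤ interphase` (in the terminal cycle, nothing is aborted).
This is the simplest process consistent with a fixed lag followed by
steady initiation; re-initiation limits, polymerase collisions, and
promoter-specific kinetics are deliberately absent. Initiations too late
to finish are drawn and counted as aborted rather than suppressed — the
alternative (no doomed initiations) changes no completed-count statistics,
only the aborted tally. Per-cycle random streams are spawned from
`(root_seed, cycle)` so results are independent of simulation order. The
simulator's expectation equals `rate × nuclei × productive_window`, which
the test suite checks by Monte Carlo (1,000 replicates within 3 SE) on
random schedules.

## Normalization and PCA

Counts are normalized per sample to counts-per-million with the column
total as library size (the matrix is the authority on the library once
alignment is upstream), then `log2(CPM + 1)`. Matrices carry a stage tag
(`counts → log2cpm → row_scaled`) and operations refuse inputs at the
wrong stage, preventing double normalization. Row scaling (for heatmaps)
centers each gene to mean 0, sd 1 (sample sd), mapping constant rows to
zero with a flag. PCA is centered but not variance-scaled, over all genes
(a top-variable-gene subset is a caller choice, not the default), and is
checked against a plain SVD oracle. Outlier embryos are removed only via
an explicit exclusion list — no automatic rule is applied, since any
threshold would be arbitrary.

## Classification rules

*Zygotic identification*: a gene is zygotic when its linear fold change
between condition means (computed from mean Log2 CPM+1 difference)
strictly exceeds 1.5 **and** a Welch unequal-variance t test on replicate
values gives p strictly below 0.05. Welch is the natural two-sample test
at n = 2–3 per condition; no multiple-testing correction is applied
because the rule is a raw per-gene threshold. *Grouping under arrest*
(condition means relative to control C12, margin 0 by default): an
"initial decrease" means being below baseline at both 30 and 50 minutes
of arrest (an "either" switch is provided); group 1 = no initial decrease
and above baseline at 70 minutes; group 2 = initial decrease followed by
re-accumulation (70-minute value above the 30/50 minimum); group 3 = the
rest. The 15-minute point is reported but not used by the rule. The
baseline for "increased upon arrest" is control C12 — the same baseline
as the fold-change profiles — with the comparator configurable.
*Maternal clearance*: previously-reported maternal genes whose control
C14L mean falls below their control C12 mean. *Priming-feature
enrichment*: two-sided Fisher exact test on the 2×2 membership table of
two disjoint gene sets.

## The delay classifier

Haploid embryos slow their cycles one cycle later than diploids, so genes
whose activation tracks cell-cycle slowing show a one-cycle-delayed
profile in haploids. The classifier is a transparent shift-fit: median-
center both profiles, compute the mean-squared error of the haploid
profile against the diploid profile shifted by 0 and by 1 cycle (toward
later cycles, truncated overlap), and call `nc_dependent` /
`time_dependent` for whichever fit is better by more than a 5% relative
margin (`ambiguous` otherwise). Median-centering and the ratio form make
the call invariant to additive offsets and positive rescaling. Only
shifts {0, 1} are considered — the construct of interest is a one-cycle
delay. Genes without diploid activation (amplitude at or below the
caller's noise floor) are not classifiable and are reported separately.

## The synthetic generator

The generator emulates the cycle-12-arrest study design: control embryos
at C12 (mid-interphase, 6.25 min after mitosis 11), C13 (25 min), C14
early (+10 min into C14, 47.5 min) and C14 late (+70 min, 107.5 min),
and arrested embryos at 15/30/50/70 min, three replicates each (24
samples). Control nuclei double each cycle (4× from C12 to C14); arrested
nuclei stay at the C12 count. Expected abundance per gene is a decaying
maternal pool, `M·exp(−k·t)`, plus zygotic accrual: per completed cycle,
`rate × nuclei × productive_window`; within the cycle in progress, only
transcripts that have fully completed by the sampling time; arrested
embryos accrue continuously through their open-ended interphase
(`rate × nuclei × max(0, t − lag − eclipse)`). Maternal decay is
exponential with an onset because observed clearance curves constrain no
particular functional form; production before cycle 12 is neglected (the
windows are tiny and the reference time is mitosis 11). Counts are
gamma-Poisson (negative binomial, dispersion 0.1, i.e. a biological CV of
~32% between replicate embryos) with log-normal library sizes (median
5×10⁵, log-sd 0.15) — the standard minimal overdispersion model for
RNA-seq.

Default catalog (2,000 genes): 28% zygotic-only (planted group 1; a fifth
carry delay classes, split evenly nc-like/time-like), 6% maternal-and-
zygotic (group 2: decay 0.08–0.10/min, initial pool 350–650, rate
1.8–2.6/min/nucleus, short TUs), 41% maternal-only (40% stable
housekeeping at 800–2,500 transcripts, 60% decaying at 0.03–0.07/min — the
clearance cohort, a small fraction planted as group 3), 25% silent. Two
design constraints shaped these ranges, fixed before any recovery was
measured: (1) on noiseless expected profiles every planted gene satisfies
its classification rule with ≥ ~0.5 Log2 units to spare at each compared
pair, so recovery rates measure noise robustness rather than luck; (2)
the stable background carries most of the library mass, keeping
CPM composition shifts between conditions below ~0.2 Log2 units.
Delay-profile tables give per-nucleus productive output per cycle; the
haploid profile of an nc-like gene is the diploid profile shifted one
cycle later, with Gaussian noise at 10% of amplitude on both.

What the generator does **not** emulate: read-level artifacts (mappability,
GC bias, multi-mapping), gene–gene correlation beyond library composition,
spatially patterned expression, zygotic transcript degradation, and
condition-dependent maternal-decay modulation. Passing recovery tests
therefore demonstrates that the classifiers implement their rules
correctly and tolerate replicate-level overdispersion — not that the rules
are optimal for real embryos.

## Problem sizes and numerical choices

The default study is 2,000 genes × 24 samples, which exercises every code
path while keeping the full suite in seconds. Monte-Carlo agreement uses
1,000 replicates per instance (3-SE bands). Ties: fold-change and p-value
thresholds are strict inequalities; zero-variance t tests yield p = 1;
constant rows scale to zero with a flag; all clamping happens before
division. Seeds are combined through `numpy` seed sequences
(`(seed, stream)` pairs), so every sub-stream is reproducible and
order-independent.

## Known limitations

- The reconstructed interphases for cycles 9, 11, 12 are interpolations;
  conclusions sensitive to those cycles should re-run with measured
  schedules.
- The delay classifier is a surrogate for the original microarray
  procedure, which is defined in external work; labels near the ambiguity
  band should not be over-interpreted.
- Absolute transcript-to-count scaling in the generator is arbitrary;
  only relative comparisons (fold changes, labels) are meaningful.
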