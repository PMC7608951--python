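# zgakit

Quantitative tools for studying **zygotic genome activation (ZGA)** under
the rapid cell cycles of the early embryo — built around the idea that
mitosis aborts every nascent transcript, so cell-cycle duration, not the
nucleo-cytoplasmic (N/C) ratio itself, gates when a gene can first produce
complete mRNA.

It is aimed at developmental biologists and computational researchers who
want to (1) model how interphase length limits productive transcription as
a function of gene length, and (2) classify single-embryo RNA-seq data from
control versus cell-cycle-arrested embryos, with a synthetic-data generator
that makes every stage of the pipeline testable without external downloads.

## The model

For cell cycle *c* with interphase *I_c*, mitosis *M*, post-mitotic lag
*L*, and a gene with primary transcription-unit (TU) length *ℓ* kb
elongated at *k* minutes/kb:

```
eclipse time          E(ℓ) = k·ℓ                    (k = 0.7 min/kb)
transcriptional window W_c = max(0, I_c − L)        (L = 4 min)
productive window     P_c(ℓ) = max(0, W_c − E(ℓ))
expression efficiency ε_c(ℓ) = 100·P_c(ℓ)/(I_c + M) (M = 5 min)
```

The terminal cycle (cycle 14) has no subsequent mitosis and runs at 100%.
A Poisson-process simulator of initiation/elongation/abortion reproduces
the closed form in expectation. On top of this sit the RNA-seq procedures:
Log2(CPM+1) normalization, PCA trajectories, zygotic-gene identification
(fold change > 1.5 and Welch p < 0.05), a three-way grouping of the
arrest response (rise / dip-then-rise / no rise), maternal-clearance
selection, Fisher-exact priming-feature enrichment, and a one-cycle-delay
classifier separating "N/C-dependent" from "time-dependent" genes in
paired diploid/haploid profiles.

## Worked example

```python
>>> from zgakit import default_schedule, eclipse_time, efficiency_table
>>> sched = default_schedule()
>>> eclipse_time(1.0, sched)        # minutes to traverse a 1-kb TU
0.7
>>> efficiency_table([0.5, 2.0, 10.0, 40.0], sched).round(1)
cycle          8     9     10    11    12    13     14
tu_length_kb
0.5           0.0  11.0  22.1  35.5  46.6  53.2  100.0
2.0           0.0   1.0  13.3  28.3  40.6  48.0  100.0
10.0          0.0   0.0   0.0   0.0   8.6  20.0  100.0
40.0          0.0   0.0   0.0   0.0   0.0   0.0  100.0
```

Each cell is the time-averaged percent of maximal expression a TU of that
length can reach in that cycle: a 0.5-kb gene is already weakly
expressible in cycle 9, a 10-kb gene first becomes productive in cycle 12,
and a 40-kb gene cannot complete a single transcript before cycle 14 —
longer genes have a later, more abrupt onset.

End-to-end on synthetic data:

```bash
zgakit synth-study --n-genes 2000 --seed 1 --out study/
zgakit classify-zga --matrix study/counts.tsv --meta study/meta.tsv --out zga/
zgakit classify-nc --profiles study/profiles.tsv --out-prefix nc
```

The `classify-zga` summary reports the arrest-response partition (group 1
rising, group 2 dipping then re-accumulating, group 3 never rising), and
`classify-nc` prints the N/C-dependent / time-dependent counts; planted
truth labels in `study/truth.tsv` let you score both (≥ 95% recovery at
the default noise settings).

## Layout

- `src/zgakit/schedule.py` — cycle schedules (shipped default in `data/`)
- `src/zgakit/window_model.py` — closed-form windows and efficiency
- `src/zgakit/abortion.py` — initiation/abortion simulator
- `src/zgakit/expression.py` — counts I/O, Log2(CPM+1), PCA, profiles
- `src/zgakit/pipeline.py` — ZGA classification procedures
- `src/zgakit/nc_time.py` — one-cycle-delay classifier
- `src/zgakit/synth.py` — synthetic study generator with planted truth
- `docs/methods.md` — modeling assumptions, parameter choices, limitations
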