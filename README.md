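# hepatarget

Tools for identifying the direct transcriptional targets of a lineage-driving
transcription factor during the endoderm-to-hepatic transition, following the
evidence funnel used to characterize HNF4A in differentiating hepatic
progenitors.

## The scientific problem

A transcription factor is a *direct* driver of a cell-state transition when the
genes that fail to activate in its absence are also the genes whose promoters it
physically occupies. `hepatarget` operationalizes this as a staged funnel over
candidate genes:

1. **dependency** — expression reduced at least 4-fold (p ≤ 0.05) in the
   factor-depleted condition versus control at the post-transition day;
2. **occupancy** — the gene has an assigned ChIP binding site (each peak is
   assigned to its nearest transcription start site, TSS);
3. **proximity** — the assigned site lies within 1 kb of the TSS
   (promoter-proximal);
4. **liver enrichment** — in a 16-tissue expression panel, liver strictly
   exceeds at least 13 of the 15 other tissues;
5. **induction** — expression rises at least 4-fold between the endoderm day
   (day 5) and the hepatic-progenitor day (day 8) in control cells;
6. **confirmed** — occupancy independently confirmed by ChIP-qPCR, with the
   regulator itself excluded.

Each stage is a subset of the previous one (checked as an invariant). The
packaged 25-gene candidate table reproduces the published funnel: 25
promoter-proximal candidates → 18 liver-enriched → 8 confirmed direct targets
(APOA2, SFRP5, N4BP2L1, SLC35D1, APOB, ANKS4B, PLA2G12B, F7).

Supporting modules cover the surrounding workflow: peak-to-TSS assignment with
signed, strand-aware distances (upstream negative); differential expression and
sample clustering over the differentiation time course, including detection of
the day-7→8 transition; qPCR standard-curve fitting with the 90–110% primer
efficiency rule and percent-input ChIP quantification; and a seeded synthetic
data generator with a truth manifest and an auditor that re-derives every
manifest claim from the written files.

## Worked example

Generate a synthetic bundle, audit it against its own truth manifest, and run
the full pipeline:

```console
$ hepatarget simulate -o demo/bundle --seed 7
bundle written to demo/bundle (12 planted targets)
$ hepatarget audit -o demo/bundle
audit passed
$ cat > demo/run.yaml <<EOF
genes: demo/bundle/genes.gtf
peaks: demo/bundle/peaks.narrowPeak
expression: demo/bundle/expression.tsv
samples: demo/bundle/samples.tsv
panel: demo/bundle/tissue_panel.tsv
confirmation: demo/bundle/confirmation.tsv
dilutions: demo/bundle/qpcr_dilutions.tsv
chip_ct: demo/bundle/chip_ct.tsv
EOF
$ hepatarget run-all --config demo/run.yaml -o demo/out
report written to demo/out/report.json
funnel counts: {'dependency': 49, 'occupancy': 22, 'proximity': 15, 'liver': 12, 'induction': 12, 'confirmed': 12}
```

The 12 confirmed genes in `demo/out/report.json` are exactly the 12 planted
targets, and the report records the detected transition between days 7 and 8.
Re-running `run-all` with the same configuration reproduces `report.json`
byte-for-byte.

The packaged candidate table:

```console
$ hepatarget reproduce-table1
proximity: 25
liver: 18
induction: 13
confirmed: 8
confirmed set: ANKS4B, APOA2, APOB, F7, N4BP2L1, PLA2G12B, SFRP5, SLC35D1
```

(The command exits with status 3 if the recomputed funnel deviates from these
reference counts.)

Other subcommands — `assign`, `diff`, `cluster`, `induced-sets`, `funnel`,
`qpcr-curve`, `chip-quant` — expose the individual pipeline stages; see
`hepatarget --help`.

The same functionality is available as a library:

```python
from hepatarget import (
    assign_peaks, read_annotation, read_peaks,
    diff_expression, run_funnel, reproduce_table1,
)
```

## Documentation

See [`docs/methods.md`](docs/methods.md) for the underlying model, parameter
defaults and rationale, the synthetic generator's scope and limits, and known
limitations.
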