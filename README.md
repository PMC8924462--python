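# crcatlas

Classification and cohort statistics for circulating rare cells (CRCs)
detected by combined immunostaining + FISH image scanning. The package
takes per-cell event tables (staining calls, cell size, chromosome-8 and
optional chromosome-12 FISH spot counts) and provides:

- **Ploidy calling and phenotype gates** (`crcatlas.events`): spot-count →
  ploidy class, small/large size gating against the mean WBC diameter, and
  the CTC (CD45−/CD31−, marker-positive or chromosome-8 aneuploid) and CTEC
  (CD45−/CD31+, aneuploid) predicates.
- **71-leaf subtype atlas** (`crcatlas.atlas`): deterministic enumeration of
  the size × ploidy × (PM, CD31, Vim) marker-combination label set
  (2 sizes × 4 aneuploid ploidy classes × 8 combos, plus 7 size-agnostic
  marker-positive diploid leaves), per-event classification into exactly one
  leaf or an explicit non-leaf category (residual WBC, hematologic CRC,
  diploid-null, QC failure), and cluster/CTM annotation flags.
- **Dual-probe co-detection** (`crcatlas.dualprobe`): chromosome-8 ×
  chromosome-12 ploidy patterns, per-patient aneuploid totals, the
  patient-level single-probe false-negative rate (chr8-diploid /
  chr12-aneuploid carriers), and a paired two-tailed t-test comparing the
  two probes.
- **Cohort statistics** (`crcatlas.cohort`): per-patient aggregation,
  CTC positivity percentages (half-up, 1 decimal), group medians (half-up,
  2 decimals), and a tie-corrected Kruskal–Wallis H test.
- **Synthetic cohorts** (`crcatlas.simulate`, `crcatlas.params`): a seeded
  generator whose per-patient totals follow a hurdle (zero-inflated shifted
  negative-binomial) model fitted so the analytic median matches a
  configured target; the shipped parameter table covers 31 disease groups
  (positivity taken from the bundled reference cohort counts) plus a
  dual-probe `co_detection` group. The classification pipeline provably
  recovers the drawn totals.
- **TSV I/O and CLI** (`crcatlas.io`, `crcatlas.cli`).

## CLI

```sh
crc simulate --group "Infectious diseases" --n 200 --seed 42 -o events.tsv
crc classify events.tsv -o labeled.tsv
crc aggregate events.tsv -o patients.tsv
crc stats patients.tsv -o groups.tsv
crc dualprobe events.tsv -o probe_summary.tsv   # needs a co-detection cohort
crc atlas export -o atlas.tsv                   # the 71-row atlas table
crc run -o outdir --seed 42                     # full pipeline
```

Event tables are tab-separated with a fixed 16-column header
(`patient_id … cep12_spots`); booleans are 0/1, missing optional values are
empty strings, unknown columns pass through unchanged.

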