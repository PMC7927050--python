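# serrata

Familial serrated-polyposis gene-discovery pipeline, rebuilt as a reusable,
tested Python package and exercised end-to-end on synthetic cohorts with
known ground truth.

The pipeline has three analytical arms:

1. **Germline prioritization** — three-round variant selection per family:
   hard filters (population allele frequency strictly < 0.1%, missense or
   truncating impact, ≥ 3 of 6 deleterious predictor verdicts for missense),
   co-segregation (variant shared by every affected sequenced member, with
   dominant/recessive handling and a cross-family consistency exclusion),
   and declarative gene-function curation (cancer / senescence / epigenetics
   prioritized sets, non-cancer-disease exclusion sets).
2. **Two-hit germline–somatic integration** — somatic sample QC by shared
   callable footprint (≥ 70%), second-hit SNV/indel detection in candidate
   genes (depth ≥ 10, AAF ≥ 20%), and loss-of-heterozygosity detection via
   an exact two-sided binomial allelic-imbalance test (alpha 0.01, effect
   floor 0.15) with a direction requirement (variant allele retained) and
   gene-level aggregation over flanking heterozygous support sites.
   Unpaired samples are filtered against a panel of normals instead.
3. **Somatic mutational profiling** — TMB and indel burden with strict
   load classes (hypermutated > 10 mut/Mb, ultra-hypermutated > 100 mut/Mb),
   SBS96 and ID83 context classification against the reference, signature
   refitting by non-negative least squares with backward pruning, aetiology
   flagging (clock-like, MMR-deficiency, artifact), and driver-gene
   reporting (BRAF/KRAS/POLE/POLD1/MMR genes, no AAF cutoff, hotspot
   matching).

Because the analyses are validated on synthetic data, the package ships a
first-class cohort simulator (`serrata.cohort_sim`) that emits a
deterministic reference FASTA, gene map, pedigrees, per-family germline
VCFs with planted causal variants plus calibrated background, and somatic
VCFs drawn from signature mixtures with planted second hits, LOH events and
driver hotspots — all with a machine-readable truth table.

## CLI

```sh
serrata simulate --seed 1 --outdir cohort/          # synthetic cohort + truth
serrata prioritize --vcf-dir cohort/germline --ped cohort/cohort.ped \
    --gene-sets cohort/gene_sets.yaml --outdir prio/
serrata twohit --cohort-dir cohort/ --outdir out/   # paired two-hit analysis
serrata profile --somatic-vcf cohort/somatic/SPS.07.vcf \
    --ref cohort/reference.fa --callable-bed cohort/somatic/SPS.07.bed \
    --out profile.json
serrata run --outdir run/ --seed 1                  # simulate + full pipeline
serrata report --run-dir run/
```

`serrata run` writes `candidates.tsv` (gene-level evidence table with
G / G-S paired-analysis labels), per-round prioritization and attrition
tables, per-sample burden / signature-weight / driver tables, a QC ledger,
a run manifest with the config hash, and a human-readable `report.md`.
Runs are byte-identical given the same config and seed.

## Layout

```
src/serrata/
  types.py                core domain types (variants, genotypes, pedigrees)
  intervals.py            callable-region interval sets (BED dialect)
  formats_io.py           VCF/PED/BED/TSV/YAML readers & writers
  cohort_sim.py           ground-truth synthetic cohort simulator
  germline_prioritizer.py three-round prioritization + co-segregation
  somatic_integration.py  QC, second-hit scan, LOH testing, panel filter
  mutational_profile.py   burden, SBS96/ID83, NNLS refitting, drivers
  pipeline.py             orchestration, summary, report rendering
  cli.py                  click-based CLI (`serrata ...`)
  data/                   bundled synthetic signature catalogs + ID83 bins
scripts/
  acceptance.py           acceptance report (see above)
  make_bundled_catalogs.py  regenerates the frozen data/ TSVs
tests/                    pytest suite incl. tests/test_acceptance.py
```

The bundled signature catalogs are synthetic stand-ins with the real
catalogs' shape and qualitative character; regenerate them with
`python scripts/make_bundled_catalogs.py`.
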