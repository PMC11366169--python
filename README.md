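# imprintscan

Analysis toolkit for methylation at imprinted differentially methylated
regions (DMRs) in tumour cohorts. Imprinted DMRs are methylated on exactly
one parental allele, so array beta-values sit near 0.5 in biparental
tissue; deviations mark gain (GOM) or loss (LOM) of methylation, which may
be true epimutations or mere consequences of allele-specific copy-number
alterations (CNAs). The package covers the whole workflow:

- **registry** — a curated catalog of 49 imprinted DMRs (GRCh37, 1-based
  inclusive intervals, parental methylated allele, overlapping genes) and
  assignment of array probes to regions.
- **classify** — five-state probe calls (GOM if beta > 0.8, LOM if
  beta < 0.2, Intermediate GOM/LOM outside the control mean ± 2 SD band,
  else No change), region calls by a strict >60% probe-majority rule,
  cohort summaries with a strict >30% "most altered" rule, and per-sample
  altered-DMR burdens.
- **cna** — allele-specific segment profiles (nMajor/nMinor), per-region
  copy-state resolution, CNA-predicted methylation (minor methylation value
  nMinor/(nMajor+nMinor), side assigned from whether most observed betas
  are ≤ 0.5), and per-region OLS of observed on predicted methylation with
  adjusted R².
- **stats** — Pearson chi-squared association of region status with
  clinical factors, Benjamini–Hochberg adjustment, pairwise Wilcoxon
  rank-sum comparisons of altered-DMR burden.
- **survival** — Kaplan–Meier / log-rank by status group, Cox
  proportional-hazards contrasts (focal status vs No change, optionally
  adjusted for MYCN amplification, 11q deletion and age group), low-risk
  stratification within MYCN-non-amplified samples, and an exhaustive
  expression-cutoff scan with Bonferroni correction.
- **synthetic** — a fully seeded cohort generator (betas, probe manifest,
  segments, clinical table, survival outcomes, UPD-like references) with
  ground-truth tables, so every stage is testable without external data.

## Command line

```bash
imprintscan simulate --seed 1 --n-tumours 300 --out cohort/
imprintscan classify --betas cohort/betas.tsv --manifest cohort/manifest.tsv \
    --controls cohort/controls.txt --out calls/
imprintscan concordance --betas cohort/betas.tsv --manifest cohort/manifest.tsv \
    --segments cohort/segments.tsv --out cna/
imprintscan associate --region-calls calls/region_calls.tsv \
    --clinical cohort/clinical.tsv --out assoc.tsv
imprintscan survival --region-calls calls/region_calls.tsv \
    --clinical cohort/clinical.tsv --dmr NNAT:TSS-DMR --out surv/
```

All interchange formats are plain TSV: beta matrices (probe_id × samples),
probe manifests (probe_id, chrom, pos), ASCAT-style segments (sample,
chrom, startpos, endpos, nMajor, nMinor) and clinical tables (age_group,
stage, mycn, chr11, os_time_years, os_event).

## Python API sketch

```python
from imprintscan import classify, cna, registry, synthetic

catalog = registry.load_dmr_catalog()                 # packaged 49 regions
bundle = synthetic.generate_cohort(synthetic.demo_config(seed=1))
probe_map, _ = registry.map_probes_to_dmrs(bundle.manifest, catalog)
ctrl = classify.build_control_reference(bundle.betas, bundle.control_ids)
probe_calls = classify.classify_probes(bundle.betas[bundle.tumour_ids], probe_map, ctrl)
region_calls = classify.aggregate_regions(probe_calls)
summary = classify.summarize_cohort(region_calls)

states = cna.resolve_copy_states(bundle.segments, catalog)
preds = cna.predict_cohort(states, bundle.betas[bundle.tumour_ids], probe_map)
table = cna.regression_table(preds)                   # adj R² per region
```
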