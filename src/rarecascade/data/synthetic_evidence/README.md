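# Synthetic evidence tables

Small emulation snapshots of the four gene-evidence sources the cascade
joins against. They exist so the pipeline is runnable and testable with no
external downloads; point `rarecascade.evidence.load_evidence` at full
database exports with the same headers for real analyses.

- `glgc.tsv` — lipid-trait association p-values (GLGC-style). Trait
  p-values for QTRT1, PPARD, CABP1, LDLR and HLA-E are published reference
  values; the remaining rows are synthetic placeholders marking membership.
- `cardiogram.tsv` — CAD-associated gene symbols (CARDIoGRAMplusC4D-style).
- `mgi.tsv` — mouse phenotype categories (MGI-style). Category assignments
  are synthetic: they record plausible membership, not curated annotations.
- `gwas_catalog.tsv` — CAD flags (GWAS-catalog-style).

All files are TSV with a header row; `#` lines are comments; gene symbols
are matched after case-folding.
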