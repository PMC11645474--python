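"""End-to-end cascade orchestration.

Stage order is fixed: simulate (or load) -> variant QC -> qualifying-set
construction -> collapsing burden scan -> p/OR screen -> database-evidence
filter -> any-phenotype significance -> pathway-pattern filters (lipid,
thrombosis, inflammation). Every stage writes its table to the output
directory and contributes a (stage, genes in, genes out) row to the count
ledger, which is monotone non-increasing by construction.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import burden as burden_mod
from . import phenotypes as pheno_mod
from .config import PipelineConfig, dump_config
from .evidence import evidence_filter, load_evidence
from .qc import apply_qc, genotype_frame, read_vcf
from .sets import build_gene_sets, gene_sets_frame
from .simulate import simulate_cohort, write_cohort

logger = logging.getLogger(__name__)

STAGES = (
    "qc",
    "sets",
    "burden",
    "screen",
    "evidence",
    "phenotype_significant",
    "lipid",
    "thrombosis",
    "inflammation",
)


def screened_fraction_pct(n_included: int, n_screened: int) -> float:
    """Percentage of screened patients retained by the inclusion criteria,
    rounded to two decimals (e.g. 92 of 1950 -> 4.72)."""
    if n_screened <= 0 or n_included < 0 or n_included > n_screened:
        raise ValueError("need 0 <= n_included <= n_screened with n_screened > 0")
    return round(100.0 * n_included / n_screened, 2)


@dataclass
class CascadeReport:
    """Stage-by-stage count ledger plus paths of every emitted table."""

    stage_counts: list[tuple[str, int, int]] = field(default_factory=list)
    stage_tables: dict[str, str] = field(default_factory=dict)
    config_echo: str = ""
    seed: int = 0

    def summary_text(self) -> str:
        lines = ["stage\tgenes_in\tgenes_out"]
        for name, n_in, n_out in self.stage_counts:
            lines.append(f"{name}\t{n_in}\t{n_out}")
        lines.append(f"seed\t{self.seed}\t-")
        return "\n".join(lines) + "\n"


def run_pipeline(config: PipelineConfig, out_dir: str) -> CascadeReport:
    """Execute the full cascade on a simulated cohort; deterministic in
    ``config.sim.seed``. All intermediates are written under ``out_dir``."""
    config.validate()
    os.makedirs(out_dir, exist_ok=True)
    report = CascadeReport(config_echo=dump_config(config), seed=config.sim.seed)
    t0 = time.time()

    cohort = simulate_cohort(config.sim)
    paths = write_cohort(cohort, os.path.join(out_dir, "cohort"))
    report.stage_tables.update(paths)
    logger.info("simulated cohort: %d samples, %d variants",
                len(cohort.sample_ids), len(cohort.variant_ids))

    # --- QC on the persisted VCF (stage isolation: re-reads its own input)
    variants, sample_ids = read_vcf(paths["vcf"])
    labels = pd.read_csv(paths["labels"], sep="\t", index_col="sample_id")["status"]
    labels = labels.reindex(sample_ids)
    control_mask = (labels == "control").to_numpy()
    retained, qc_log = apply_qc(variants, config.qc, control_mask)
    qc_path = os.path.join(out_dir, "qc_log.tsv")
    qc_log.to_csv(qc_path, sep="\t", index=False)
    report.stage_tables["qc_log"] = qc_path

    annotations = pd.read_csv(paths["annotations"], sep="\t")
    genes_in = annotations["gene"].nunique()
    retained_ids = {v.variant_id for v in retained}

    # --- qualifying sets
    cells = build_gene_sets(annotations, retained_ids, config.maf_threshold)
    sets_path = os.path.join(out_dir, "gene_sets.tsv")
    gene_sets_frame(cells).to_csv(sets_path, sep="\t", index=False)
    report.stage_tables["gene_sets"] = sets_path
    genes_sets = len({g for g, _ in cells})
    report.stage_counts.append(("qc", genes_in, genes_in))
    report.stage_counts.append(("sets", genes_in, genes_sets))

    # --- burden scan + screen
    geno = genotype_frame(retained, sample_ids)
    results = burden_mod.burden_scan(
        cells, geno, labels, or_estimator=config.or_estimator, cmaf_mode=config.cmaf_mode
    )
    burden_path = os.path.join(out_dir, "burden.tsv")
    results.to_csv(burden_path, sep="\t", index=False)
    report.stage_tables["burden"] = burden_path
    genes_burden = results["gene"].nunique()
    report.stage_counts.append(("burden", genes_sets, genes_burden))
    logger.info("burden scan: %d (gene,set) tests over %d genes", len(results), genes_burden)

    screened, screen_genes = burden_mod.threshold_screen(
        results, p_max=config.p_max, or_min=config.or_min
    )
    screen_path = os.path.join(out_dir, "screen.tsv")
    screened.to_csv(screen_path, sep="\t", index=False)
    report.stage_tables["screen"] = screen_path
    report.stage_counts.append(("screen", genes_burden, len(screen_genes)))

    # --- evidence mapping
    table = load_evidence(config.evidence_dir)
    surviving = evidence_filter(screen_genes, table)
    ev_path = os.path.join(out_dir, "evidence.tsv")
    surviving.to_csv(ev_path, sep="\t", index=False)
    report.stage_tables["evidence"] = ev_path
    ev_genes = list(surviving["gene"])
    report.stage_counts.append(("evidence", len(screen_genes), len(ev_genes)))

    # --- carrier-phenotype scan within cases
    phenotypes = pd.read_csv(paths["phenotypes"], sep="\t", index_col="sample_id")
    case_mask = (labels == "case").to_numpy()
    scan = pheno_mod.phenotype_scan(ev_genes, cells, geno, phenotypes, case_mask)
    scan_path = os.path.join(out_dir, "phenotype_scan.tsv")
    scan.to_csv(scan_path, sep="\t", index=False)
    report.stage_tables["phenotype_scan"] = scan_path
    logger.info("phenotype scan: %d regressions", len(scan))

    sig_genes = pheno_mod.any_significant_filter(scan, alpha=config.alpha)
    sig = scan[scan["gene"].isin(sig_genes)]
    report.stage_counts.append(("phenotype_significant", len(ev_genes), len(sig_genes)))

    # --- pathway-pattern filters
    lipid = pheno_mod.lipid_filter(sig, direction=config.lipid_direction, alpha=config.alpha)
    lipid_path = os.path.join(out_dir, "lipid_genes.tsv")
    lipid.to_csv(lipid_path, sep="\t", index=False)
    report.stage_tables["lipid"] = lipid_path
    report.stage_counts.append(("lipid", len(sig_genes), len(lipid)))

    thromb = pheno_mod.thrombosis_filter(sig, alpha=config.alpha)
    thromb_path = os.path.join(out_dir, "thrombosis_genes.tsv")
    pd.DataFrame(
        [{"gene": g, "direction": d} for d in ("thrombosis", "bleeding") for g in thromb[d]]
    ).to_csv(thromb_path, sep="\t", index=False)
    report.stage_tables["thrombosis"] = thromb_path
    report.stage_counts.append(("thrombosis", len(sig_genes), len(thromb["thrombosis"])))

    inflam_rows = []
    for anchor in config.inflammation_anchors:
        for g in pheno_mod.inflammation_filter(sig, anchor=anchor, alpha=config.alpha):
            inflam_rows.append({"gene": g, "anchor": anchor})
    inflam = pd.DataFrame(inflam_rows, columns=["gene", "anchor"])
    inflam_path = os.path.join(out_dir, "inflammation_genes.tsv")
    inflam.to_csv(inflam_path, sep="\t", index=False)
    report.stage_tables["inflammation"] = inflam_path
    report.stage_counts.append(("inflammation", len(sig_genes), inflam["gene"].nunique()))

    # --- Table-1-style cohort comparison (descriptive, not a filter stage)
    compare = pheno_mod.cohort_compare(phenotypes, labels)
    cmp_path = os.path.join(out_dir, "cohort_compare.tsv")
    compare.to_csv(cmp_path, sep="\t", index=False)
    report.stage_tables["cohort_compare"] = cmp_path

    with open(os.path.join(out_dir, "run_summary.txt"), "w") as fh:
        fh.write(report.summary_text())
    with open(os.path.join(out_dir, "run_summary.json"), "w") as fh:
        json.dump(
            {
                "stage_counts": [list(t) for t in report.stage_counts],
                "seed": report.seed,
                "tables": report.stage_tables,
            },
            fh,
            indent=2,
        )
    with open(os.path.join(out_dir, "config_echo.yaml"), "w") as fh:
        fh.write(report.config_echo)
    logger.info("pipeline finished in %.1f s", time.time() - t0)
    return report
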