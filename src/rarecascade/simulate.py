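"""Synthetic case-control exome cohort generator.

Emulates the structure the downstream cascade expects: rare variants
(MAF < 5%) grouped by gene, planted risk genes with case-enriched carrier
frequencies, five correlated deleteriousness-predictor calls per missense
variant, and Gaussian phenotypes with additive carrier shifts.

Planted genes carry no background variation: each planted carrier receives
a single heterozygous allele at a randomly chosen variant of the gene, so
the configured carrier probability is the direct estimand of the collapsing
test. Non-planted variants draw an allele frequency from ``maf_range`` and
sample genotypes identically (binomially) in both arms.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import (
    FUNCTIONAL_CLASSES,
    MALE_FRACTION,
    ConfigError,
    SimConfig,
)

PREDICTORS = ("lrt", "mutationtaster", "polyphen_humdiv", "polyphen_humvar", "sift")

ANNOTATION_COLUMNS = ("variant_id", "gene", "functional_class", *PREDICTORS, "maf")


@dataclass
class SimulatedCohort:
    """In-memory synthetic cohort: genotypes, per-variant metadata, sequencing
    quality fields, annotations, phenotypes, labels, and the planted truth."""

    sample_ids: list[str]
    variant_ids: list[str]
    genes: list[str]  # gene of each variant, aligned with variant_ids
    genotypes: np.ndarray  # samples x variants, values 0/1/2 (-1 = missing)
    labels: pd.Series  # sample_id -> "case" / "control"
    truth: pd.DataFrame
    depths: np.ndarray  # samples x variants total read depth
    alt_depths: np.ndarray  # samples x variants alt-allele read depth
    mapping_quality: np.ndarray  # per-variant MQ
    strand_counts: np.ndarray  # variants x 4: ref_fwd, ref_rev, alt_fwd, alt_rev
    annotations: pd.DataFrame | None = None
    phenotypes: pd.DataFrame | None = None
    positions: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def genotype_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.genotypes, index=self.sample_ids, columns=self.variant_ids
        )

    @property
    def case_mask(self) -> np.ndarray:
        return (self.labels == "case").to_numpy()


def _allele_frequencies(genotypes: np.ndarray) -> np.ndarray:
    """Alt-allele frequency per variant over non-missing genotypes."""
    valid = genotypes >= 0
    alt = np.where(valid, genotypes, 0).sum(axis=0)
    slots = 2 * valid.sum(axis=0)
    with np.errstate(invalid="ignore"):
        return np.where(slots > 0, alt / np.maximum(slots, 1), 0.0)


def simulate_genotypes(config: SimConfig) -> SimulatedCohort:
    """Draw genotypes, arm labels, per-sample depths and site quality fields."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_cases + config.n_controls
    planted_names = [pg.gene for pg in config.planted_burden_genes]
    if len(set(planted_names)) != len(planted_names):
        raise ConfigError("duplicate planted gene ids")
    if len(planted_names) > config.n_genes:
        raise ConfigError("more planted genes than n_genes")
    filler = [f"GENE{i:04d}" for i in range(config.n_genes - len(planted_names))]
    genes_unique = planted_names + filler
    vpg = config.variants_per_gene
    genes = [g for g in genes_unique for _ in range(vpg)]
    variant_ids = [f"{g}_v{i}" for g in genes_unique for i in range(vpg)]
    n_var = len(variant_ids)
    positions = np.arange(1, n_var + 1) * 1000

    sample_ids = [f"CASE{i:04d}" for i in range(config.n_cases)] + [
        f"CTRL{i:04d}" for i in range(config.n_controls)
    ]
    labels = pd.Series(
        ["case"] * config.n_cases + ["control"] * config.n_controls,
        index=sample_ids,
        name="status",
    )
    is_case = labels.to_numpy() == "case"

    genotypes = np.zeros((n, n_var), dtype=np.int8)
    planted_set = set(planted_names)
    bg_cols = np.array([g not in planted_set for g in genes])
    if bg_cols.any():
        afs = rng.uniform(*config.maf_range, size=int(bg_cols.sum()))
        genotypes[:, bg_cols] = rng.binomial(2, afs, size=(n, int(bg_cols.sum())))

    truth_rows = []
    for k, pg in enumerate(config.planted_burden_genes):
        probs = np.where(is_case, pg.case_carrier_prob, pg.control_carrier_prob)
        carriers = np.flatnonzero(rng.random(n) < probs)
        cols = np.arange(k * vpg, (k + 1) * vpg)
        which = rng.integers(0, vpg, size=carriers.size)
        genotypes[carriers, cols[which]] = 1
        truth_rows.append(
            {
                "gene": pg.gene,
                "case_carrier_prob": pg.case_carrier_prob,
                "control_carrier_prob": pg.control_carrier_prob,
                "n_case_carriers": int(is_case[carriers].sum()),
                "n_control_carriers": int((~is_case[carriers]).sum()),
            }
        )
    for eff in config.planted_phenotype_effects:
        truth_rows.append(
            {"gene": eff.gene, "phenotype": eff.phenotype, "shift": eff.shift}
        )
    truth = pd.DataFrame(truth_rows)

    # Sequencing-quality fields consistent with the genotypes: deep, balanced
    # sites that pass default QC unless the caller perturbs them.
    depths = rng.poisson(100, size=(n, n_var)).astype(np.int32)
    depths = np.maximum(depths, 10)
    alt_frac = np.select(
        [genotypes <= 0, genotypes == 1], [0.0, 0.5], default=1.0
    )
    alt_depths = rng.binomial(depths, alt_frac).astype(np.int32)
    mapping_quality = np.full(n_var, 60.0)
    ref_total = (depths - alt_depths).sum(axis=0)
    alt_total = alt_depths.sum(axis=0)
    ref_fwd = rng.binomial(ref_total, 0.5)
    alt_fwd = rng.binomial(alt_total, 0.5)
    strand_counts = np.stack(
        [ref_fwd, ref_total - ref_fwd, alt_fwd, alt_total - alt_fwd], axis=1
    ).astype(np.int64)

    return SimulatedCohort(
        sample_ids=sample_ids,
        variant_ids=variant_ids,
        genes=genes,
        genotypes=genotypes,
        labels=labels,
        truth=truth,
        depths=depths,
        alt_depths=alt_depths,
        mapping_quality=mapping_quality,
        strand_counts=strand_counts,
        positions=positions,
    )


def simulate_annotations(cohort: SimulatedCohort, config: SimConfig) -> pd.DataFrame:
    """Assign functional classes, latent deleterious states and predictor calls.

    Missense variants get a latent deleterious state; each of the five
    predictors independently agrees with that state with probability
    ``predictor_concordance`` (the PolyPhen-2 HumDiv column reports a damaging
    category rather than a binary call). Disruptive classes (nonsense, splice,
    frameshift) carry no predictor calls: their set membership is class-driven.
    Planted-gene variants are restricted to non-synonymous classes with a
    deleterious latent state, so planted carriers hold qualifying alleles.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n_var = len(cohort.variant_ids)
    classes = np.array(FUNCTIONAL_CLASSES)
    weights = np.array([config.functional_class_weights.get(c, 0.0) for c in classes])
    planted = {pg.gene for pg in config.planted_burden_genes}
    is_planted = np.array([g in planted for g in cohort.genes])

    func = np.empty(n_var, dtype=object)
    func[~is_planted] = rng.choice(classes, size=int((~is_planted).sum()), p=weights)
    if is_planted.any():
        nonsyn = classes[:4]
        w = weights[:4]
        if w.sum() <= 0:
            w = np.ones(4)
        func[is_planted] = rng.choice(
            nonsyn, size=int(is_planted.sum()), p=w / w.sum()
        )

    is_missense = func == "missense"
    latent = np.zeros(n_var, dtype=bool)
    latent[is_missense] = rng.random(int(is_missense.sum())) < config.latent_deleterious_prob
    latent[is_planted] = True

    calls = {p: np.full(n_var, ".", dtype=object) for p in PREDICTORS}
    mi = np.flatnonzero(is_missense)
    for p in PREDICTORS:
        agree = rng.random(mi.size) < config.predictor_concordance
        deleterious = np.where(agree, latent[mi], ~latent[mi])
        if p == "polyphen_humdiv":
            # damaging HumDiv calls come in two categories, both deleterious
            cat = np.where(
                rng.random(mi.size) < 0.5, "probably_damaging", "possibly_damaging"
            )
            calls[p][mi] = np.where(deleterious, cat, "benign")
        else:
            calls[p][mi] = np.where(deleterious, "deleterious", "tolerated")

    afs = _allele_frequencies(cohort.genotypes)
    maf = np.minimum(afs, 1.0 - afs)
    ann = pd.DataFrame(
        {
            "variant_id": cohort.variant_ids,
            "gene": cohort.genes,
            "functional_class": func,
            **calls,
            "maf": maf,
        }
    )
    cohort.annotations = ann
    return ann


def simulate_phenotypes(cohort: SimulatedCohort, config: SimConfig) -> pd.DataFrame:
    """Gaussian phenotypes around the configured baselines, plus additive
    shifts for carriers of planted genes, plus a categorical sex column."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    n = len(cohort.sample_ids)
    data = {}
    for name, (mean, sd) in config.phenotype_baselines.items():
        data[name] = mean + rng.normal(0.0, sd, size=n) if sd > 0 else np.full(n, mean)
    pheno = pd.DataFrame(data, index=cohort.sample_ids)

    gene_cols = {}
    for eff in config.planted_phenotype_effects:
        if eff.phenotype not in pheno.columns:
            raise ConfigError(f"planted effect on unknown phenotype {eff.phenotype!r}")
        if eff.gene not in gene_cols:
            cols = [i for i, g in enumerate(cohort.genes) if g == eff.gene]
            gene_cols[eff.gene] = (cohort.genotypes[:, cols] > 0).any(axis=1)
        pheno.loc[gene_cols[eff.gene], eff.phenotype] += eff.shift

    is_case = cohort.case_mask
    p_male = np.where(is_case, MALE_FRACTION["case"], MALE_FRACTION["control"])
    pheno["sex"] = np.where(rng.random(n) < p_male, "male", "female")
    cohort.phenotypes = pheno
    return pheno


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Run all three generator stages; fully determined by ``config.seed``."""
    cohort = simulate_genotypes(config)
    simulate_annotations(cohort, config)
    simulate_phenotypes(cohort, config)
    return cohort


# ---------------------------------------------------------------------------
# on-disk representation


def write_vcf(cohort: SimulatedCohort, path: str) -> None:
    """Emit a VCF v4.2 with per-sample GT, DP, AD and site INFO MQ and SB."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=1>\n")
        fh.write('##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">\n')
        fh.write(
            '##INFO=<ID=SB,Number=4,Type=Integer,'
            'Description="Strand counts: ref-fwd,ref-rev,alt-fwd,alt-rev">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(cohort.sample_ids)
            + "\n"
        )
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
        for j, vid in enumerate(cohort.variant_ids):
            sb = ",".join(str(int(x)) for x in cohort.strand_counts[j])
            info = f"MQ={cohort.mapping_quality[j]:g};SB={sb}"
            fields = [
                "1",
                str(int(cohort.positions[j])),
                vid,
                "A",
                "G",
                ".",
                "PASS",
                info,
                "GT:DP:AD",
            ]
            for i in range(len(cohort.sample_ids)):
                dp = int(cohort.depths[i, j])
                ad = int(cohort.alt_depths[i, j])
                fields.append(f"{gt_str[int(cohort.genotypes[i, j])]}:{dp}:{dp - ad},{ad}")
            fh.write("\t".join(fields) + "\n")


def write_cohort(cohort: SimulatedCohort, directory: str) -> dict[str, str]:
    """Write the cohort as VCF + annotation/phenotype/labels/truth TSVs.

    Files round-trip losslessly through ``qc.read_vcf`` and the pandas
    readers. Returns a name -> path mapping.
    """
    os.makedirs(directory, exist_ok=True)
    paths = {
        "vcf": os.path.join(directory, "genotypes.vcf"),
        "annotations": os.path.join(directory, "annotations.tsv"),
        "phenotypes": os.path.join(directory, "phenotypes.tsv"),
        "labels": os.path.join(directory, "labels.tsv"),
        "truth": os.path.join(directory, "truth.tsv"),
    }
    write_vcf(cohort, paths["vcf"])
    if cohort.annotations is not None:
        cohort.annotations.to_csv(paths["annotations"], sep="\t", index=False)
    if cohort.phenotypes is not None:
        cohort.phenotypes.to_csv(
            paths["phenotypes"], sep="\t", index_label="sample_id"
        )
    cohort.labels.rename("status").to_csv(
        paths["labels"], sep="\t", index_label="sample_id"
    )
    cohort.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
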