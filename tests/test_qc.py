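"""Site-level QC rules, engineered per-rule fixtures, and VCF ingestion."""

import numpy as np
import pandas as pd
import pytest

from rarecascade import QCThresholds, SimConfig, apply_qc, read_vcf, simulate_genotypes, write_cohort
from rarecascade.config import ConfigError
from rarecascade.qc import VariantRecord

N = 40  # samples; the last 30 are controls
CONTROLS = np.array([False] * 10 + [True] * 30)


def make_variant(vid, **overrides):
    """A clean variant passing every rule: 4 scattered hets, deep balanced
    coverage. Overrides perturb exactly one quantity."""
    genotypes = np.zeros(N, dtype=np.int8)
    genotypes[[2, 8, 20, 30]] = 1  # one het in cases, three in controls
    depths = np.full(N, 30)
    ad = np.stack([depths.copy(), np.zeros(N, dtype=int)], axis=1)
    for i in np.flatnonzero(genotypes == 1):
        ad[i] = (15, 15)
    fields = dict(
        variant_id=vid,
        chrom="1",
        pos=100,
        ref="A",
        alt="G",
        genotypes=genotypes,
        depths=depths,
        allele_depths=ad,
        mapping_quality=60.0,
        strand_counts=(600, 600, 30, 30),
    )
    fields.update(overrides)
    return VariantRecord(**fields)


def hwe_fail_variant(vid):
    # controls split into 15 hom-ref / 15 hom-alt with no hets: extreme
    # heterozygote deficit, exact HWE p ~ 1.3e-9
    genotypes = np.zeros(N, dtype=np.int8)
    genotypes[25:] = 2
    depths = np.full(N, 30)
    ad = np.stack(
        [np.where(genotypes == 0, 30, 0), np.where(genotypes == 2, 30, 0)], axis=1
    )
    return make_variant(vid, genotypes=genotypes, allele_depths=ad)


def minor_depth_fail_variant(vid):
    v = make_variant(vid)
    carriers = v.genotypes >= 1
    v.depths = np.where(carriers, 3, 40)
    for i in np.flatnonzero(carriers):
        v.allele_depths[i] = (1, 2)
    return v


@pytest.fixture()
def engineered():
    """Ten variants: one fails each of the six rules, four are clean."""
    shallow = make_variant("fail_mean_depth", depths=np.full(N, 7))
    shallow.allele_depths = np.stack(
        [np.where(shallow.genotypes == 1, 3, 7), np.where(shallow.genotypes == 1, 4, 0)],
        axis=1,
    )
    failing = [
        shallow,
        minor_depth_fail_variant("fail_minor_depth"),
        make_variant("fail_mq", mapping_quality=10.0),
        make_variant("fail_strand", strand_counts=(600, 600, 60, 0)),
        make_variant("fail_imbalance"),
        hwe_fail_variant("fail_hwe"),
    ]
    # imbalance: het alt fraction 0.1, below the [0.25, 0.75] band
    for i in np.flatnonzero(failing[4].genotypes == 1):
        failing[4].allele_depths[i] = (27, 3)
    clean = [make_variant(f"ok{i}") for i in range(4)]
    return failing + clean


EXPECTED_RULE = {
    "fail_mean_depth": "mean_depth",
    "fail_minor_depth": "minor_allele_depth",
    "fail_mq": "mapping_quality",
    "fail_strand": "strand_bias",
    "fail_imbalance": "allelic_imbalance",
    "fail_hwe": "hwe",
}


class TestApplyQC:
    def test_each_rule_fires_on_its_engineered_variant(self, engineered):
        retained, log = apply_qc(engineered, QCThresholds(), CONTROLS)
        assert sorted(v.variant_id for v in retained) == ["ok0", "ok1", "ok2", "ok3"]
        fired = dict(zip(log["variant_id"], log["rule"]))
        assert fired == EXPECTED_RULE

    def test_mean_depth_boundary(self):
        v = make_variant("d79", depths=np.full(N, 7.9))
        v.allele_depths = np.zeros((N, 2))  # keep AD <= DP; no hets consulted
        _, log = apply_qc([v], QCThresholds(), CONTROLS)
        assert "mean_depth" in set(log["rule"])

    def test_clean_variant_absent_from_log(self):
        retained, log = apply_qc([make_variant("ok")], QCThresholds(), CONTROLS)
        assert len(retained) == 1 and log.empty

    def test_idempotent(self, engineered):
        retained, _ = apply_qc(engineered, QCThresholds(), CONTROLS)
        again, log2 = apply_qc(retained, QCThresholds(), CONTROLS)
        assert [v.variant_id for v in again] == [v.variant_id for v in retained]
        assert log2.empty

    def test_retained_set_monotone_in_thresholds(self, engineered):
        strict, _ = apply_qc(engineered, QCThresholds(), CONTROLS)
        loose = QCThresholds(
            min_minor_allele_mean_depth=1.0,
            min_mean_depth=1.0,
            min_mapping_quality=5.0,
            strand_bias_p=1e-9,
            allelic_imbalance_band=(0.05, 0.95),
            hwe_p=1e-12,
        )
        relaxed, _ = apply_qc(engineered, loose, CONTROLS)
        assert {v.variant_id for v in strict} <= {v.variant_id for v in relaxed}

    def test_zero_control_mask_rejected(self, engineered):
        with pytest.raises(ConfigError):
            apply_qc(engineered, QCThresholds(), np.zeros(N, dtype=bool))

    def test_minor_allele_depth_alternative_mode(self):
        v = minor_depth_fail_variant("v")
        # mean minor-allele AD among carriers is 2 < 4: fails in both modes
        _, log_allele = apply_qc([v], QCThresholds(minor_depth_mode="allele"), CONTROLS)
        assert "minor_allele_depth" in set(log_allele["rule"])


class TestReadVCF:
    def test_genotype_encoding_and_missing(self, tmp_path):
        vcf = tmp_path / "t.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\tS4\n"
            "1\t100\tv1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\t./.\n"
        )
        records, samples = read_vcf(str(vcf))
        assert samples == ["S1", "S2", "S3", "S4"]
        np.testing.assert_array_equal(records[0].genotypes, [0, 1, 2, -1])

    def test_multiallelic_split_with_per_allele_depths(self, tmp_path):
        vcf = tmp_path / "m.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="d">\n'
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="a">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
            "1\t55\t.\tA\tC,T\t.\tPASS\t.\tGT:DP:AD\t0/1:30:14,16,0\t1/2:28:0,13,15\n"
        )
        records, _ = read_vcf(str(vcf))
        assert len(records) == 2
        first, second = records
        assert (first.alt, second.alt) == ("C", "T")
        np.testing.assert_array_equal(first.genotypes, [1, 1])
        np.testing.assert_array_equal(second.genotypes, [0, 1])
        np.testing.assert_array_equal(first.allele_depths[:, 1], [16, 13])
        np.testing.assert_array_equal(second.allele_depths[:, 1], [0, 15])

    def test_simulated_cohort_qc_passes_cleanly(self, tmp_path):
        cfg = SimConfig(n_cases=25, n_controls=25, n_genes=20, seed=13)
        cohort = simulate_genotypes(cfg)
        paths = write_cohort(cohort, str(tmp_path))
        records, samples = read_vcf(paths["vcf"])
        labels = pd.read_csv(paths["labels"], sep="\t", index_col="sample_id")["status"]
        retained, _ = apply_qc(
            records, QCThresholds(), (labels.reindex(samples) == "control").to_numpy()
        )
        # deep balanced simulated sites: the vast majority must survive
        assert len(retained) >= 0.9 * len(records)
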