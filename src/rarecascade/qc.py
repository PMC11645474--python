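"""Site-level variant quality control.

Six exclusion rules, any of which drops a variant: (i) low mean depth,
(ii) low mean depth among minor-allele carriers, (iii) low mapping quality,
(iv) strand bias (two-sided exact test on ref/alt x fwd/rev read counts),
(v) heterozygote allelic imbalance, (vi) Hardy-Weinberg disequilibrium in
control samples (cases are expected to violate HWE at true risk sites, so
the test is restricted to controls).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ConfigError, QCThresholds
from .exact import fisher_two_sided, hwe_exact_p

logger = logging.getLogger(__name__)

QC_RULES = (
    "mean_depth",
    "minor_allele_depth",
    "mapping_quality",
    "strand_bias",
    "allelic_imbalance",
    "hwe",
)


@dataclass
class VariantRecord:
    """One bi-allelic called site with per-sample genotype and depth fields."""

    variant_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    genotypes: np.ndarray  # per-sample alt-allele count, -1 = missing
    depths: np.ndarray  # per-sample total depth
    allele_depths: np.ndarray  # per-sample (ref_depth, alt_depth)
    mapping_quality: float | None
    strand_counts: tuple[int, int, int, int] | None  # ref_fwd, ref_rev, alt_fwd, alt_rev

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.variant_id}: position must be 1-based")


class VCFParseError(ValueError):
    pass


def read_vcf(path: str) -> tuple[list[VariantRecord], list[str]]:
    """Read a VCF v4.2 into VariantRecords; multi-allelic sites are split
    into one record per alternate allele, with per-allele AD bookkeeping.

    Returns (records, sample_ids).
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare OSError on bad files
        raise VCFParseError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    n = len(samples)
    records: list[VariantRecord] = []
    for v in vcf:
        gts = v.genotypes  # [allele1, allele2, phased] per sample
        for g in gts:
            if len(g) != 3:
                raise VCFParseError(
                    f"non-diploid genotype at {v.CHROM}:{v.POS} ({g[:-1]})"
                )
        try:
            ad = v.format("AD")
        except KeyError:
            ad = None
        try:
            dp = v.format("DP")
            dp = dp.reshape(n).astype(np.int64)
        except KeyError:
            dp = (
                ad.sum(axis=1).astype(np.int64)
                if ad is not None
                else np.zeros(n, dtype=np.int64)
            )
        dp = np.maximum(dp, 0)
        mq = v.INFO.get("MQ")
        sb = v.INFO.get("SB")
        if sb is not None:
            sb = tuple(int(x) for x in (sb if hasattr(sb, "__len__") else (sb,)))
            if len(sb) != 4:
                sb = None
        for k, alt in enumerate(v.ALT):
            alt_idx = k + 1
            gt = np.full(n, -1, dtype=np.int8)
            for i, g in enumerate(gts):
                a1, a2 = g[0], g[1]
                if a1 < 0 or a2 < 0:
                    continue
                gt[i] = int(a1 == alt_idx) + int(a2 == alt_idx)
            if ad is not None and ad.shape[1] > alt_idx:
                ref_d = np.maximum(ad[:, 0].astype(np.int64), 0)
                alt_d = np.maximum(ad[:, alt_idx].astype(np.int64), 0)
            else:
                ref_d = np.where(gt == 0, dp, np.where(gt == 1, dp // 2, 0))
                alt_d = np.where(gt >= 0, dp - ref_d, 0)
            vid = v.ID if v.ID else f"{v.CHROM}:{v.POS}:{v.REF}:{alt}"
            if len(v.ALT) > 1:
                vid = f"{vid}_{alt}" if v.ID else vid
            records.append(
                VariantRecord(
                    variant_id=vid,
                    chrom=v.CHROM,
                    pos=v.POS,
                    ref=v.REF,
                    alt=alt,
                    genotypes=gt,
                    depths=dp.copy(),
                    allele_depths=np.stack([ref_d, alt_d], axis=1),
                    mapping_quality=float(mq) if mq is not None else None,
                    strand_counts=sb,
                )
            )
    return records, samples


def _strand_bias_p(ref_fwd: int, ref_rev: int, alt_fwd: int, alt_rev: int) -> float:
    """Two-sided Fisher exact p on the ref/alt x fwd/rev read-count table.

    Strand tables carry whole-cohort read counts (margins in the tens of
    thousands), so this delegates to scipy's vectorised exact test rather
    than the big-integer enumeration used for carrier tables.
    """
    if min(ref_fwd + ref_rev, alt_fwd + alt_rev, ref_fwd + alt_fwd, ref_rev + alt_rev) == 0:
        return 1.0
    from scipy.stats import fisher_exact

    return float(fisher_exact([[ref_fwd, ref_rev], [alt_fwd, alt_rev]]).pvalue)


def _failure(rec: VariantRecord, thresholds: QCThresholds, control_mask: np.ndarray):
    """Yield (rule, value, threshold) for every QC rule the variant fails."""
    gt = rec.genotypes
    valid = gt >= 0
    th = thresholds

    if valid.any():
        mean_depth = float(rec.depths[valid].mean())
        if mean_depth < th.min_mean_depth:
            yield "mean_depth", mean_depth, th.min_mean_depth

        af = gt[valid].sum() / (2 * valid.sum())
        minor_is_alt = af <= 0.5
        minor_carrier = valid & ((gt >= 1) if minor_is_alt else (gt <= 1))
        if minor_carrier.any():
            if th.minor_depth_mode == "total":
                md = float(rec.depths[minor_carrier].mean())
            else:
                col = 1 if minor_is_alt else 0
                md = float(rec.allele_depths[minor_carrier, col].mean())
            if md < th.min_minor_allele_mean_depth:
                yield "minor_allele_depth", md, th.min_minor_allele_mean_depth

    if rec.mapping_quality is not None and rec.mapping_quality < th.min_mapping_quality:
        yield "mapping_quality", rec.mapping_quality, th.min_mapping_quality

    if rec.strand_counts is not None:
        p_sb = _strand_bias_p(*rec.strand_counts)
        if p_sb < th.strand_bias_p:
            yield "strand_bias", p_sb, th.strand_bias_p

    het = gt == 1
    if het.any():
        ad = rec.allele_depths[het]
        tot = ad.sum(axis=1)
        ok = tot > 0
        if ok.any():
            frac = float((ad[ok, 1] / tot[ok]).mean())
            lo, hi = th.allelic_imbalance_band
            if not (lo <= frac <= hi):
                yield "allelic_imbalance", frac, lo if frac < lo else hi

    ctl = gt[control_mask]
    ctl = ctl[ctl >= 0]
    if ctl.size:
        n_hom_ref = int((ctl == 0).sum())
        n_het = int((ctl == 1).sum())
        n_hom_alt = int((ctl == 2).sum())
        p_hwe = hwe_exact_p(n_hom_ref, n_het, n_hom_alt)
        if p_hwe < th.hwe_p:
            yield "hwe", p_hwe, th.hwe_p


def apply_qc(
    variants: list[VariantRecord],
    thresholds: QCThresholds | None = None,
    control_mask: np.ndarray | None = None,
) -> tuple[list[VariantRecord], pd.DataFrame]:
    """Apply all six exclusion rules; a variant failing any rule is dropped.

    Returns (retained variants, QC log) where the log holds one row per
    (variant, failed rule) with the offending value and the threshold.
    ``control_mask`` selects the samples used for the HWE test; it must pick
    at least one sample.
    """
    if thresholds is None:
        thresholds = QCThresholds()
    thresholds.validate()
    if control_mask is None:
        raise ConfigError("control_mask is required for the HWE rule")
    control_mask = np.asarray(control_mask, dtype=bool)
    if not control_mask.any():
        raise ConfigError("control_mask selects zero samples")

    retained: list[VariantRecord] = []
    log_rows = []
    for rec in variants:
        failures = list(_failure(rec, thresholds, control_mask))
        if failures:
            for rule, value, threshold in failures:
                log_rows.append(
                    {
                        "variant_id": rec.variant_id,
                        "rule": rule,
                        "value": value,
                        "threshold": threshold,
                    }
                )
        else:
            retained.append(rec)
    log = pd.DataFrame(log_rows, columns=["variant_id", "rule", "value", "threshold"])
    logger.info(
        "QC: retained %d / %d variants (%d exclusion records)",
        len(retained),
        len(variants),
        len(log),
    )
    return retained, log


def genotype_frame(
    variants: list[VariantRecord], sample_ids: list[str]
) -> pd.DataFrame:
    """Samples-by-variants allele-count table (-1 = missing)."""
    if not variants:
        return pd.DataFrame(index=sample_ids)
    data = np.stack([v.genotypes for v in variants], axis=1)
    return pd.DataFrame(
        data, index=sample_ids, columns=[v.variant_id for v in variants]
    )
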