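"""Per-gene collapsing (CAST-style) burden test.

A gene's qualifying variants in a given SNV set are collapsed to a single
per-sample carrier indicator (dominant coding: at least one minor allele at
at least one qualifying site). Carrier counts in cases vs controls form a
2x2 table tested with the two-sided Fisher exact test; the screen keeps
rows with p below ``p_max`` and odds ratio above ``or_min``. No
multiple-testing correction is applied at this stage — the scan reports the
number of tests performed so users can correct downstream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exact import fisher_two_sided, odds_ratio
from .sets import SET_ORDER, SetLabel

BURDEN_COLUMNS = (
    "gene",
    "set",
    "n_carrier_cases",
    "n_noncarrier_cases",
    "n_carrier_controls",
    "n_noncarrier_controls",
    "cmaf",
    "or_estimate",
    "p",
)


def carrier_status(genotypes: pd.DataFrame, qualifying_variant_ids) -> pd.Series:
    """Per-sample carrier indicator over the qualifying variants.

    A sample carries iff it has >= 1 minor allele at >= 1 qualifying site.
    Samples missing at every qualifying site are dropped from the result
    (they enter neither carrier nor non-carrier counts).
    """
    ids = list(qualifying_variant_ids)
    if not ids:
        raise ValueError("empty qualifying variant list")
    missing = [v for v in ids if v not in genotypes.columns]
    if missing:
        raise KeyError(f"variants absent from genotype table: {missing[:5]}")
    sub = genotypes[ids].to_numpy()
    informative = (sub >= 0).any(axis=1)
    carrier = (sub > 0).any(axis=1)
    return pd.Series(carrier[informative], index=genotypes.index[informative])


def collapsed_maf(
    genotypes: pd.DataFrame, qualifying_variant_ids, mode: str = "allele"
) -> float:
    """Collapsed minor allele frequency over a gene's qualifying variants.

    ``allele`` (default): total minor-allele count over all qualifying sites
    and non-missing samples, divided by the number of non-missing allele
    slots (two per sample per site). ``carrier``: fraction of informative
    samples carrying at least one qualifying allele.
    """
    ids = list(qualifying_variant_ids)
    if not ids:
        raise ValueError("empty qualifying variant list")
    sub = genotypes[ids].to_numpy()
    valid = sub >= 0
    if not valid.any():
        raise ValueError("all genotypes missing at qualifying variants")
    if mode == "carrier":
        status = carrier_status(genotypes, ids)
        return float(status.mean())
    if mode != "allele":
        raise ValueError(f"unknown cmaf mode {mode!r}")
    alt = int(sub[valid].sum())
    slots = int(2 * valid.sum())
    f = alt / slots
    return min(f, 1.0 - f)


def burden_scan(
    gene_sets: dict[tuple[str, SetLabel], list[str]],
    genotypes: pd.DataFrame,
    labels: pd.Series,
    or_estimator: str = "haldane",
    cmaf_mode: str = "allele",
) -> pd.DataFrame:
    """One burden test per non-empty (gene, set) cell.

    ``labels`` maps sample id to "case"/"control" and must cover the
    genotype table's samples, with at least one of each.
    """
    labels = labels.reindex(genotypes.index)
    if labels.isna().any():
        raise ValueError("labels missing for some genotyped samples")
    is_case = (labels == "case").to_numpy()
    if not is_case.any() or is_case.all():
        raise ValueError("need at least one case and one control")

    geno = genotypes.to_numpy()
    col_of = {v: i for i, v in enumerate(genotypes.columns)}
    rows = []
    for (gene, label), ids in sorted(
        gene_sets.items(), key=lambda kv: (kv[0][0], SET_ORDER.index(kv[0][1]))
    ):
        if not ids:
            continue
        cols = [col_of[v] for v in ids]
        sub = geno[:, cols]
        valid = sub >= 0
        informative = valid.any(axis=1)
        carrier = (sub > 0).any(axis=1)
        a = int((carrier & is_case & informative).sum())
        b = int((~carrier & is_case & informative).sum())
        c = int((carrier & ~is_case & informative).sum())
        d = int((~carrier & ~is_case & informative).sum())
        alt = int(sub[valid].sum())
        slots = int(2 * valid.sum())
        if slots == 0:
            continue
        f = alt / slots
        rows.append(
            {
                "gene": gene,
                "set": label.value,
                "n_carrier_cases": a,
                "n_noncarrier_cases": b,
                "n_carrier_controls": c,
                "n_noncarrier_controls": d,
                "cmaf": (a + c) / max(a + b + c + d, 1)
                if cmaf_mode == "carrier"
                else min(f, 1.0 - f),
                "or_estimate": odds_ratio(a, b, c, d, estimator=or_estimator),
                "p": fisher_two_sided(a, b, c, d),
            }
        )
    return pd.DataFrame(rows, columns=BURDEN_COLUMNS)


def threshold_screen(
    results: pd.DataFrame, p_max: float = 0.05, or_min: float = 3.5
) -> tuple[pd.DataFrame, list[str]]:
    """Keep rows with p < p_max and OR > or_min (strict inequalities).

    Returns (surviving rows, deduplicated gene list) — a gene survives if any
    of its set-level rows survives; order of first appearance is preserved.
    """
    if results.empty:
        return results.copy(), []
    kept = results[(results["p"] < p_max) & (results["or_estimate"] > or_min)]
    genes = list(dict.fromkeys(kept["gene"]))
    return kept.reset_index(drop=True), genes
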