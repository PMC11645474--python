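"""Carrier-phenotype association and pathway-pattern filters.

Within the case arm, each candidate gene's carriers of qualifying mutations
are compared with non-carriers on every quantitative phenotype by ordinary
least squares of the phenotype on the 0/1 carrier indicator (no covariates).
With a single binary regressor the OLS slope is exactly the carrier-minus-
noncarrier mean difference and its t-test equals the pooled-variance
two-sample t-test, which is how it is computed here.

Downstream filters encode the cascade's pathway patterns: any-phenotype
significance, positive lipid association, joint PT+APTT reduction
(thrombosis direction; joint elevation is reported separately as a bleeding
direction), and an inflammation pattern anchored on CRP or fibrinogen with
concordant white-cell shifts. A gene passes a pattern if the rows of any of
its SNV sets satisfy it.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .burden import carrier_status
from .exact import fisher_two_sided
from .sets import SET_ORDER, SetLabel

logger = logging.getLogger(__name__)

LIPID_TRAITS = ("TC", "LDL_C", "TG", "HDL_C", "ApoA1", "ApoB", "ApoE", "NHDL_C")
INFLAMMATION_REQUIRED = ("WBC", "neutrophil_pct", "monocyte_pct")

SCAN_COLUMNS = ("gene", "set", "phenotype", "beta", "p", "n_carriers")


class DegenerateFitWarning(UserWarning):
    pass


def carrier_regression(phenotype_values, carrier_flags) -> tuple[float, float]:
    """OLS of phenotype on carrier indicator: (beta, two-sided p).

    Missing phenotype values are dropped first; at least one carrier and one
    non-carrier must remain. Zero residual variance is degenerate: p = 1
    (with a warning) when the group means agree, p = 0 when they differ.
    """
    y = np.asarray(phenotype_values, dtype=float)
    x = np.asarray(carrier_flags, dtype=bool)
    keep = ~np.isnan(y)
    y, x = y[keep], x[keep]
    if not x.any() or x.all():
        raise ValueError("need >= 1 carrier and >= 1 noncarrier with phenotype data")
    yc, yn = y[x], y[~x]
    beta = float(yc.mean() - yn.mean())
    ssw = float(((yc - yc.mean()) ** 2).sum() + ((yn - yn.mean()) ** 2).sum())
    if ssw == 0.0:
        warnings.warn("zero residual variance in carrier regression", DegenerateFitWarning)
        return beta, 1.0 if beta == 0.0 else 0.0
    df = y.size - 2
    if df <= 0:
        warnings.warn("no residual degrees of freedom", DegenerateFitWarning)
        return beta, 1.0
    se = np.sqrt(ssw / df * (1.0 / yc.size + 1.0 / yn.size))
    t = beta / se
    return beta, float(2.0 * stats.t.sf(abs(t), df))


def phenotype_scan(
    candidate_genes: list[str],
    gene_sets: dict[tuple[str, SetLabel], list[str]],
    genotypes: pd.DataFrame,
    phenotypes: pd.DataFrame,
    case_mask,
) -> pd.DataFrame:
    """Carrier-vs-noncarrier regression for every (candidate gene, set,
    quantitative phenotype), restricted to case samples.

    Cells whose preconditions fail (no case carriers, no non-carriers, or
    all-missing phenotype) are logged and skipped.
    """
    case_mask = np.asarray(case_mask, dtype=bool)
    cases = genotypes.index[case_mask]
    geno_cases = genotypes.loc[cases]
    pheno_cases = phenotypes.loc[cases]
    numeric = pheno_cases.select_dtypes(include=[np.number]).columns
    wanted = set(candidate_genes)
    rows = []
    for (gene, label), ids in sorted(
        gene_sets.items(), key=lambda kv: (kv[0][0], SET_ORDER.index(kv[0][1]))
    ):
        if gene not in wanted or not ids:
            continue
        status = carrier_status(geno_cases, ids)
        n_car = int(status.sum())
        if n_car == 0 or n_car == status.size:
            logger.info("skip %s/%s: %d case carriers of %d", gene, label.value, n_car, status.size)
            continue
        for phen in numeric:
            y = pheno_cases.loc[status.index, phen]
            flags = status[y.notna()]
            if flags.empty or not flags.any() or flags.all():
                logger.info("skip %s/%s/%s: no informative contrast", gene, label.value, phen)
                continue
            beta, p = carrier_regression(y.to_numpy(), status.to_numpy())
            rows.append(
                {
                    "gene": gene,
                    "set": label.value,
                    "phenotype": phen,
                    "beta": beta,
                    "p": p,
                    "n_carriers": n_car,
                }
            )
    return pd.DataFrame(rows, columns=SCAN_COLUMNS)


def any_significant_filter(results: pd.DataFrame, alpha: float = 0.05) -> list[str]:
    """Genes with at least one phenotype row at p < alpha (order-preserving)."""
    if results.empty:
        return []
    kept = results[results["p"] < alpha]
    sig = set(kept["gene"])
    return [g for g in dict.fromkeys(results["gene"]) if g in sig]


def lipid_filter(
    results: pd.DataFrame,
    traits: tuple[str, ...] = LIPID_TRAITS,
    direction: str = "positive",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Genes with a significant lipid association in the configured direction.

    Returns one row per gene with the driving (set, trait) pairs.
    """
    if direction not in ("positive", "negative"):
        raise ValueError("direction must be 'positive' or 'negative'")
    if results.empty:
        return pd.DataFrame(columns=["gene", "driving"])
    sign_ok = results["beta"] > 0 if direction == "positive" else results["beta"] < 0
    hits = results[results["phenotype"].isin(traits) & (results["p"] < alpha) & sign_ok]
    rows = []
    for gene in dict.fromkeys(results["gene"]):
        g = hits[hits["gene"] == gene]
        if not g.empty:
            driving = sorted({(r["set"], r["phenotype"]) for _, r in g.iterrows()})
            rows.append({"gene": gene, "driving": ";".join(f"{s}:{t}" for s, t in driving)})
    return pd.DataFrame(rows, columns=["gene", "driving"])


def thrombosis_filter(results: pd.DataFrame, alpha: float = 0.05) -> dict[str, list[str]]:
    """Genes whose PT and APTT rows are both significant within one SNV set.

    Joint reductions flag a thrombotic direction; joint elevations are kept
    separately as a bleeding direction (no thrombotic risk). Genes with only
    one of the two significant, or discordant signs, pass neither list.
    """
    thrombosis: list[str] = []
    bleeding: list[str] = []
    if results.empty:
        return {"thrombosis": [], "bleeding": []}
    for gene in dict.fromkeys(results["gene"]):
        g = results[results["gene"] == gene]
        for s in g["set"].unique():
            rows = g[g["set"] == s].set_index("phenotype")
            if "PT" not in rows.index or "APTT" not in rows.index:
                continue
            pt, aptt = rows.loc["PT"], rows.loc["APTT"]
            if pt["p"] < alpha and aptt["p"] < alpha:
                if pt["beta"] < 0 and aptt["beta"] < 0:
                    if gene not in thrombosis:
                        thrombosis.append(gene)
                elif pt["beta"] > 0 and aptt["beta"] > 0:
                    if gene not in bleeding:
                        bleeding.append(gene)
    return {"thrombosis": thrombosis, "bleeding": bleeding}


def inflammation_filter(
    results: pd.DataFrame, anchor: str = "CRP", alpha: float = 0.05
) -> list[str]:
    """Genes matching the inflammation pattern within at least one SNV set:
    anchor (CRP or fibrinogen) raised, WBC count raised, neutrophil fraction
    raised, monocyte fraction lowered — all at p < alpha."""
    if anchor not in ("CRP", "fibrinogen"):
        raise ValueError("anchor must be 'CRP' or 'fibrinogen'")
    out: list[str] = []
    if results.empty:
        return out
    need = (anchor, *INFLAMMATION_REQUIRED)
    for gene in dict.fromkeys(results["gene"]):
        g = results[results["gene"] == gene]
        for s in g["set"].unique():
            rows = g[g["set"] == s].set_index("phenotype")
            if any(ph not in rows.index for ph in need):
                logger.info("inflammation_filter: %s/%s missing required rows", gene, s)
                continue
            ok = (
                rows.loc[anchor, "beta"] > 0
                and rows.loc[anchor, "p"] < alpha
                and rows.loc["WBC", "beta"] > 0
                and rows.loc["WBC", "p"] < alpha
                and rows.loc["neutrophil_pct", "beta"] > 0
                and rows.loc["neutrophil_pct", "p"] < alpha
                and rows.loc["monocyte_pct", "beta"] < 0
                and rows.loc["monocyte_pct", "p"] < alpha
            )
            if ok and gene not in out:
                out.append(gene)
    return out


def cohort_compare(
    phenotypes: pd.DataFrame, labels: pd.Series, exact_max_n: int = 25
) -> pd.DataFrame:
    """Case-vs-control cohort comparison table.

    Quantitative phenotypes: per-arm mean and SD with a two-sided Wilcoxon
    rank-sum p (exact when both arms have <= ``exact_max_n`` samples and no
    ties, tie-corrected normal approximation otherwise). Categorical columns:
    per-arm percentage of the modal category with a two-sided Fisher exact p.
    """
    labels = labels.reindex(phenotypes.index)
    is_case = (labels == "case").to_numpy()
    if is_case.sum() < 2 or (~is_case).sum() < 2:
        raise ValueError("need >= 2 samples per arm")
    rows = []
    for col in phenotypes.columns:
        series = phenotypes[col]
        if pd.api.types.is_numeric_dtype(series):
            a = series[is_case].dropna().to_numpy(dtype=float)
            b = series[~is_case].dropna().to_numpy(dtype=float)
            if a.size < 2 or b.size < 2:
                logger.info("cohort_compare: %s has too few values, omitted", col)
                continue
            no_ties = np.unique(np.concatenate([a, b])).size == a.size + b.size
            method = "exact" if (max(a.size, b.size) <= exact_max_n and no_ties) else "asymptotic"
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)
            rows.append(
                {
                    "phenotype": col,
                    "type": "quantitative",
                    "case_mean": float(a.mean()),
                    "case_sd": float(a.std(ddof=1)),
                    "control_mean": float(b.mean()),
                    "control_sd": float(b.std(ddof=1)),
                    "p": p,
                }
            )
        else:
            vals = series.dropna()
            if vals.empty:
                logger.info("cohort_compare: %s all missing, omitted", col)
                continue
            top = vals.mode().iloc[0]
            a_pos = int(((series == top) & is_case & series.notna()).sum())
            a_tot = int((is_case & series.notna()).sum())
            b_pos = int(((series == top) & ~is_case & series.notna()).sum())
            b_tot = int((~is_case & series.notna()).sum())
            p = fisher_two_sided(a_pos, a_tot - a_pos, b_pos, b_tot - b_pos)
            rows.append(
                {
                    "phenotype": f"{col}={top}",
                    "type": "categorical",
                    "case_mean": 100.0 * a_pos / max(a_tot, 1),
                    "case_sd": np.nan,
                    "control_mean": 100.0 * b_pos / max(b_tot, 1),
                    "control_sd": np.nan,
                    "p": p,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["phenotype", "type", "case_mean", "case_sd", "control_mean", "control_sd", "p"],
    )
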