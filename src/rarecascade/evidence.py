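"""Gene-evidence mapping against database export tables.

Four TSV sources are joined by (case-folded) gene symbol:

* ``glgc.tsv``          — gene, tc_p, tg_p, ldl_p, hdl_p: lipid-trait
  association p-values (Global Lipids Genetics Consortium style);
* ``cardiogram.tsv``    — gene: CAD association (CARDIoGRAMplusC4D style);
* ``mgi.tsv``           — gene, category: mouse phenotype annotations in the
  five relevant categories (cardiovascular, adipose, metabolism,
  endocrine/exocrine, liver);
* ``gwas_catalog.tsv``  — gene: CAD flag from a GWAS-catalog style export.

The evidence filter keeps a gene with evidence in at least one of GLGC,
CARDIoGRAMplusC4D or MGI; the GWAS-catalog flag is recorded as annotation
only. The package ships small synthetic emulation tables; callers may point
the loader at full database exports with the same headers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

MGI_CATEGORIES = frozenset(
    {"cardiovascular", "adipose", "metabolism", "endocrine/exocrine", "liver"}
)
GLGC_TRAITS = ("tc_p", "tg_p", "ldl_p", "hdl_p")
SOURCES = ("glgc", "cardiogram", "mgi", "gwas_catalog")


@dataclass
class EvidenceTable:
    """Per-gene evidence joined from the four sources (keys case-folded)."""

    glgc: dict[str, dict[str, float]] = field(default_factory=dict)
    cardiogram: set[str] = field(default_factory=set)
    mgi: dict[str, set[str]] = field(default_factory=dict)
    gwas_catalog: set[str] = field(default_factory=set)

    def provenance(self, gene: str) -> dict[str, bool]:
        g = gene.casefold()
        return {
            "glgc": g in self.glgc,
            "cardiogram": g in self.cardiogram,
            "mgi": g in self.mgi,
            "gwas_catalog": g in self.gwas_catalog,
        }


def _read_tsv(path, required: tuple[str, ...]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return df


def packaged_evidence_dir() -> Path:
    """Directory of the bundled synthetic evidence tables."""
    return Path(resources.files("rarecascade") / "data" / "synthetic_evidence")


def load_evidence(directory: str | Path | None = None) -> EvidenceTable:
    """Load the four evidence TSVs from ``directory`` (default: the bundled
    synthetic tables). Duplicate gene rows: last wins, with a warning."""
    d = Path(directory) if directory is not None else packaged_evidence_dir()
    table = EvidenceTable()

    glgc = _read_tsv(d / "glgc.tsv", ("gene",))
    for row in glgc.to_dict("records"):
        g = str(row["gene"]).casefold()
        if g in table.glgc:
            logger.warning("glgc.tsv: duplicate gene %s, keeping last row", row["gene"])
        traits = {
            t: float(row[t])
            for t in GLGC_TRAITS
            if t in row and pd.notna(row[t])
        }
        bad = [t for t, p in traits.items() if not 0 < p <= 1]
        if bad:
            raise ValueError(f"glgc.tsv: p-value outside (0,1] for {row['gene']} {bad}")
        if traits:  # GLGC evidence means at least one trait p present
            table.glgc[g] = traits

    for row in _read_tsv(d / "cardiogram.tsv", ("gene",)).to_dict("records"):
        table.cardiogram.add(str(row["gene"]).casefold())

    mgi = _read_tsv(d / "mgi.tsv", ("gene", "category"))
    for row in mgi.to_dict("records"):
        cat = str(row["category"]).strip().lower()
        if cat not in MGI_CATEGORIES:
            raise ValueError(f"mgi.tsv: unknown category {row['category']!r}")
        table.mgi.setdefault(str(row["gene"]).casefold(), set()).add(cat)

    for row in _read_tsv(d / "gwas_catalog.tsv", ("gene",)).to_dict("records"):
        table.gwas_catalog.add(str(row["gene"]).casefold())
    return table


def evidence_filter(
    genes: list[str],
    table: EvidenceTable,
    require: tuple[str, ...] = ("glgc", "cardiogram", "mgi"),
) -> pd.DataFrame:
    """Keep genes with evidence in >= 1 of the required sources.

    Returns an order-preserving table of survivors with one boolean
    provenance column per source plus an ``all_four`` flag.
    """
    unknown = set(require) - set(SOURCES)
    if unknown:
        raise ValueError(f"unknown evidence sources {sorted(unknown)}")
    rows = []
    for gene in genes:
        prov = table.provenance(gene)
        if any(prov[s] for s in require):
            rows.append(
                {"gene": gene, **prov, "all_four": all(prov[s] for s in SOURCES)}
            )
    return pd.DataFrame(rows, columns=["gene", *SOURCES, "all_four"])
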