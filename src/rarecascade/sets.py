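"""Qualifying-SNV set construction.

Each rare variant (MAF strictly below the threshold) is classified into up
to five nested deleteriousness sets:

* ``nonsynonymous`` — missense, nonsense, splice-site or frameshift indel;
* ``polyphen``      — disruptive, or missense called damaging ("possibly" or
  "probably") by PolyPhen-2 HumDiv;
* ``broad``         — disruptive, or missense called deleterious by at least
  one of the five predictors (LRT, MutationTaster, PolyPhen-2 HumDiv,
  PolyPhen-2 HumVar, SIFT);
* ``strict``        — disruptive, or missense called deleterious by all five
  (a missing call counts as not deleterious);
* ``disruptive``    — nonsense, splice-site or frameshift indel only.

Nesting holds by construction: disruptive is contained in every other set,
strict in broad, polyphen in broad, and broad in nonsynonymous.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import pandas as pd

PREDICTORS = ("lrt", "mutationtaster", "polyphen_humdiv", "polyphen_humvar", "sift")

_DELETERIOUS_CALLS = {
    "deleterious",
    "damaging",
    "probably_damaging",
    "possibly_damaging",
    "d",
}
_TOLERATED_CALLS = {"tolerated", "benign", "neutral", "t"}
_MISSING_CALLS = {"", ".", "na", "nan", "none", "missing"}

DISRUPTIVE_CLASSES = frozenset({"nonsense", "splice", "frameshift_indel"})
NONSYNONYMOUS_CLASSES = DISRUPTIVE_CLASSES | {"missense"}
KNOWN_CLASSES = NONSYNONYMOUS_CLASSES | {"synonymous", "other"}


class SetLabel(str, enum.Enum):
    NONSYNONYMOUS = "nonsynonymous"
    POLYPHEN = "polyphen"
    BROAD = "broad"
    STRICT = "strict"
    DISRUPTIVE = "disruptive"


SET_ORDER = tuple(SetLabel)


def normalize_call(call) -> str:
    """Map a raw predictor call onto {deleterious, tolerated, missing}."""
    if call is None or (isinstance(call, float) and math.isnan(call)):
        return "missing"
    s = str(call).strip().lower().replace(" ", "_")
    if s in _DELETERIOUS_CALLS:
        return "deleterious"
    if s in _TOLERATED_CALLS:
        return "tolerated"
    if s in _MISSING_CALLS:
        return "missing"
    raise ValueError(f"unrecognised predictor call {call!r}")


@dataclass
class AnnotationRecord:
    """Gene, functional class, five predictor calls and MAF for one variant."""

    variant_id: str
    gene: str
    functional_class: str
    predictor_calls: dict[str, str]  # predictor -> deleterious/tolerated/missing
    maf: float

    @classmethod
    def from_row(cls, row) -> "AnnotationRecord":
        return cls(
            variant_id=row["variant_id"],
            gene=row["gene"],
            functional_class=str(row["functional_class"]).strip().lower(),
            predictor_calls={p: normalize_call(row.get(p)) for p in PREDICTORS},
            maf=float(row["maf"]),
        )


def classify_variant(a: AnnotationRecord) -> set[SetLabel]:
    """Pure classification of one annotated variant into its SNV sets."""
    fc = a.functional_class
    if fc not in KNOWN_CLASSES:
        raise ValueError(f"{a.variant_id}: unknown functional class {fc!r}")
    out: set[SetLabel] = set()
    disruptive = fc in DISRUPTIVE_CLASSES
    if fc in NONSYNONYMOUS_CLASSES:
        out.add(SetLabel.NONSYNONYMOUS)
    if disruptive:
        out.update(
            {SetLabel.DISRUPTIVE, SetLabel.POLYPHEN, SetLabel.BROAD, SetLabel.STRICT}
        )
    elif fc == "missense":
        calls = [a.predictor_calls.get(p, "missing") for p in PREDICTORS]
        if a.predictor_calls.get("polyphen_humdiv") == "deleterious":
            out.add(SetLabel.POLYPHEN)
        if any(c == "deleterious" for c in calls):
            out.add(SetLabel.BROAD)
        if all(c == "deleterious" for c in calls):
            out.add(SetLabel.STRICT)
    return out


def build_gene_sets(
    annotations: pd.DataFrame,
    retained_ids: set[str] | None = None,
    maf_threshold: float = 0.05,
) -> dict[tuple[str, SetLabel], list[str]]:
    """Group QC-retained rare qualifying variants by (gene, set).

    Only variants with MAF strictly below ``maf_threshold`` (and present in
    ``retained_ids``, when given) qualify. Cells without any qualifying
    variant are omitted.
    """
    ids = annotations["variant_id"]
    if ids.duplicated().any():
        dupes = sorted(ids[ids.duplicated()].unique())
        raise ValueError(f"duplicate variant ids in annotations: {dupes[:5]}")
    cells: dict[tuple[str, SetLabel], list[str]] = {}
    for row in annotations.to_dict("records"):
        if retained_ids is not None and row["variant_id"] not in retained_ids:
            continue
        rec = AnnotationRecord.from_row(row)
        if not rec.maf < maf_threshold:
            continue
        for label in classify_variant(rec):
            cells.setdefault((rec.gene, label), []).append(rec.variant_id)
    return cells


def gene_sets_frame(cells: dict[tuple[str, SetLabel], list[str]]) -> pd.DataFrame:
    """Long-format membership table (gene, set, variant_id)."""
    rows = [
        {"gene": g, "set": s.value, "variant_id": vid}
        for (g, s), vids in sorted(
            cells.items(), key=lambda kv: (kv[0][0], SET_ORDER.index(kv[0][1]))
        )
        for vid in vids
    ]
    return pd.DataFrame(rows, columns=["gene", "set", "variant_id"])
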