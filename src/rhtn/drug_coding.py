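"""The 14-class antihypertensive vocabulary and product-to-class mapping.

Prescribing records carry product identifiers; the analysis works at the
level of 14 pharmacological classes.  Fixed-dose combination products are
split into their constituent classes so a patient is attributed with
exposure to each ingredient.
"""

from __future__ import annotations

import enum
from pathlib import Path
from typing import Mapping

import pandas as pd


class DrugClass(str, enum.Enum):
    VASODILATOR = "vasodilator"
    CENTRALLY_ACTING = "centrally_acting"
    ADRENERGIC_BLOCKER = "adrenergic_blocker"
    ALPHA_BLOCKER = "alpha_blocker"
    ACE_INHIBITOR = "ace_inhibitor"
    ANGIOTENSIN_RECEPTOR_BLOCKER = "angiotensin_receptor_blocker"
    RENIN_INHIBITOR = "renin_inhibitor"
    THIAZIDE_DIURETIC = "thiazide_diuretic"
    LOOP_DIURETIC = "loop_diuretic"
    POTASSIUM_SPARING_DIURETIC = "potassium_sparing_diuretic"
    ALDOSTERONE_ANTAGONIST = "aldosterone_antagonist"
    BETA_BLOCKER = "beta_blocker"
    CALCIUM_CHANNEL_BLOCKER = "calcium_channel_blocker"
    OTHER = "other"


#: classes satisfying the "inclusive of a diuretic" requirement.  The four
#: diuretic-type classes; configurable because guidelines do not pin down
#: whether e.g. aldosterone antagonists qualify.
DIURETIC_CLASSES: frozenset[str] = frozenset(
    {
        DrugClass.THIAZIDE_DIURETIC.value,
        DrugClass.LOOP_DIURETIC.value,
        DrugClass.POTASSIUM_SPARING_DIURETIC.value,
        DrugClass.ALDOSTERONE_ANTAGONIST.value,
    }
)

ProductMap = Mapping[str, frozenset[str]]


class UnknownProductError(KeyError):
    def __init__(self, unknown: set[str]):
        self.unknown = sorted(unknown)
        super().__init__(
            f"{len(self.unknown)} product_id(s) not in the product map: "
            f"{self.unknown[:10]}"
        )


def load_product_map(path: str | Path) -> dict[str, frozenset[str]]:
    """Read ``product_map.csv`` (columns ``product_id, class1..classK``,
    variable width) into a product -> class-set mapping."""
    df = pd.read_csv(path, dtype=str)
    if "product_id" not in df.columns:
        raise ValueError("product_map: missing 'product_id' column")
    class_cols = [c for c in df.columns if c != "product_id"]
    valid = {c.value for c in DrugClass}
    out: dict[str, frozenset[str]] = {}
    for _, row in df.iterrows():
        classes = {row[c] for c in class_cols if isinstance(row[c], str) and row[c]}
        bad = classes - valid
        if bad:
            raise ValueError(f"product {row['product_id']}: unknown classes {sorted(bad)}")
        if not classes:
            raise ValueError(f"product {row['product_id']}: maps to no class")
        out[str(row["product_id"])] = frozenset(classes)
    return out


def expand_prescriptions(
    raw_scripts: pd.DataFrame,
    product_map: ProductMap,
    lenient: bool = False,
) -> pd.DataFrame:
    """Expand product-level scripts into one record per constituent class.

    ``raw_scripts`` needs columns ``patient_id, issue_date, product_id``
    and optionally ``days_supply``; the issue date and days' supply are
    copied to every constituent.  Unknown products raise
    :class:`UnknownProductError` unless ``lenient``, in which case the
    offending rows are dropped (count available via the returned frame's
    ``attrs['n_skipped_unknown']``).
    """
    required = {"patient_id", "issue_date", "product_id"}
    missing = required - set(raw_scripts.columns)
    if missing:
        raise ValueError(f"raw scripts missing column(s) {sorted(missing)}")

    known = raw_scripts["product_id"].astype(str).isin(product_map.keys())
    if not known.all():
        unknown = set(raw_scripts.loc[~known, "product_id"].astype(str))
        if not lenient:
            raise UnknownProductError(unknown)
    kept = raw_scripts[known].copy()

    classes = kept["product_id"].astype(str).map(
        lambda p: sorted(product_map[p])
    )
    out = kept.copy()
    out["drug_class"] = classes
    out = out.explode("drug_class", ignore_index=True)
    cols = ["patient_id", "issue_date", "drug_class"]
    if "days_supply" in out.columns:
        cols.append("days_supply")
    out = out[cols]
    out.attrs["n_skipped_unknown"] = int((~known).sum())
    return out
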