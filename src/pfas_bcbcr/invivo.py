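"""In vivo benchmark: 28-day rat study lowest effect levels (LELs).

A National Toxicology Program study dosed rats with seven PFAS and recorded,
per chemical and sex, lowest effect levels (mg/kg-day) for nine phenotypes
(organ weights, hematocrit, cholesterol, thyroid hormones) together with the
plasma concentration measured at the lowest LEL. The lowest LEL per
chemical/sex is the in vivo point of departure; its plasma concentration gives
an internal-dose anchor against which the in vitro set-level PODs are compared.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .chem_registry import SchemaError, ValidationError

__all__ = [
    "PHENOTYPES",
    "Sex",
    "InVivoRow",
    "load_invivo_table",
    "packaged_invivo_path",
    "lowest_lel",
    "invivo_intervals",
    "compare_invitro_invivo",
]

PHENOTYPES: tuple[str, ...] = (
    "liver_weight",
    "relative_liver_weight",
    "kidney_weight",
    "relative_kidney_weight",
    "decreased_hematocrit",
    "decreased_cholesterol",
    "decreased_t3",
    "decreased_free_t4",
    "decreased_total_t4",
)


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


@dataclass(frozen=True)
class InVivoRow:
    """One chemical x sex row: phenotype LELs (mg/kg-day) and the plasma
    concentration (ng/mL) measured at the lowest LEL dose."""

    name: str
    sex: Sex
    lels: Mapping[str, Optional[float]]
    plasma_at_lowest_lel: float

    def __post_init__(self) -> None:
        present = [v for v in self.lels.values() if v is not None]
        if not present:
            raise ValidationError(f"{self.name}/{self.sex.value}: no LEL reported")
        if any(v <= 0 for v in present):
            raise ValidationError(f"{self.name}/{self.sex.value}: LELs must be > 0")


def packaged_invivo_path() -> Path:
    """Path of the packaged 28-day rat study fixture."""
    return Path(__file__).parent / "data" / "ntp_invivo_table1.csv"


def load_invivo_table(path: str | Path | None = None) -> list[InVivoRow]:
    """Load the chemical/sex LEL table ("NA" marks untested/unaffected)."""
    path = packaged_invivo_path() if path is None else Path(path)
    rows: list[InVivoRow] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in ("name", "sex", "plasma_at_lowest_lel_ngml", *PHENOTYPES)
                   if c not in header]
        if missing:
            raise SchemaError(f"in vivo table missing column(s): {missing}")
        for row in reader:
            lels = {
                p: (None if row[p].strip().upper() == "NA" else float(row[p]))
                for p in PHENOTYPES
            }
            rows.append(
                InVivoRow(
                    name=row["name"].strip(),
                    sex=Sex(row["sex"].strip().lower()),
                    lels=lels,
                    plasma_at_lowest_lel=float(row["plasma_at_lowest_lel_ngml"]),
                )
            )
    return rows


def lowest_lel(row: InVivoRow) -> tuple[float, list[str]]:
    """Minimum reported LEL (mg/kg-day) and every phenotype attaining it."""
    present = {p: v for p, v in row.lels.items() if v is not None}
    low = min(present.values())
    attaining = [p for p in PHENOTYPES if present.get(p) == low]
    return low, attaining


def invivo_intervals(rows: Sequence[InVivoRow]) -> dict[str, tuple[float, float]]:
    """Per chemical, the [min, max] of male/female plasma-at-lowest-LEL (ng/mL)."""
    by_chem: dict[str, list[float]] = {}
    for r in rows:
        by_chem.setdefault(r.name, []).append(r.plasma_at_lowest_lel)
    return {name: (min(v), max(v)) for name, v in by_chem.items()}


def compare_invitro_invivo(
    set_pods_ngml: pd.DataFrame,
    rows: Sequence[InVivoRow],
) -> tuple[pd.DataFrame, int]:
    """Compare in vitro set-level PODs with the in vivo plasma interval.

    ``set_pods_ngml`` needs columns ``name`` (chemical abbreviation matching
    the in vivo table), ``assay_set`` and ``pod_ngml``. Each set-level POD is
    flagged ``below_range`` / ``in_range`` / ``above_range`` against the closed
    interval spanned by the male and female plasma concentrations at the
    lowest LEL. Returns the per-set table and the count of chemicals for which
    at least one in vitro POD falls inside the interval.
    """
    for col in ("name", "assay_set", "pod_ngml"):
        if col not in set_pods_ngml.columns:
            raise ValidationError(f"set POD table missing column {col!r}")
    intervals = invivo_intervals(rows)

    out_rows = []
    for _, r in set_pods_ngml.iterrows():
        if r["name"] not in intervals:
            continue
        lo, hi = intervals[r["name"]]
        pod = float(r["pod_ngml"])
        if pod < lo:
            flag = "below_range"
        elif pod > hi:
            flag = "above_range"
        else:  # closed interval: boundary counts as overlapping
            flag = "in_range"
        out_rows.append(
            {
                "name": r["name"],
                "assay_set": r["assay_set"],
                "pod_ngml": pod,
                "invivo_low_ngml": lo,
                "invivo_high_ngml": hi,
                "flag": flag,
            }
        )
    table = pd.DataFrame(
        out_rows,
        columns=["name", "assay_set", "pod_ngml", "invivo_low_ngml",
                 "invivo_high_ngml", "flag"],
    )
    if table.empty:
        return table, 0
    n_overlap = int(
        table.groupby("name")["flag"].apply(lambda f: (f == "in_range").any()).sum()
    )
    return table, n_overlap
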