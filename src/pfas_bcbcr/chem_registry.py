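"""Chemical identity, molecular weight, unit conversion, and PFAS chain length.

The registry holds one :class:`ChemicalRecord` per substance (keyed by DTXSID) and
provides the two pieces of chemistry the screening pipeline needs:

* molar <-> mass concentration conversion (1 uM = MW ng/mL), used to put in vitro
  points of departure on the same ng/mL scale as plasma concentrations, and
* the perfluorinated chain length — the maximum contiguous run of fully
  fluorinated carbons — used to organize biomonitoring results by structure.
"""

from __future__ import annotations

import csv
import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from ._atomic_weights import ATOMIC_WEIGHTS

__all__ = [
    "HalfLifeClass",
    "ChemicalRecord",
    "SchemaError",
    "ValidationError",
    "load_roster",
    "packaged_roster_path",
    "molecular_weight",
    "molar_to_mass",
    "mass_to_molar",
    "chain_length",
]


class SchemaError(ValueError):
    """An input table is missing required columns."""


class ValidationError(ValueError):
    """An input record violates a domain invariant."""


class HalfLifeClass(str, enum.Enum):
    """Predicted human plasma half-life class (QSAR bins)."""

    LT_HALF_DAY = "lt_half_day"
    LT_1_WEEK = "lt_1_week"
    LT_2_MONTHS = "lt_2_months"
    GT_2_MONTHS = "gt_2_months"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class ChemicalRecord:
    """One substance: identity, structure, and toxicokinetic annotations.

    ``rb2p_measured`` is an in vivo measured blood-to-plasma concentration ratio;
    ``rb2p_predicted`` an in vitro-derived prediction. When both are present the
    measured value takes precedence (see :meth:`effective_rb2p`).
    """

    dtxsid: str
    casrn: str
    name: str
    abbreviation: str
    formula: Optional[str] = None
    smiles: Optional[str] = None
    rb2p_predicted: Optional[float] = None
    rb2p_measured: Optional[float] = None
    halflife_class: HalfLifeClass = HalfLifeClass.UNKNOWN

    def __post_init__(self) -> None:
        if not self.dtxsid:
            raise ValidationError("dtxsid must be non-empty")
        for attr in ("rb2p_predicted", "rb2p_measured"):
            v = getattr(self, attr)
            if v is not None and v <= 0:
                raise ValidationError(f"{attr} must be > 0, got {v!r} for {self.dtxsid}")

    @property
    def mw(self) -> Optional[float]:
        """Molecular weight in g/mol computed from the formula, or None."""
        if not self.formula:
            return None
        return molecular_weight(self.formula)

    def effective_rb2p(self) -> tuple[Optional[float], str]:
        """Blood-to-plasma ratio and its provenance.

        Returns ``(ratio, source)`` where source is one of ``measured_in_vivo``,
        ``in_vitro_predicted`` or ``default`` (ratio None in the default case;
        the caller supplies the fallback value).
        """
        if self.rb2p_measured is not None:
            return self.rb2p_measured, "measured_in_vivo"
        if self.rb2p_predicted is not None:
            return self.rb2p_predicted, "in_vitro_predicted"
        return None, "default"


_ROSTER_REQUIRED = ("dtxsid", "casrn", "name", "abbreviation")


def packaged_roster_path() -> Path:
    """Path of the packaged 31-chemical roster fixture."""
    return Path(__file__).parent / "data" / "roster_table2.csv"


def load_roster(path: str | Path) -> list[ChemicalRecord]:
    """Load a chemical roster CSV.

    Required columns: dtxsid, casrn, name, abbreviation. Optional: formula,
    smiles, rb2p (predicted), rb2p_measured, halflife_class. Duplicate DTXSIDs
    are rejected.
    """
    records: list[ChemicalRecord] = []
    seen: set[str] = set()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in _ROSTER_REQUIRED if c not in header]
        if missing:
            raise SchemaError(f"roster is missing required column(s): {missing}")
        for row in reader:
            dtxsid = row["dtxsid"].strip()
            if dtxsid in seen:
                raise ValidationError(f"duplicate dtxsid in roster: {dtxsid}")
            seen.add(dtxsid)

            def opt(key: str) -> Optional[str]:
                v = (row.get(key) or "").strip()
                return v or None

            hl = opt("halflife_class")
            records.append(
                ChemicalRecord(
                    dtxsid=dtxsid,
                    casrn=row["casrn"].strip(),
                    name=row["name"].strip(),
                    abbreviation=row["abbreviation"].strip(),
                    formula=opt("formula"),
                    smiles=opt("smiles"),
                    rb2p_predicted=float(v) if (v := opt("rb2p")) else None,
                    rb2p_measured=float(v) if (v := opt("rb2p_measured")) else None,
                    halflife_class=HalfLifeClass(hl) if hl else HalfLifeClass.UNKNOWN,
                )
            )
    return records


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def molecular_weight(formula: str) -> float:
    """Molecular weight (g/mol) of a Hill-style molecular formula.

    Accepts plain element/count strings such as ``C8HF15O2``. Dot-separated
    components (salts, e.g. ``C8F15O2.H4N``) are summed.
    """
    total = 0.0
    for part in formula.replace("·", ".").split("."):
        part = part.strip()
        if not part:
            continue
        pos = 0
        for m in _FORMULA_TOKEN.finditer(part):
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {formula!r} at {part[pos:]!r}")
            pos = m.end()
            symbol, count = m.group(1), int(m.group(2) or 1)
            try:
                total += ATOMIC_WEIGHTS[symbol] * count
            except KeyError:
                raise ValueError(f"unknown element {symbol!r} in formula {formula!r}") from None
        if pos != len(part):
            raise ValueError(f"cannot parse formula {formula!r} at {part[pos:]!r}")
    if total == 0.0:
        raise ValueError(f"empty formula {formula!r}")
    return total


def molar_to_mass(conc_um: float, mw: float) -> float:
    """Convert a concentration in uM to ng/mL (1 uM = MW ng/mL)."""
    if conc_um < 0:
        raise ValueError(f"concentration must be >= 0, got {conc_um}")
    if mw <= 0:
        raise ValueError(f"molecular weight must be > 0, got {mw}")
    return conc_um * mw


def mass_to_molar(conc_ngml: float, mw: float) -> float:
    """Convert a concentration in ng/mL to uM; exact inverse of molar_to_mass."""
    if conc_ngml < 0:
        raise ValueError(f"concentration must be >= 0, got {conc_ngml}")
    if mw <= 0:
        raise ValueError(f"molecular weight must be > 0, got {mw}")
    return conc_ngml / mw


def chain_length(smiles: Optional[str]) -> Optional[int]:
    """Maximum contiguous count of fully fluorinated carbons in a structure.

    A carbon is fully fluorinated when it bears at least one fluorine and no
    hydrogens — every hydrogen position is fluorinated. Bonds to backbone
    heteroatoms (the sulfonate sulfur of a perfluoroalkane sulfonic acid, an
    ether oxygen) do not disqualify a carbon; a carbon with no fluorine at all
    (e.g. a carboxyl carbon) never counts. This gives the conventional counts
    for the common perfluoroalkyl acids: 7 for an 8-carbon carboxylic acid, 8
    for an 8-carbon sulfonic acid.

    The chain length is the longest simple path in the carbon-carbon adjacency
    graph restricted to qualifying carbons. Returns None (a missing marker,
    never 0) when no structure is available, and 0 when the structure has no
    qualifying carbon.
    """
    if smiles is None:
        return None
    from rdkit import Chem  # deferred: structure handling is optional elsewhere

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")

    qualifying: list[int] = []
    for atom in mol.GetAtoms():
        if atom.GetSymbol() != "C":
            continue
        if atom.GetTotalNumHs() > 0:
            continue
        n_f = sum(1 for nb in atom.GetNeighbors() if nb.GetSymbol() == "F")
        if n_f >= 1:
            qualifying.append(atom.GetIdx())

    if not qualifying:
        return 0

    qset = set(qualifying)
    adj: dict[int, list[int]] = {i: [] for i in qualifying}
    for bond in mol.GetBonds():
        a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if a in qset and b in qset:
            adj[a].append(b)
            adj[b].append(a)

    # Longest simple path by DFS; PFAS carbon skeletons are tiny, so exhaustive
    # search is cheap and handles branching deterministically.
    best = 0

    def dfs(node: int, visited: set[int], depth: int) -> None:
        nonlocal best
        best = max(best, depth)
        for nxt in adj[node]:
            if nxt not in visited:
                visited.add(nxt)
                dfs(nxt, visited, depth + 1)
                visited.remove(nxt)

    for start in qualifying:
        dfs(start, {start}, 1)
    return best


def roster_index(records: Iterable[ChemicalRecord]) -> dict[str, ChemicalRecord]:
    """Index a roster by DTXSID."""
    return {r.dtxsid: r for r in records}
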