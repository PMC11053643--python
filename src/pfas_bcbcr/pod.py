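"""In vitro point-of-departure (POD) aggregation.

Endpoint-level potencies (AC50 / BMC / LEL, in uM) from eight assay technology
sets are aggregated in two stages:

1. per assay set, active endpoint potencies collapse to a set-level POD — the
   lower 5th percentile of the active potency distribution for most
   technologies, or the minimum for technologies that define their POD that way
   (cell-proliferation impedance, phenotypic-profiling category BMCs, zebrafish
   endpoint BMCs);
2. per chemical, the chemical-level POD is the minimum over set-level PODs.

An assay set with no active endpoints gets a censoring sentinel of 1000 uM so
that downstream ratios remain computable but are flagged as lower bounds on
potency information, not real potencies. Developmental-neurotoxicity (DNT)
endpoints pass through curve-quality filters before aggregation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .chem_registry import ChemicalRecord, ValidationError, molar_to_mass

__all__ = [
    "Hitcall",
    "PotencyKind",
    "AggregationPolicy",
    "AssayEndpointResult",
    "AssaySetPOD",
    "ChemicalPOD",
    "PodConfig",
    "SENTINEL_POD_UM",
    "dnt_filter",
    "pod_set",
    "pod_chemical",
    "aggregate",
]

SENTINEL_POD_UM = 1000.0

#: Maximum tested concentration per technology (uM); metadata reported next to
#: censored PODs, never used in aggregation. 100 uM unless a technology tested
#: higher.
MAX_TESTED_CONC_UM: dict[str, float] = {
    "ACEA": 300.0,
    "ATG": 300.0,
    "Thyroid": 200.0,
}
DEFAULT_MAX_TESTED_CONC_UM = 100.0


class Hitcall(enum.IntEnum):
    INACTIVE = 0
    ACTIVE = 1
    UNDETERMINED = -1  # concentration series too short to call


class PotencyKind(str, enum.Enum):
    AC50 = "AC50"
    BMC = "BMC"
    LEL = "LEL"


class AggregationPolicy(str, enum.Enum):
    P5 = "P5"  # lower 5th percentile of active potencies
    MIN = "MIN"  # minimum active potency


#: technology prefix -> set-level aggregation rule
DEFAULT_POLICIES: dict[str, AggregationPolicy] = {
    "ACEA": AggregationPolicy.MIN,
    "HTPP": AggregationPolicy.MIN,
    "Zebrafish": AggregationPolicy.MIN,
    # ATG, BSK_*, DNT_*, HTTr_*, Thyroid_* use the default P5
}


@dataclass(frozen=True)
class PodConfig:
    """Aggregation policy configuration.

    ``percentile_method`` is any interpolation convention accepted by
    :func:`numpy.percentile` (default ``"linear"``, i.e. the common type-7
    convention of interpolating between order statistics).
    """

    policies: Mapping[str, AggregationPolicy] = field(
        default_factory=lambda: dict(DEFAULT_POLICIES)
    )
    sentinel_um: float = SENTINEL_POD_UM
    percentile: float = 5.0
    percentile_method: str = "linear"

    def policy_for(self, assay_set: str) -> AggregationPolicy:
        if assay_set in self.policies:
            return self.policies[assay_set]
        prefix = assay_set.split("_", 1)[0]
        return self.policies.get(prefix, AggregationPolicy.P5)


@dataclass(frozen=True)
class AssayEndpointResult:
    """One endpoint-level concentration-response result."""

    dtxsid: str
    assay_set: str
    endpoint_id: str
    hitcall: Hitcall
    potency_um: Optional[float] = None
    potency_kind: PotencyKind = PotencyKind.AC50
    caution_flags: int = 0
    model_top: Optional[float] = None
    cutoff: Optional[float] = None
    n_concs: Optional[int] = None
    min_conc_um: Optional[float] = None
    max_conc_um: Optional[float] = None

    def __post_init__(self) -> None:
        if self.hitcall == Hitcall.ACTIVE:
            if self.potency_um is None or self.potency_um <= 0:
                raise ValidationError(
                    f"active endpoint {self.endpoint_id} must carry a positive potency"
                )


@dataclass(frozen=True)
class AssaySetPOD:
    """Set-level POD for one chemical x assay technology."""

    dtxsid: str
    assay_set: str
    pod_um: float
    n_active: int
    censored: bool
    max_tested_conc_um: float = DEFAULT_MAX_TESTED_CONC_UM


@dataclass(frozen=True)
class ChemicalPOD:
    """Chemical-level POD: the minimum over set-level PODs."""

    dtxsid: str
    pod_um: float
    driving_set: str
    censored: bool  # True only when *every* contributing set was censored
    pod_ngml: Optional[float] = None


# --- DNT curve-quality filter ---------------------------------------------------

_DNT_PREFIXES = ("DNT_",)


def _is_dnt(assay_set: str) -> bool:
    return assay_set.startswith(_DNT_PREFIXES) or assay_set == "DNT"


def dnt_filter(result: AssayEndpointResult) -> AssayEndpointResult:
    """Demote low-confidence developmental-neurotoxicity curves to inactive.

    An endpoint from a DNT assay set is forced inactive (hitcall 0, potency
    cleared) when any of three criteria hold:

    1. the curve carries >= 3 caution flags;
    2. the curve is active with a model top <= 1.2 x cutoff and a fitted
       potency below the lowest tested concentration (a weak, extrapolated
       hit);
    3. the hitcall is undetermined (-1; fewer than four concentrations).

    Non-DNT records and curves meeting none of the criteria pass through
    unchanged. The filter is idempotent.
    """
    if not _is_dnt(result.assay_set):
        return result

    flagged = result.caution_flags >= 3
    weak_extrapolated = (
        result.hitcall == Hitcall.ACTIVE
        and result.model_top is not None
        and result.cutoff is not None
        and result.model_top <= 1.2 * result.cutoff
        and result.potency_um is not None
        and result.min_conc_um is not None
        and result.potency_um < result.min_conc_um
    )
    undetermined = result.hitcall == Hitcall.UNDETERMINED or (
        result.n_concs is not None and result.n_concs < 4
    )

    if flagged or weak_extrapolated or undetermined:
        return replace(result, hitcall=Hitcall.INACTIVE, potency_um=None)
    return result


# --- aggregation ----------------------------------------------------------------


def pod_set(
    results: Sequence[AssayEndpointResult],
    config: PodConfig = PodConfig(),
) -> AssaySetPOD:
    """Collapse one chemical x assay set's endpoints to a set-level POD.

    With no active endpoints the sentinel (default 1000 uM) is returned with
    ``censored=True``. Otherwise the configured policy applies: P5 takes the
    lower 5th percentile of active potencies, MIN their minimum.
    """
    if not results:
        raise ValidationError("pod_set needs at least one endpoint result")
    keys = {(r.dtxsid, r.assay_set) for r in results}
    if len(keys) > 1:
        raise ValidationError(f"pod_set received mixed chemical/assay-set input: {sorted(keys)}")
    dtxsid, assay_set = next(iter(keys))

    if _is_dnt(assay_set):
        results = [dnt_filter(r) for r in results]

    active = [r.potency_um for r in results if r.hitcall == Hitcall.ACTIVE]
    max_conc = max(
        (r.max_conc_um for r in results if r.max_conc_um is not None),
        default=MAX_TESTED_CONC_UM.get(assay_set.split("_", 1)[0], DEFAULT_MAX_TESTED_CONC_UM),
    )
    if not active:
        return AssaySetPOD(dtxsid, assay_set, config.sentinel_um, 0, True, max_conc)

    policy = config.policy_for(assay_set)
    if policy == AggregationPolicy.MIN:
        pod = min(active)
    else:
        pod = float(
            np.percentile(np.asarray(active, dtype=float), config.percentile,
                          method=config.percentile_method)
        )
    return AssaySetPOD(dtxsid, assay_set, pod, len(active), False, max_conc)


def pod_chemical(
    set_pods: Sequence[AssaySetPOD],
    chemical: Optional[ChemicalRecord] = None,
) -> ChemicalPOD:
    """Minimum over set-level PODs, with a deterministic lexicographic tie-break.

    ``censored`` is True only when every set was censored (the chemical showed
    no activity anywhere, so the sentinel is all we know). The ng/mL value is
    attached when the chemical's molecular weight is available.
    """
    if not set_pods:
        raise ValidationError("pod_chemical needs at least one set-level POD")
    dtxsids = {p.dtxsid for p in set_pods}
    if len(dtxsids) > 1:
        raise ValidationError(f"pod_chemical received multiple chemicals: {sorted(dtxsids)}")

    winner = min(set_pods, key=lambda p: (p.pod_um, p.assay_set))
    all_censored = all(p.censored for p in set_pods)

    pod_ngml = None
    if chemical is not None and chemical.mw is not None:
        pod_ngml = molar_to_mass(winner.pod_um, chemical.mw)
    return ChemicalPOD(
        dtxsid=next(iter(dtxsids)),
        pod_um=winner.pod_um,
        driving_set=winner.assay_set,
        censored=all_censored,
        pod_ngml=pod_ngml,
    )


def aggregate(
    results: Iterable[AssayEndpointResult],
    roster: Mapping[str, ChemicalRecord],
    config: PodConfig = PodConfig(),
) -> tuple[list[AssaySetPOD], list[ChemicalPOD]]:
    """Full two-stage aggregation over a mixed endpoint table."""
    by_key: dict[tuple[str, str], list[AssayEndpointResult]] = {}
    for r in results:
        by_key.setdefault((r.dtxsid, r.assay_set), []).append(r)

    set_pods = [pod_set(v, config) for v in by_key.values()]
    by_chem: dict[str, list[AssaySetPOD]] = {}
    for p in set_pods:
        by_chem.setdefault(p.dtxsid, []).append(p)
    chem_pods = [
        pod_chemical(v, roster.get(dtxsid)) for dtxsid, v in sorted(by_chem.items())
    ]
    return set_pods, chem_pods


# --- CSV ingest -----------------------------------------------------------------

def load_assay_results(path) -> list[AssayEndpointResult]:
    """Read an endpoint-level assay CSV.

    Columns: dtxsid, assay_set, endpoint_id, potency_um, potency_kind, hitcall,
    caution_flags, model_top, cutoff, n_concs, min_conc_um, max_conc_um.
    """
    import csv

    from .chem_registry import SchemaError

    required = ("dtxsid", "assay_set", "endpoint_id", "hitcall")
    out: list[AssayEndpointResult] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in required if c not in header]
        if missing:
            raise SchemaError(f"assay table missing required column(s): {missing}")
        for row in reader:
            def opt_float(key):
                v = (row.get(key) or "").strip()
                return float(v) if v and v.upper() != "NA" else None

            def opt_int(key, default=None):
                v = (row.get(key) or "").strip()
                return int(v) if v else default

            kind = (row.get("potency_kind") or "AC50").strip() or "AC50"
            out.append(
                AssayEndpointResult(
                    dtxsid=row["dtxsid"].strip(),
                    assay_set=row["assay_set"].strip(),
                    endpoint_id=row["endpoint_id"].strip(),
                    hitcall=Hitcall(int(row["hitcall"])),
                    potency_um=opt_float("potency_um"),
                    potency_kind=PotencyKind(kind),
                    caution_flags=opt_int("caution_flags", 0),
                    model_top=opt_float("model_top"),
                    cutoff=opt_float("cutoff"),
                    n_concs=opt_int("n_concs"),
                    min_conc_um=opt_float("min_conc_um"),
                    max_conc_um=opt_float("max_conc_um"),
                )
            )
    return out
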