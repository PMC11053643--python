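"""BCBCR: the Bioactive Concentration to Blood Concentration Ratio.

BCBCR = in vitro chemical-level POD (ng/mL) / measured plasma concentration
(ng/mL). It is a margin-of-exposure-style screening statistic: values below 1
mean measured human blood levels reach in vitro bioactive concentrations;
values below 100-1000 are a reasonable level of concern once the method's
uncertainty factors are stacked. One ratio is computed per chemical x study
population x summary metric, classified into threshold bands, and chemicals
are ranked by their minimum ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .biomonitoring import (
    Metric,
    MetricGroup,
    PlasmaRecord,
    PopulationClass,
    group_metric,
)
from .chem_registry import ChemicalRecord, HalfLifeClass, ValidationError
from .pod import ChemicalPOD

__all__ = [
    "DEFAULT_THRESHOLDS",
    "BCBCRResult",
    "compute_bcbcr",
    "compute_all",
    "classify",
    "band_label",
    "rank_chemicals",
    "results_frame",
    "headline_chemicals",
]

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS: tuple[float, ...] = (1.0, 100.0, 1000.0, 10000.0)
ABOVE_MAX = "above_max"


@dataclass(frozen=True)
class BCBCRResult:
    """One POD/plasma ratio with its provenance and classification flags."""

    dtxsid: str
    snaid: str
    metric: Metric
    metric_group: MetricGroup
    population_class: PopulationClass
    matrix: str
    plasma_ngml: float
    pod_ngml: float
    bcbcr: float
    censored: bool
    halflife_applicable: bool
    abbreviation: str = ""


def compute_bcbcr(
    plasma: PlasmaRecord,
    pod: ChemicalPOD,
    chemical: Optional[ChemicalRecord] = None,
) -> BCBCRResult:
    """Ratio of the chemical-level POD (ng/mL) to one plasma concentration.

    The censoring flag is inherited from the POD (a censored POD makes the
    ratio a statement about the absence of observed bioactivity up to the
    sentinel, not a real potency). ``halflife_applicable`` records whether the
    constant-blood-level assumption behind the statistic holds, i.e. the
    chemical's predicted half-life class is the longest bin (> 2 months).
    """
    if plasma.dtxsid != pod.dtxsid:
        raise ValidationError(
            f"chemical mismatch: plasma record {plasma.dtxsid} vs POD {pod.dtxsid}"
        )
    if pod.pod_ngml is None or pod.pod_ngml <= 0:
        raise ValidationError(f"POD for {pod.dtxsid} has no positive ng/mL value")
    if plasma.plasma_value <= 0:
        raise ZeroDivisionError(
            f"plasma concentration is {plasma.plasma_value}; BCBCR undefined"
        )
    applicable = (
        chemical is not None and chemical.halflife_class == HalfLifeClass.GT_2_MONTHS
    )
    return BCBCRResult(
        dtxsid=plasma.dtxsid,
        snaid=plasma.snaid,
        metric=plasma.metric,
        metric_group=group_metric(plasma.metric),
        population_class=plasma.population_class,
        matrix=plasma.matrix.value,
        plasma_ngml=plasma.plasma_value,
        pod_ngml=pod.pod_ngml,
        bcbcr=pod.pod_ngml / plasma.plasma_value,
        censored=pod.censored,
        halflife_applicable=applicable,
        abbreviation=chemical.abbreviation if chemical is not None else "",
    )


def compute_all(
    plasma_records: Sequence[PlasmaRecord],
    pods: Sequence[ChemicalPOD],
    roster: dict[str, ChemicalRecord],
) -> list[BCBCRResult]:
    """All chemical x population x metric ratios; zero-plasma records are
    skipped with a warning rather than failing the batch."""
    pod_by_chem = {p.dtxsid: p for p in pods}
    out: list[BCBCRResult] = []
    for rec in plasma_records:
        pod = pod_by_chem.get(rec.dtxsid)
        if pod is None or pod.pod_ngml is None:
            continue
        try:
            out.append(compute_bcbcr(rec, pod, roster.get(rec.dtxsid)))
        except ZeroDivisionError:
            logger.warning(
                "skipping %s/%s %s: zero plasma concentration",
                rec.snaid, rec.dtxsid, rec.metric.value,
            )
    return out


def band_label(threshold: Optional[float]) -> str:
    return ABOVE_MAX if threshold is None else f"<{threshold:g}"


def classify(
    bcbcr: float | BCBCRResult,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> str:
    """Band a ratio by the smallest threshold it is strictly below.

    With the default thresholds the bands are "<1", "<100", "<1000", "<10000"
    and "above_max". The comparison is strict, so a ratio of exactly 1.0 falls
    in "<100".
    """
    ts = list(thresholds)
    if not ts or any(t <= 0 for t in ts) or any(b <= a for a, b in zip(ts, ts[1:])):
        raise ValueError(f"thresholds must be positive and strictly increasing: {ts}")
    value = bcbcr.bcbcr if isinstance(bcbcr, BCBCRResult) else bcbcr
    for t in ts:
        if value < t:
            return band_label(t)
    return ABOVE_MAX


def results_frame(
    results: Sequence[BCBCRResult],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Long-format results table (one row per ratio) with band labels."""
    rows = [
        {
            "dtxsid": r.dtxsid,
            "abbreviation": r.abbreviation,
            "snaid": r.snaid,
            "population_class": r.population_class.value,
            "matrix": r.matrix,
            "metric": r.metric.value,
            "metric_group": r.metric_group.value,
            "plasma_ngml": r.plasma_ngml,
            "pod_ngml": r.pod_ngml,
            "bcbcr": r.bcbcr,
            "band": classify(r.bcbcr, thresholds),
            "censored": r.censored,
            "halflife_applicable": r.halflife_applicable,
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def rank_chemicals(
    results: Sequence[BCBCRResult],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Per-chemical ranking by minimum BCBCR, ascending.

    Columns: min_bcbcr, the population/metric driving it, per-band counts, and
    a ``pod_censored`` flag ("POD censored at max tested concentration") for
    chemicals whose POD is only a sentinel — they are retained, not dropped.
    """
    if not results:
        return pd.DataFrame(
            columns=["dtxsid", "abbreviation", "min_bcbcr", "driving_snaid",
                     "driving_population", "driving_metric", "band", "pod_censored"]
        )
    df = results_frame(results, thresholds)
    band_names = [band_label(t) for t in thresholds] + [ABOVE_MAX]

    rows = []
    for dtxsid, grp in df.groupby("dtxsid", sort=False):
        imin = grp["bcbcr"].idxmin()
        best = grp.loc[imin]
        row = {
            "dtxsid": dtxsid,
            "abbreviation": best["abbreviation"],
            "min_bcbcr": best["bcbcr"],
            "driving_snaid": best["snaid"],
            "driving_population": best["population_class"],
            "driving_metric": best["metric"],
            "band": best["band"],
            "pod_censored": bool(grp["censored"].any()),
        }
        counts = grp["band"].value_counts()
        for b in band_names:
            row[f"n_{b}"] = int(counts.get(b, 0))
        rows.append(row)
    out = pd.DataFrame(rows).sort_values("min_bcbcr", kind="mergesort", ignore_index=True)
    out.insert(0, "rank", range(1, len(out) + 1))
    return out


def headline_chemicals(
    results: Sequence[BCBCRResult], threshold: float = 1.0
) -> set[str]:
    """Abbreviations (or DTXSIDs) of chemicals with any BCBCR below threshold."""
    return {
        (r.abbreviation or r.dtxsid) for r in results if r.bcbcr < threshold
    }


def load_appendix(directory: str | Path) -> tuple[Path, Path]:
    """Locate user-supplied appendix tables for the full published analysis.

    The complete per-population biomonitoring values and per-chemical in vitro
    POD tables are distributed as a journal appendix, not with this package.
    To reproduce the published chemical-level results, place them at
    ``<directory>/biomonitoring.csv`` (ingest schema of
    :func:`pfas_bcbcr.biomonitoring.load_biomonitoring`) and
    ``<directory>/assay_results.csv`` (schema of
    :func:`pfas_bcbcr.pod.load_assay_results`).
    """
    directory = Path(directory)
    bio = directory / "biomonitoring.csv"
    assays = directory / "assay_results.csv"
    missing = [str(p) for p in (bio, assays) if not p.is_file()]
    if missing:
        raise FileNotFoundError(
            "appendix data not found: "
            + ", ".join(missing)
            + ". The published per-population biomonitoring and POD tables are "
            "journal appendix material and are not shipped with this package; "
            "see README 'Reproducing the published screen' for where to put them."
        )
    return bio, assays
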