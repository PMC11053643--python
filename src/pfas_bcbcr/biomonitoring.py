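"""Biomonitoring ingest, matrix-to-plasma conversion, metric grouping, and QC.

Human biomonitoring studies report population summary statistics (percentiles,
means, medians, extremes) of PFAS concentrations in whole blood, serum, plasma
or cord matrices. This module normalizes those heterogeneous records to a single
plasma-equivalent ng/mL scale:

* serum and plasma (and their cord variants) are taken as plasma directly;
* whole blood, cord blood and dried blood spots are divided by the chemical's
  blood-to-plasma concentration ratio (Rb2p), falling back to a default of 0.5
  when no measured or predicted ratio is available.

Values are never dropped or deduplicated; a QC pass flags high concentrations
for manual review against the source documents.
"""

from __future__ import annotations

import csv
import enum
import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .chem_registry import ChemicalRecord, SchemaError, ValidationError

__all__ = [
    "Matrix",
    "Metric",
    "MetricGroup",
    "PopulationClass",
    "Rb2pSource",
    "BiomonitoringRecord",
    "PlasmaRecord",
    "DEFAULT_RB2P",
    "QC_THRESHOLD_NGML",
    "normalize_metric",
    "group_metric",
    "to_plasma",
    "qc_flag",
    "load_biomonitoring",
]

logger = logging.getLogger(__name__)

DEFAULT_RB2P = 0.5
QC_THRESHOLD_NGML = 100.0


class PopulationClass(str, enum.Enum):
    EXPOSED = "exposed"
    GENERAL = "general"


class Matrix(str, enum.Enum):
    WHOLE_BLOOD = "whole_blood"
    SERUM = "serum"
    PLASMA = "plasma"
    CORD_BLOOD = "cord_blood"
    CORD_SERUM = "cord_serum"
    CORD_PLASMA = "cord_plasma"
    BLOOD_SPOT = "blood_spot"


#: Matrices converted with the blood-to-plasma ratio; the rest pass through.
BLOOD_LIKE = frozenset({Matrix.WHOLE_BLOOD, Matrix.CORD_BLOOD, Matrix.BLOOD_SPOT})


class Metric(str, enum.Enum):
    P5 = "p5"
    P10 = "p10"
    P25 = "p25"
    P50 = "p50"
    P75 = "p75"
    P90 = "p90"
    P95 = "p95"
    P98 = "p98"
    P99 = "p99"
    MAXIMUM = "maximum"
    MINIMUM = "minimum"
    MEAN = "mean"
    MEDIAN = "median"


class MetricGroup(str, enum.Enum):
    """Presentation strata for summary metrics (high to low)."""

    HIGH = "high"
    P75 = "p75"
    P50 = "p50"
    P25 = "p25"
    LOW = "low"


class Rb2pSource(str, enum.Enum):
    MEASURED_IN_VIVO = "measured_in_vivo"
    IN_VITRO_PREDICTED = "in_vitro_predicted"
    DEFAULT = "default"


@dataclass(frozen=True)
class BiomonitoringRecord:
    """One population-level summary concentration from one study data set."""

    snaid: str
    dtxsid: str
    matrix: Matrix
    metric: Metric
    value: float  # ng/mL
    population_class: PopulationClass = PopulationClass.GENERAL
    location: str = ""
    cohort: str = ""
    lod: Optional[float] = None
    loq: Optional[float] = None
    n_subjects: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.snaid:
            raise ValidationError("snaid must be non-empty")
        if self.value < 0:
            raise ValidationError(f"concentration must be >= 0, got {self.value}")


@dataclass(frozen=True)
class PlasmaRecord:
    """A biomonitoring record harmonized to a plasma-equivalent concentration."""

    record: BiomonitoringRecord
    plasma_value: float  # ng/mL
    conversion_factor: float
    rb2p_source: Rb2pSource
    qc_flagged: bool = False

    # convenience passthroughs used throughout the pipeline
    @property
    def snaid(self) -> str:
        return self.record.snaid

    @property
    def dtxsid(self) -> str:
        return self.record.dtxsid

    @property
    def metric(self) -> Metric:
        return self.record.metric

    @property
    def matrix(self) -> Matrix:
        return self.record.matrix

    @property
    def population_class(self) -> PopulationClass:
        return self.record.population_class


# --- metric label normalization -------------------------------------------------

_MEAN_LABELS = {"mean", "arithmetic mean", "geometric mean", "average"}

_METRIC_ALIASES: dict[str, Metric] = {
    "median": Metric.MEDIAN,
    "maximum": Metric.MAXIMUM,
    "max": Metric.MAXIMUM,
    "minimum": Metric.MINIMUM,
    "min": Metric.MINIMUM,
}
for _m in _MEAN_LABELS:
    _METRIC_ALIASES[_m] = Metric.MEAN
for _p in (5, 10, 25, 50, 75, 90, 95, 98, 99):
    _METRIC_ALIASES[f"p{_p}"] = Metric(f"p{_p}")
    _METRIC_ALIASES[f"{_p}th percentile"] = Metric(f"p{_p}")
    _METRIC_ALIASES[f"{_p}th %ile"] = Metric(f"p{_p}")
    _METRIC_ALIASES[f"percentile {_p}"] = Metric(f"p{_p}")


def normalize_metric(raw_label: str) -> Metric:
    """Map a study's metric spelling onto the canonical metric enum.

    All flavors of mean ("mean", "arithmetic mean", "geometric mean",
    "average") collapse to ``mean``; percentile spellings such as "50th
    percentile" or "P50" map to the matching percentile.
    """
    if not raw_label or not raw_label.strip():
        raise ValidationError("metric label must be non-empty")
    key = raw_label.strip().lower()
    try:
        return _METRIC_ALIASES[key]
    except KeyError:
        raise ValidationError(f"unrecognized concentration metric label: {raw_label!r}") from None


_METRIC_GROUP: dict[Metric, MetricGroup] = {
    Metric.P90: MetricGroup.HIGH,
    Metric.P95: MetricGroup.HIGH,
    Metric.P98: MetricGroup.HIGH,
    Metric.P99: MetricGroup.HIGH,
    Metric.MAXIMUM: MetricGroup.HIGH,
    Metric.P75: MetricGroup.P75,
    Metric.P50: MetricGroup.P50,
    Metric.MEAN: MetricGroup.P50,
    Metric.MEDIAN: MetricGroup.P50,
    Metric.P25: MetricGroup.P25,
    Metric.P5: MetricGroup.LOW,
    Metric.P10: MetricGroup.LOW,
    Metric.MINIMUM: MetricGroup.LOW,
}


def group_metric(metric: Metric) -> MetricGroup:
    """Band a metric into the High / 75th / 50th / 25th / Low strata."""
    return _METRIC_GROUP[metric]


# --- matrix conversion ----------------------------------------------------------


def to_plasma(
    record: BiomonitoringRecord,
    chemical: Optional[ChemicalRecord] = None,
    default_rb2p: float = DEFAULT_RB2P,
) -> PlasmaRecord:
    """Convert one biomonitoring record to a plasma-equivalent concentration.

    Serum/plasma matrices (and cord serum/plasma) pass through with factor 1.
    Blood-like matrices are divided by the blood-to-plasma ratio: a measured in
    vivo ratio when available, else an in vitro-derived prediction, else
    ``default_rb2p``.
    """
    if record.matrix not in BLOOD_LIKE:
        return PlasmaRecord(record, record.value, 1.0, _passthrough_source(chemical))

    rb2p, source = (None, "default") if chemical is None else chemical.effective_rb2p()
    if rb2p is None:
        rb2p, source = default_rb2p, "default"
    if rb2p <= 0:
        raise ValidationError(f"blood-to-plasma ratio must be > 0, got {rb2p}")
    factor = 1.0 / rb2p
    return PlasmaRecord(record, record.value * factor, factor, Rb2pSource(source))


def _passthrough_source(chemical: Optional[ChemicalRecord]) -> Rb2pSource:
    # factor-1 matrices: record where a ratio *would* have come from, for the log
    if chemical is None:
        return Rb2pSource.DEFAULT
    _, source = chemical.effective_rb2p()
    return Rb2pSource(source)


def qc_flag(
    records: Sequence[PlasmaRecord],
    threshold: float = QC_THRESHOLD_NGML,
) -> list[PlasmaRecord]:
    """Return the records whose plasma value strictly exceeds ``threshold``.

    Flagged copies are returned for manual review; the input is not mutated and
    nothing is dropped.
    """
    if threshold <= 0:
        raise ValueError(f"QC threshold must be > 0, got {threshold}")
    return [replace(r, qc_flagged=True) for r in records if r.plasma_value > threshold]


# --- CSV ingest -----------------------------------------------------------------

_BIOMON_REQUIRED = ("snaid", "dtxsid", "matrix", "metric", "value")

#: accepted unit spellings -> multiplicative factor to ng/mL
_UNIT_FACTORS = {
    "ng/ml": 1.0,
    "ug/l": 1.0,
    "µg/l": 1.0,
    "μg/l": 1.0,
    "ppb": 1.0,
    "ug/ml": 1000.0,
    "µg/ml": 1000.0,
    "μg/ml": 1000.0,
    "ng/l": 1e-3,
    "": 1.0,  # assumed already ng/mL
}


def load_biomonitoring(path: str | Path) -> list[BiomonitoringRecord]:
    """Load long-format biomonitoring summary records from CSV.

    Expected columns: snaid, dtxsid, location, cohort, population_class,
    matrix, metric, value, unit, lod, loq, n_subjects (location/cohort/
    population_class/unit/lod/loq/n_subjects optional). Concentrations are
    normalized to ng/mL; metric labels are normalized via
    :func:`normalize_metric`. Non-numeric values (e.g. "<LOD") are rejected
    with a warning rather than imputed.
    """
    out: list[BiomonitoringRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in _BIOMON_REQUIRED if c not in header]
        if missing:
            raise SchemaError(f"biomonitoring table missing required column(s): {missing}")
        for i, row in enumerate(reader, start=2):
            raw_value = (row["value"] or "").strip()
            try:
                value = float(raw_value)
            except ValueError:
                warnings.warn(
                    f"row {i}: non-numeric concentration {raw_value!r} rejected "
                    "(censored values are not imputed)",
                    stacklevel=2,
                )
                continue
            unit = (row.get("unit") or "").strip().lower()
            try:
                value *= _UNIT_FACTORS[unit]
            except KeyError:
                raise ValidationError(f"row {i}: unrecognized concentration unit {unit!r}") from None

            pop_raw = (row.get("population_class") or "").strip().lower()
            if pop_raw:
                population = PopulationClass(pop_raw)
            else:
                logger.warning("row %d: population_class missing; defaulting to general", i)
                population = PopulationClass.GENERAL

            def opt_float(key: str) -> Optional[float]:
                v = (row.get(key) or "").strip()
                return float(v) if v else None

            n_subj = (row.get("n_subjects") or "").strip()
            out.append(
                BiomonitoringRecord(
                    snaid=row["snaid"].strip(),
                    dtxsid=row["dtxsid"].strip(),
                    location=(row.get("location") or "").strip(),
                    cohort=(row.get("cohort") or "").strip(),
                    population_class=population,
                    matrix=Matrix(row["matrix"].strip().lower()),
                    metric=normalize_metric(row["metric"]),
                    value=value,
                    lod=opt_float("lod"),
                    loq=opt_float("loq"),
                    n_subjects=int(n_subj) if n_subj else None,
                )
            )
    return out


def convert_all(
    records: Iterable[BiomonitoringRecord],
    roster: dict[str, ChemicalRecord],
    default_rb2p: float = DEFAULT_RB2P,
) -> list[PlasmaRecord]:
    """Convert every record (counts conserved; duplicates retained by design)."""
    out = []
    for rec in records:
        chem = roster.get(rec.dtxsid)
        plasma = to_plasma(rec, chem, default_rb2p=default_rb2p)
        if plasma.conversion_factor != 1.0:
            logger.info(
                "%s/%s: %s -> plasma with factor %.4g (%s)",
                rec.snaid, rec.dtxsid, rec.matrix.value,
                plasma.conversion_factor, plasma.rb2p_source.value,
            )
        out.append(plasma)
    return out
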