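"""Synthetic biomonitoring, assay, and roster inputs with known ground truth.

Real inputs to the screen are (a) population *summary statistics* of blood
PFAS concentrations and (b) endpoint-level in vitro potencies. The generator
emulates both from known truths so every pipeline stage is testable:

* plasma concentrations in a population are log-normal — the standard working
  model for biomonitoring data of chemicals with stable blood levels — with a
  chosen geometric mean (gm) and geometric standard deviation (gsd). A
  population reported in a blood-like matrix is converted subject-by-subject
  to the blood scale with the true blood-to-plasma ratio before summarizing,
  so the pipeline's inverse conversion must recover the plasma summaries
  exactly;
* endpoint potencies for an assay set scatter log-normally above/around a true
  set-level POD, placed so the set's aggregation statistic (lower 5th
  percentile, or the minimum for MIN-policy technologies) equals the truth in
  expectation (exactly, at zero noise);
* developmental-neurotoxicity sets additionally receive low-confidence decoy
  curves (heavily flagged, weak-and-extrapolated, or undetermined) at known
  rates and at potencies *below* the truth, so the curve-quality filter is
  load-bearing: skipping it corrupts the recovered POD.

One global seed fans out to per-spec seeds by stable hashing, so adding a
population or assay block does not perturb the draws of the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .biomonitoring import (
    BLOOD_LIKE,
    BiomonitoringRecord,
    Matrix,
    Metric,
    PopulationClass,
)
from .chem_registry import ChemicalRecord, ValidationError
from .pod import (
    AggregationPolicy,
    AssayEndpointResult,
    Hitcall,
    PodConfig,
    PotencyKind,
)

__all__ = [
    "PopulationSpec",
    "Scenario",
    "stable_seed",
    "simulate_population",
    "simulate_assays",
    "simulate_scenario",
    "default_scenario",
]

#: z-score of the lower 5th percentile of a standard normal
_Z05 = -1.6448536269514722

#: metrics emitted for every simulated population, with their quantile (None =
#: moment-based)
_METRIC_QUANTILES: dict[Metric, Optional[float]] = {
    Metric.MINIMUM: 0.0,
    Metric.P5: 0.05,
    Metric.P10: 0.10,
    Metric.P25: 0.25,
    Metric.P50: 0.50,
    Metric.MEDIAN: 0.50,
    Metric.P75: 0.75,
    Metric.P90: 0.90,
    Metric.P95: 0.95,
    Metric.P98: 0.98,
    Metric.P99: 0.99,
    Metric.MAXIMUM: 1.0,
    Metric.MEAN: None,
}


def stable_seed(global_seed: int, *parts: object) -> int:
    """Deterministic sub-seed < 2**31 from a global seed and a label tuple."""
    label = ":".join(str(p) for p in (global_seed, *parts))
    return zlib.crc32(label.encode()) & 0x7FFFFFFF


@dataclass(frozen=True)
class PopulationSpec:
    """Ground truth for one simulated study population."""

    snaid: str
    dtxsid: str
    gm: float  # geometric mean plasma concentration, ng/mL
    gsd: float  # geometric standard deviation (dimensionless, > 1)
    n_subjects: int = 100
    matrix: Matrix = Matrix.SERUM
    population_class: PopulationClass = PopulationClass.GENERAL
    lod: float = 0.01  # ng/mL
    true_rb2p: float = 0.5  # used only when matrix is blood-like

    def __post_init__(self) -> None:
        if self.gm <= 0:
            raise ValidationError("gm must be > 0")
        if self.gsd <= 1:
            raise ValidationError("gsd must be > 1 (use e.g. 1.0001 for near-degenerate)")
        if self.n_subjects < 5:
            raise ValidationError("n_subjects must be >= 5")
        if self.true_rb2p <= 0:
            raise ValidationError("true_rb2p must be > 0")


def simulate_population(spec: PopulationSpec, seed: int) -> list[BiomonitoringRecord]:
    """Draw one population and report it as summary-metric records.

    Plasma values are LogNormal(ln gm, ln gsd). For blood-like matrices the
    individual values are multiplied by the true blood-to-plasma ratio before
    summarizing (blood = plasma x Rb2p). One record per metric is emitted.
    """
    rng = np.random.default_rng(stable_seed(seed, "pop", spec.snaid, spec.dtxsid))
    plasma = rng.lognormal(mean=np.log(spec.gm), sigma=np.log(spec.gsd),
                           size=spec.n_subjects)
    values = plasma * spec.true_rb2p if spec.matrix in BLOOD_LIKE else plasma

    records = []
    for metric, q in _METRIC_QUANTILES.items():
        v = float(np.mean(values)) if q is None else float(np.quantile(values, q))
        records.append(
            BiomonitoringRecord(
                snaid=spec.snaid,
                dtxsid=spec.dtxsid,
                matrix=spec.matrix,
                metric=metric,
                value=v,
                population_class=spec.population_class,
                lod=spec.lod,
                n_subjects=spec.n_subjects,
            )
        )
    return records


#: per decoy kind, how many low-confidence DNT curves are injected per set
DNT_DECOYS_PER_CRITERION = 2


def simulate_assays(
    dtxsid: str,
    true_pods: Mapping[str, Optional[float]],
    noise: float = 0.0,
    seed: int = 0,
    n_endpoints: int = 20,
    config: PodConfig = PodConfig(),
) -> list[AssayEndpointResult]:
    """Endpoint-level results whose aggregation recovers ``true_pods``.

    ``true_pods`` maps assay-set name to a true set-level POD in uM, or None
    for an inactive set (all endpoints inactive; aggregation must return the
    sentinel). ``noise`` is the log-scale standard deviation of endpoint
    scatter: for P5-policy sets potencies are drawn log-normally with the
    distribution's 5th percentile pinned at the truth; for MIN-policy sets
    they are drawn at or above the truth so the sample minimum converges to it
    (and equals it exactly at zero noise).

    DNT sets get ``DNT_DECOYS_PER_CRITERION`` extra curves per filter
    criterion, each nominally active at one tenth of the true POD, which the
    curve-quality filter must remove.
    """
    if not true_pods:
        raise ValidationError("true_pods must be non-empty")
    out: list[AssayEndpointResult] = []
    for assay_set, truth in true_pods.items():
        rng = np.random.default_rng(stable_seed(seed, "assay", dtxsid, assay_set))
        if truth is None:
            for j in range(n_endpoints):
                out.append(
                    AssayEndpointResult(
                        dtxsid=dtxsid, assay_set=assay_set,
                        endpoint_id=f"{assay_set}_ep{j}",
                        hitcall=Hitcall.INACTIVE,
                    )
                )
            continue

        policy = config.policy_for(assay_set)
        z = rng.standard_normal(n_endpoints)
        if policy == AggregationPolicy.MIN:
            potencies = truth * np.exp(noise * np.abs(z))
        else:
            median = truth * np.exp(-_Z05 * noise)  # pins the P5 at the truth
            potencies = median * np.exp(noise * z)
        for j, p in enumerate(potencies):
            out.append(
                AssayEndpointResult(
                    dtxsid=dtxsid, assay_set=assay_set,
                    endpoint_id=f"{assay_set}_ep{j}",
                    hitcall=Hitcall.ACTIVE,
                    potency_um=float(p),
                    potency_kind=PotencyKind.AC50,
                    model_top=2.0, cutoff=1.0, n_concs=8,
                    min_conc_um=1e-3, max_conc_um=100.0,
                )
            )

        if assay_set.startswith("DNT"):
            decoy_potency = truth / 10.0
            for k in range(DNT_DECOYS_PER_CRITERION):
                out.append(  # criterion 1: >= 3 caution flags
                    AssayEndpointResult(
                        dtxsid=dtxsid, assay_set=assay_set,
                        endpoint_id=f"{assay_set}_decoy_flags{k}",
                        hitcall=Hitcall.ACTIVE, potency_um=decoy_potency,
                        caution_flags=3, model_top=2.0, cutoff=1.0,
                        n_concs=8, min_conc_um=1e-3, max_conc_um=100.0,
                    )
                )
                out.append(  # criterion 2: weak top, potency below tested range
                    AssayEndpointResult(
                        dtxsid=dtxsid, assay_set=assay_set,
                        endpoint_id=f"{assay_set}_decoy_weak{k}",
                        hitcall=Hitcall.ACTIVE, potency_um=decoy_potency,
                        model_top=1.1, cutoff=1.0, n_concs=8,
                        min_conc_um=truth, max_conc_um=100.0,
                    )
                )
                out.append(  # criterion 3: undetermined hitcall (short series)
                    AssayEndpointResult(
                        dtxsid=dtxsid, assay_set=assay_set,
                        endpoint_id=f"{assay_set}_decoy_short{k}",
                        hitcall=Hitcall.UNDETERMINED, n_concs=3,
                        min_conc_um=1e-3, max_conc_um=100.0,
                    )
                )
    return out


@dataclass(frozen=True)
class Scenario:
    """A full synthetic study: chemicals, populations, and true PODs."""

    chemicals: Sequence[ChemicalRecord]
    populations: Sequence[PopulationSpec]
    true_pods_um: Mapping[str, Mapping[str, Optional[float]]]  # dtxsid -> set -> uM
    assay_noise: float = 0.0
    n_endpoints: int = 20


def default_scenario() -> Scenario:
    """A three-chemical demonstration scenario.

    Geometric means are placed so the chemicals land in clearly separated
    BCBCR bands: one heavily exposed population drives a ratio below 1, one
    sits in the tens, and one chemical is inactive everywhere (censored POD).
    """
    from .chem_registry import load_roster, packaged_roster_path, roster_index

    roster = roster_index(load_roster(packaged_roster_path()))
    pfoa = roster["DTXSID8031865"]
    pfos = roster["DTXSID3031864"]
    pfbs = roster["DTXSID5030030"]

    populations = [
        PopulationSpec("SYN_PFOA_EXP", pfoa.dtxsid, gm=5000.0, gsd=2.5,
                       n_subjects=200, matrix=Matrix.SERUM,
                       population_class=PopulationClass.EXPOSED),
        PopulationSpec("SYN_PFOA_GEN", pfoa.dtxsid, gm=4.0, gsd=2.0,
                       n_subjects=500, matrix=Matrix.SERUM),
        PopulationSpec("SYN_PFOS_EXP", pfos.dtxsid, gm=800.0, gsd=2.5,
                       n_subjects=150, matrix=Matrix.WHOLE_BLOOD,
                       population_class=PopulationClass.EXPOSED),
        PopulationSpec("SYN_PFOS_GEN", pfos.dtxsid, gm=15.0, gsd=2.0,
                       n_subjects=500, matrix=Matrix.SERUM),
        PopulationSpec("SYN_PFBS_GEN", pfbs.dtxsid, gm=0.5, gsd=2.0,
                       n_subjects=300, matrix=Matrix.PLASMA),
    ]
    true_pods: dict[str, dict[str, Optional[float]]] = {
        pfoa.dtxsid: {"ATG": 8.0, "BSK_LPS": 3.0, "DNT_MEA": 12.0, "Zebrafish": 30.0},
        pfos.dtxsid: {"ATG": 2.0, "BSK_LPS": 6.0, "HTPP_U2OS": 10.0},
        pfbs.dtxsid: {"ATG": None, "BSK_LPS": None, "Zebrafish": None},
    }
    return Scenario(
        chemicals=[pfoa, pfos, pfbs],
        populations=populations,
        true_pods_um=true_pods,
        assay_noise=0.2,
    )


def simulate_scenario(
    scenario: Scenario, seed: int, out_dir: str | Path
) -> dict[str, Path]:
    """Write roster, biomonitoring, and assay CSVs for a scenario.

    Returns the three paths keyed ``roster`` / ``biomonitoring`` / ``assays``.
    Outputs are a pure function of (scenario, seed).
    """
    import csv

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "roster": out_dir / "roster.csv",
        "biomonitoring": out_dir / "biomonitoring.csv",
        "assays": out_dir / "assay_results.csv",
    }

    with open(paths["roster"], "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["dtxsid", "casrn", "name", "abbreviation", "formula",
                    "smiles", "rb2p", "rb2p_measured", "halflife_class"])
        for c in scenario.chemicals:
            w.writerow([c.dtxsid, c.casrn, c.name, c.abbreviation,
                        c.formula or "", c.smiles or "",
                        c.rb2p_predicted if c.rb2p_predicted is not None else "",
                        c.rb2p_measured if c.rb2p_measured is not None else "",
                        c.halflife_class.value])

    with open(paths["biomonitoring"], "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["snaid", "dtxsid", "location", "cohort", "population_class",
                    "matrix", "metric", "value", "unit", "lod", "loq", "n_subjects"])
        for spec in scenario.populations:
            for rec in simulate_population(spec, seed):
                w.writerow([rec.snaid, rec.dtxsid, "synthetic", "synthetic",
                            rec.population_class.value, rec.matrix.value,
                            rec.metric.value, repr(rec.value), "ng/mL",
                            rec.lod if rec.lod is not None else "", "",
                            rec.n_subjects or ""])

    with open(paths["assays"], "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["dtxsid", "assay_set", "endpoint_id", "potency_um",
                    "potency_kind", "hitcall", "caution_flags", "model_top",
                    "cutoff", "n_concs", "min_conc_um", "max_conc_um"])
        for c in scenario.chemicals:
            results = simulate_assays(
                c.dtxsid, scenario.true_pods_um[c.dtxsid],
                noise=scenario.assay_noise, seed=seed,
                n_endpoints=scenario.n_endpoints,
            )
            for r in results:
                w.writerow([r.dtxsid, r.assay_set, r.endpoint_id,
                            repr(r.potency_um) if r.potency_um is not None else "",
                            r.potency_kind.value, int(r.hitcall), r.caution_flags,
                            r.model_top if r.model_top is not None else "",
                            r.cutoff if r.cutoff is not None else "",
                            r.n_concs if r.n_concs is not None else "",
                            r.min_conc_um if r.min_conc_um is not None else "",
                            r.max_conc_um if r.max_conc_um is not None else ""])
    return paths
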