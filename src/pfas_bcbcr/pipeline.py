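"""End-to-end orchestration: inputs -> plasma harmonization -> PODs -> BCBCR.

The pipeline is a pure function of (input files, configuration, seed):
re-running with identical inputs yields byte-identical tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import bcbcr as bcbcr_mod
from . import biomonitoring as bio
from . import pod as pod_mod
from .chem_registry import ChemicalRecord, load_roster, roster_index

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ResultBundle", "run_pipeline", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run depends on."""

    roster_path: Path
    biomonitoring_path: Path
    assays_path: Path
    out_dir: Path
    thresholds: tuple[float, ...] = bcbcr_mod.DEFAULT_THRESHOLDS
    sentinel_um: float = pod_mod.SENTINEL_POD_UM
    percentile_method: str = "linear"
    default_rb2p: float = bio.DEFAULT_RB2P
    qc_threshold_ngml: float = bio.QC_THRESHOLD_NGML
    filter_short_halflife: bool = False
    make_figures: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        ts = self.thresholds
        if any(t <= 0 for t in ts) or any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError(f"thresholds must be positive and increasing: {ts}")


@dataclass
class ResultBundle:
    """Tables and file paths produced by one run."""

    results: pd.DataFrame
    ranking: pd.DataFrame
    qc_flags: pd.DataFrame
    set_pods: pd.DataFrame
    files: dict[str, Path] = field(default_factory=dict)


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Parse a plain ``key = value`` config file into a RunConfig.

    Recognized keys mirror the RunConfig fields; ``thresholds`` is a
    comma-separated list. Lines starting with '#' are ignored.
    """
    raw: dict[str, str] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"config line is not 'key = value': {line!r}")
        k, v = line.split("=", 1)
        raw[k.strip()] = v.strip()

    kwargs: dict = {}
    for key in ("roster_path", "biomonitoring_path", "assays_path", "out_dir"):
        if key in raw:
            kwargs[key] = Path(raw.pop(key))
    if "thresholds" in raw:
        kwargs["thresholds"] = tuple(float(x) for x in raw.pop("thresholds").split(","))
    for key, cast in (("sentinel_um", float), ("default_rb2p", float),
                      ("qc_threshold_ngml", float), ("seed", int),
                      ("percentile_method", str)):
        if key in raw:
            kwargs[key] = cast(raw.pop(key))
    for key in ("filter_short_halflife", "make_figures"):
        if key in raw:
            kwargs[key] = raw.pop(key).lower() in ("1", "true", "yes")
    if raw:
        raise ValueError(f"unrecognized config key(s): {sorted(raw)}")
    kwargs.update(overrides)
    return RunConfig(**kwargs)


def run_pipeline(config: RunConfig) -> ResultBundle:
    """Run the whole screen and write tables (and figures) to ``out_dir``.

    Outputs: ``bcbcr_results.csv`` (one row per chemical x population x
    metric), ``ranking.csv`` (chemicals ascending by minimum BCBCR),
    ``qc_flags.csv`` (plasma values above the QC threshold, for manual
    review), ``set_pods.csv``, and four diagnostic figures.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    roster_records = load_roster(config.roster_path)
    roster = roster_index(roster_records)

    records = bio.load_biomonitoring(config.biomonitoring_path)
    plasma = bio.convert_all(records, roster, default_rb2p=config.default_rb2p)
    if len(plasma) != len(records):
        raise AssertionError("record count changed during conversion")

    qc = bio.qc_flag(plasma, threshold=config.qc_threshold_ngml)

    pod_config = pod_mod.PodConfig(
        sentinel_um=config.sentinel_um,
        percentile_method=config.percentile_method,
    )
    assay_results = pod_mod.load_assay_results(config.assays_path)
    set_pods, chem_pods = pod_mod.aggregate(assay_results, roster, pod_config)

    all_results = bcbcr_mod.compute_all(plasma, chem_pods, roster)
    if config.filter_short_halflife:
        all_results = [r for r in all_results if r.halflife_applicable]

    results_df = bcbcr_mod.results_frame(all_results, config.thresholds)
    ranking = bcbcr_mod.rank_chemicals(all_results, config.thresholds)

    qc_df = pd.DataFrame(
        [
            {
                "snaid": r.snaid,
                "dtxsid": r.dtxsid,
                "matrix": r.matrix.value,
                "metric": r.metric.value,
                "plasma_ngml": r.plasma_value,
                "conversion_factor": r.conversion_factor,
                "rb2p_source": r.rb2p_source.value,
            }
            for r in qc
        ],
        columns=["snaid", "dtxsid", "matrix", "metric", "plasma_ngml",
                 "conversion_factor", "rb2p_source"],
    )
    set_pod_df = pd.DataFrame(
        [
            {
                "dtxsid": p.dtxsid,
                "abbreviation": roster[p.dtxsid].abbreviation if p.dtxsid in roster else "",
                "assay_set": p.assay_set,
                "pod_um": p.pod_um,
                "pod_ngml": (
                    p.pod_um * roster[p.dtxsid].mw
                    if p.dtxsid in roster and roster[p.dtxsid].mw is not None
                    else None
                ),
                "n_active": p.n_active,
                "censored": p.censored,
                "max_tested_conc_um": p.max_tested_conc_um,
            }
            for p in set_pods
        ]
    )

    files: dict[str, Path] = {}
    for name, df in (
        ("bcbcr_results", results_df),
        ("ranking", ranking),
        ("qc_flags", qc_df),
        ("set_pods", set_pod_df),
    ):
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False, float_format="%.10g")
        files[name] = path

    # in vitro vs in vivo comparison against the packaged 28-day rat study
    from . import invivo as invivo_mod

    invivo_rows = invivo_mod.load_invivo_table()
    pods_named = set_pod_df.dropna(subset=["pod_ngml"]).rename(
        columns={"abbreviation": "name"}
    )[["name", "assay_set", "pod_ngml"]]
    comparison_df, n_overlap = invivo_mod.compare_invitro_invivo(pods_named, invivo_rows)
    comp_path = out_dir / "invitro_invivo_comparison.csv"
    comparison_df.to_csv(comp_path, index=False, float_format="%.10g")
    files["invitro_invivo_comparison"] = comp_path
    logger.info("in vitro POD overlaps the in vivo interval for %d chemical(s)", n_overlap)

    if config.make_figures:
        from . import plots

        plasma_df = _plasma_frame(plasma, roster)
        files.update(plots.make_all_figures(
            plasma_df, results_df, set_pod_df, roster_records, out_dir,
            comparison_df=comparison_df,
        ))
    return ResultBundle(results_df, ranking, qc_df, set_pod_df, files)


def _plasma_frame(plasma: Sequence[bio.PlasmaRecord],
                  roster: dict[str, ChemicalRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "dtxsid": r.dtxsid,
                "abbreviation": roster[r.dtxsid].abbreviation if r.dtxsid in roster else r.dtxsid,
                "snaid": r.snaid,
                "population_class": r.population_class.value,
                "matrix": r.matrix.value,
                "metric": r.metric.value,
                "metric_group": bio.group_metric(r.metric).value,
                "plasma_ngml": r.plasma_value,
                "lod": r.record.lod,
                "loq": r.record.loq,
            }
            for r in plasma
        ]
    )
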