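"""Diagnostic figures for the screen.

All concentration axes are log10 (the data span orders of magnitude); exposed
populations are drawn orange and general populations blue throughout. The
figures are best-effort analogues for eyeballing a run — the tabular outputs
are the authoritative results.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .chem_registry import ChemicalRecord, chain_length

POP_COLORS = {"exposed": "tab:orange", "general": "tab:blue"}
_GROUP_ORDER = ["high", "p75", "p50", "p25", "low"]


def _pop_colors(series: pd.Series) -> list[str]:
    return [POP_COLORS.get(v, "gray") for v in series]


def plasma_by_metric_group(plasma_df: pd.DataFrame, set_pod_df: pd.DataFrame,
                           out: Path, max_chemicals: int = 4) -> Path:
    """Per-chemical plasma distributions by metric group, with set-POD lines."""
    rng = np.random.default_rng(0)
    chems = list(plasma_df["abbreviation"].unique())[:max_chemicals]
    fig, axes = plt.subplots(len(chems), 1, figsize=(7, 2.6 * max(len(chems), 1)),
                             squeeze=False)
    for ax, chem in zip(axes.ravel(), chems):
        sub = plasma_df[plasma_df["abbreviation"] == chem]
        positions = {g: i for i, g in enumerate(_GROUP_ORDER)}
        for _, row in sub.iterrows():
            y = positions[row["metric_group"]]
            ax.scatter(row["plasma_ngml"], y + rng.uniform(-0.2, 0.2),
                       s=12, alpha=0.7,
                       color=POP_COLORS.get(row["population_class"], "gray"))
        pods = set_pod_df[set_pod_df["abbreviation"] == chem]
        for _, p in pods.iterrows():
            if p["pod_ngml"] is not None and not pd.isna(p["pod_ngml"]) and not p["censored"]:
                ax.axvline(p["pod_ngml"], lw=1.2, alpha=0.8)
        ax.set_xscale("log")
        ax.set_yticks(range(len(_GROUP_ORDER)), _GROUP_ORDER)
        ax.set_title(chem)
        ax.set_xlabel("plasma concentration (ng/mL)")
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return out


def bcbcr_by_chemical(results_df: pd.DataFrame, out: Path) -> Path:
    """Strip plot of BCBCR per chemical on a log axis, ordered by minimum."""
    rng = np.random.default_rng(0)
    fig, ax = plt.subplots(figsize=(7, 0.35 * max(results_df["abbreviation"].nunique(), 4) + 2))
    order = (
        results_df.groupby("abbreviation")["bcbcr"].min().sort_values().index.tolist()
    )
    for i, chem in enumerate(order):
        sub = results_df[results_df["abbreviation"] == chem]
        jitter = rng.uniform(-0.18, 0.18, len(sub))
        ax.scatter(sub["bcbcr"], i + jitter, s=12, alpha=0.7,
                   color=_pop_colors(sub["population_class"]))
    ax.axvline(1.0, color="k", lw=1, ls="--")
    ax.axvline(100.0, color="k", lw=0.8, ls=":")
    ax.set_xscale("log")
    ax.set_yticks(range(len(order)), order)
    ax.set_xlabel("BCBCR (POD / plasma concentration)")
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return out


def plasma_by_chain_length(plasma_df: pd.DataFrame,
                           roster: Sequence[ChemicalRecord], out: Path) -> Path:
    """Plasma concentrations vs perfluorinated chain length.

    Chemicals without a structure have no chain length and are excluded, not
    plotted at zero.
    """
    lengths = {}
    for chem in roster:
        try:
            cl = chain_length(chem.smiles)
        except (ValueError, ImportError):
            cl = None
        if cl is not None:
            lengths[chem.dtxsid] = cl
    sub = plasma_df[plasma_df["dtxsid"].isin(lengths)].copy()
    rng = np.random.default_rng(0)
    fig, ax = plt.subplots(figsize=(7, 4))
    if not sub.empty:
        sub["chain_length"] = sub["dtxsid"].map(lengths)
        jitter = rng.uniform(-0.2, 0.2, len(sub))
        ax.scatter(sub["chain_length"] + jitter, sub["plasma_ngml"], s=12,
                   alpha=0.6, color=_pop_colors(sub["population_class"]))
        ax.set_yscale("log")
    ax.set_xlabel("perfluorinated chain length (contiguous CF carbons)")
    ax.set_ylabel("plasma concentration (ng/mL)")
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return out


def invitro_vs_invivo(comparison_df: pd.DataFrame, out: Path) -> Path:
    """Set-level in vitro PODs against the in vivo plasma-at-LEL interval."""
    fig, ax = plt.subplots(figsize=(7, 4))
    if not comparison_df.empty:
        chems = comparison_df["name"].unique().tolist()
        for i, chem in enumerate(chems):
            sub = comparison_df[comparison_df["name"] == chem]
            lo = sub["invivo_low_ngml"].iloc[0]
            hi = sub["invivo_high_ngml"].iloc[0]
            ax.plot([lo, lo], [i - 0.3, i + 0.3], color="red", lw=1.5)
            ax.plot([hi, hi], [i - 0.3, i + 0.3], color="black", lw=1.5)
            ax.scatter(sub["pod_ngml"], [i] * len(sub), s=18, alpha=0.8)
        ax.set_xscale("log")
        ax.set_yticks(range(len(chems)), chems)
    ax.set_xlabel("concentration (ng/mL)")
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return out


def make_all_figures(plasma_df: pd.DataFrame, results_df: pd.DataFrame,
                     set_pod_df: pd.DataFrame, roster: Sequence[ChemicalRecord],
                     out_dir: Path,
                     comparison_df: pd.DataFrame | None = None) -> dict[str, Path]:
    out_dir = Path(out_dir)
    figs = {
        "fig_plasma_by_metric_group": plasma_by_metric_group(
            plasma_df, set_pod_df, out_dir / "fig_plasma_by_metric_group.png"),
        "fig_bcbcr_by_chemical": bcbcr_by_chemical(
            results_df, out_dir / "fig_bcbcr_by_chemical.png"),
        "fig_plasma_by_chain_length": plasma_by_chain_length(
            plasma_df, roster, out_dir / "fig_plasma_by_chain_length.png"),
    }
    if comparison_df is None:
        comparison_df = pd.DataFrame(
            columns=["name", "assay_set", "pod_ngml",
                     "invivo_low_ngml", "invivo_high_ngml", "flag"])
    figs["fig_invitro_vs_invivo"] = invitro_vs_invivo(
        comparison_df, out_dir / "fig_invitro_vs_invivo.png")
    return figs
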