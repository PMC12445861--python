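"""End-to-end analysis chains tying the individual stages together.

``run_isotope_pipeline`` is the full carbon-budget analysis: plot reference
means -> enrichment factors -> full-mycoheterotroph baseline -> two-source
mixing model -> mixed-model group comparison with Tukey-Kramer contrasts,
plus a summary table (group, delta13C mean+/-SD, delta15N mean+/-SD,
%Cdf mean+/-SD) in the style isotope studies print.

``run_otu_pipeline`` is the metabarcoding chain: guild/singleton filtering
-> relative abundance -> dominance ranking.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .isotope import (
    EnrichmentRecord,
    FmhBaseline,
    IsotopeSample,
    MixingResult,
    PlotReference,
    enrichment_factors,
    fmh_baseline,
    group_summary,
    mixing_model,
    plot_reference_means,
    records_to_frame,
    samples_to_frame,
)
from .metabarcoding import OtuTable, dominance_summary, filter_otu_table, relative_abundance
from .stats import ContrastTable, LmmFit, fit_group_lmm, tukey_kramer

__all__ = ["IsotopeReport", "OtuReport", "run_isotope_pipeline",
           "run_otu_pipeline", "format_summary_table"]


@dataclass
class IsotopeReport:
    plot_refs: list[PlotReference]
    records: list[EnrichmentRecord]
    baseline: FmhBaseline
    mixing: list[MixingResult]
    summary: pd.DataFrame           # per-group means/SDs incl. %Cdf
    lmm_fits: dict[str, LmmFit]     # response -> fit
    contrasts: dict[str, ContrastTable]


@dataclass
class OtuReport:
    filtered: OtuTable
    abundance: pd.DataFrame
    dominance: pd.DataFrame


def run_isotope_pipeline(
    samples: Sequence[IsotopeSample],
    baseline_group: str,
    clamp: bool = False,
    responses: Iterable[str] = ("delta13C", "delta15N"),
) -> IsotopeReport:
    """Run the complete isotope analysis on a sample table.

    The baseline group (conventionally the albino phenotype) is included in
    the mixing results — it sits at 100 % by construction of the baseline.
    The linear mixed models are fitted on raw delta values with plot as the
    random effect; pass ``responses=("eps13C", "eps15N")`` to model
    enrichment factors instead.
    """
    refs = plot_reference_means(samples)
    records = enrichment_factors(samples, refs)
    baseline = fmh_baseline(records, baseline_group)
    targets = [r for r in records if r.role == "target"]
    mixing = mixing_model(targets, baseline.eps13C_mean, clamp=clamp)

    summary = group_summary(samples)
    pc = pd.DataFrame(
        {
            "pcdf_mean": {m.group: m.pcdf_mean for m in mixing},
            "pcdf_sd": {m.group: m.pcdf_sd for m in mixing},
        }
    )
    summary = summary.join(pc, how="left")

    frame = samples_to_frame(samples)
    eps_frame = records_to_frame(records)
    lmm_fits: dict[str, LmmFit] = {}
    contrasts: dict[str, ContrastTable] = {}
    for resp in responses:
        data = frame if resp in frame.columns else eps_frame
        fit = fit_group_lmm(data, response=resp)
        lmm_fits[resp] = fit
        contrasts[resp] = tukey_kramer(fit)

    return IsotopeReport(
        plot_refs=refs,
        records=records,
        baseline=baseline,
        mixing=mixing,
        summary=summary,
        lmm_fits=lmm_fits,
        contrasts=contrasts,
    )


def run_otu_pipeline(
    table: OtuTable,
    drop_singletons: bool = True,
    guild_whitelist: Iterable[str] | None = None,
) -> OtuReport:
    """Filter an OTU table and summarise per-group community composition."""
    from .metabarcoding import DEFAULT_GUILD_WHITELIST

    if guild_whitelist is None:
        guild_whitelist = DEFAULT_GUILD_WHITELIST
    filtered = filter_otu_table(
        table, drop_singletons=drop_singletons, guild_whitelist=guild_whitelist
    )
    return OtuReport(
        filtered=filtered,
        abundance=relative_abundance(filtered, by="group"),
        dominance=dominance_summary(filtered, by="group"),
    )


def _fmt(mean: float, sd, decimals: int) -> str:
    if mean is None or (isinstance(mean, float) and np.isnan(mean)):
        return ""
    if sd is None or (isinstance(sd, float) and np.isnan(sd)):
        return f"{mean:.{decimals}f}"
    return f"{mean:.{decimals}f} ± {sd:.{decimals}f}"


def format_summary_table(summary: pd.DataFrame) -> pd.DataFrame:
    """Human-readable per-group table: per-mil to 1 decimal, percent to 1.

    Singleton groups print a bare mean, mirroring the usual reporting style.
    """
    rows = {}
    for group, row in summary.iterrows():
        rows[group] = {
            "n": int(row["n"]),
            "delta13C": _fmt(row.get("delta13C_mean"), row.get("delta13C_sd"), 1),
            "delta15N": _fmt(row.get("delta15N_mean"), row.get("delta15N_sd"), 1),
            "pcdf": _fmt(row.get("pcdf_mean"), row.get("pcdf_sd"), 1),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "group"
    return out
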