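"""Core stable-isotope computations for quantifying partial mycoheterotrophy.

The analysis follows the standard trophic-ecology workflow for mixotrophic
plants:

1. δ values express a sample's isotope ratio relative to an international
   standard (VPDB for carbon, atmospheric N2 for nitrogen), in per mil:
   ``delta = (R_sample / R_standard - 1) * 1000``.
2. Enrichment factors normalise each plant against the autotrophic plants
   growing in the same 2 x 2 m plot: ``eps = delta_sample - mean(delta_ref)``,
   which removes microsite effects (light, soil, water) shared within a plot.
3. A full-mycoheterotroph (FMH) baseline is the mean 13C enrichment of a
   group assumed to derive 100 % of its carbon from fungi — here albino
   (chlorophyll-free) individuals, with protocorms as an alternative.
4. A linear two-source mixing model converts a plant's 13C enrichment into
   the percentage of fungal-derived carbon:
   ``%Cdf = eps13C / eps13C_FMH * 100``.

Only carbon enrichment is converted to a nutrient fraction; 15N enrichment
is computed and reported but has no accepted two-source interpretation.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InvalidInputError, MissingReferenceError

logger = logging.getLogger(__name__)

__all__ = [
    "IsotopeSample",
    "PlotReference",
    "EnrichmentRecord",
    "FmhBaseline",
    "MixingResult",
    "delta_value",
    "plot_reference_means",
    "enrichment_factors",
    "fmh_baseline",
    "mixing_model",
    "group_summary",
    "records_to_frame",
    "samples_to_frame",
]

#: Minimum number of autotrophic reference plants a plot should contain.
#: Fewer references still yield a baseline but trigger a warning.
MIN_REFS_PER_PLOT = 3


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IsotopeSample:
    """One plant individual's isotope measurement.

    Parameters
    ----------
    sample_id
        Unique identifier.
    group
        Taxon/phenotype label (e.g. ``"O_aff_fissus_scale"``,
        ``"O_nakaianus_albino"``, ``"reference"``).
    site_id, plot_id
        Sampling site and the 2 x 2 m plot within it.
    role
        ``"target"`` for the focal orchids, ``"reference"`` for co-occurring
        autotrophic plants.
    tissue
        ``"leaf"``, ``"rhizome"`` or ``"protocorm"``.
    delta13C, delta15N
        Per-mil values vs VPDB and atmospheric N2 respectively.
    """

    sample_id: str
    group: str
    site_id: str
    plot_id: str
    role: Literal["target", "reference"]
    delta13C: float
    delta15N: float
    tissue: Literal["leaf", "rhizome", "protocorm"] = "leaf"

    def __post_init__(self) -> None:
        if self.role not in ("target", "reference"):
            raise InvalidInputError(
                f"sample {self.sample_id!r}: role must be 'target' or 'reference', "
                f"got {self.role!r}"
            )
        if not (math.isfinite(self.delta13C) and math.isfinite(self.delta15N)):
            raise InvalidInputError(
                f"sample {self.sample_id!r}: delta values must be finite"
            )
        if self.role == "reference" and not self.plot_id:
            raise InvalidInputError(
                f"reference sample {self.sample_id!r} must carry a plot_id"
            )


@dataclass(frozen=True)
class PlotReference:
    """Mean δ of the autotrophic reference plants of one plot."""

    plot_id: str
    mean_delta13C: float
    mean_delta15N: float
    n_refs: int

    def __post_init__(self) -> None:
        if self.n_refs < 1:
            raise InvalidInputError(f"plot {self.plot_id!r}: n_refs must be >= 1")


@dataclass(frozen=True)
class EnrichmentRecord:
    """Per-individual enrichment factors relative to the plot reference mean."""

    sample_id: str
    group: str
    role: str
    plot_id: str
    site_id: str
    eps13C: float
    eps15N: float


@dataclass(frozen=True)
class FmhBaseline:
    """The full-mycoheterotroph 13C-enrichment baseline (per mil)."""

    group: str
    eps13C_mean: float
    eps13C_sd: float | None
    n: int


@dataclass(frozen=True)
class MixingResult:
    """Per-group percent fungal-derived carbon from the two-source model."""

    group: str
    pcdf_mean: float
    pcdf_sd: float | None  # absent when n = 1
    n: int
    eps_fmh_baseline: float
    clamped: bool = False

    def __post_init__(self) -> None:
        if self.n < 1:
            raise InvalidInputError("MixingResult requires n >= 1")
        if self.pcdf_sd is not None and self.pcdf_sd < 0:
            raise InvalidInputError("pcdf_sd must be >= 0")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def delta_value(r_sample: float, r_standard: float) -> float:
    """Per-mil δ value of an isotope ratio against a standard ratio.

    ``delta = (r_sample / r_standard - 1) * 1000``

    Raises
    ------
    InvalidInputError
        If either ratio is not a positive finite number.
    """
    if not (math.isfinite(r_sample) and r_sample > 0):
        raise InvalidInputError(f"r_sample must be positive and finite, got {r_sample}")
    if not (math.isfinite(r_standard) and r_standard > 0):
        raise InvalidInputError(
            f"r_standard must be positive and finite, got {r_standard}"
        )
    return (r_sample / r_standard - 1.0) * 1000.0


def plot_reference_means(samples: Sequence[IsotopeSample]) -> list[PlotReference]:
    """Arithmetic mean δ13C/δ15N of the reference plants of every plot.

    Every plot that contains at least one target must also contain at least
    one reference plant; otherwise a :class:`MissingReferenceError` names the
    offending plot. Plots with fewer than :data:`MIN_REFS_PER_PLOT` references
    produce a warning (the field sampling rule asks for at least three).
    """
    refs_by_plot: dict[str, list[IsotopeSample]] = {}
    plots_with_targets: set[str] = set()
    for s in samples:
        if s.role == "reference":
            refs_by_plot.setdefault(s.plot_id, []).append(s)
        else:
            plots_with_targets.add(s.plot_id)

    for plot_id in sorted(plots_with_targets):
        if plot_id not in refs_by_plot:
            raise MissingReferenceError(plot_id)

    out: list[PlotReference] = []
    for plot_id in sorted(refs_by_plot):
        refs = refs_by_plot[plot_id]
        if len(refs) < MIN_REFS_PER_PLOT:
            warnings.warn(
                f"plot {plot_id!r} has only {len(refs)} reference plant(s); "
                f"at least {MIN_REFS_PER_PLOT} are recommended",
                UserWarning,
                stacklevel=2,
            )
        out.append(
            PlotReference(
                plot_id=plot_id,
                mean_delta13C=float(np.mean([r.delta13C for r in refs])),
                mean_delta15N=float(np.mean([r.delta15N for r in refs])),
                n_refs=len(refs),
            )
        )
    return out


def enrichment_factors(
    samples: Sequence[IsotopeSample],
    plot_refs: Sequence[PlotReference] | None = None,
) -> list[EnrichmentRecord]:
    """Per-individual enrichment factors ``eps = delta_sample - plot mean``.

    Reference plants receive records too: their within-plot mean enrichment
    is exactly zero by construction, a useful pipeline invariant.

    Parameters
    ----------
    plot_refs
        Pre-computed plot means; computed from `samples` when omitted.
    """
    if plot_refs is None:
        plot_refs = plot_reference_means(samples)
    by_plot = {p.plot_id: p for p in plot_refs}

    records: list[EnrichmentRecord] = []
    for s in samples:
        ref = by_plot.get(s.plot_id)
        if ref is None:
            raise MissingReferenceError(
                s.plot_id, f"no reference mean for plot {s.plot_id!r} "
                f"(needed by sample {s.sample_id!r})"
            )
        records.append(
            EnrichmentRecord(
                sample_id=s.sample_id,
                group=s.group,
                role=s.role,
                plot_id=s.plot_id,
                site_id=s.site_id,
                eps13C=s.delta13C - ref.mean_delta13C,
                eps15N=s.delta15N - ref.mean_delta15N,
            )
        )
    return records


def fmh_baseline(
    records: Sequence[EnrichmentRecord], baseline_group: str
) -> FmhBaseline:
    """Mean 13C enrichment of the group taken as fully mycoheterotrophic.

    Each baseline individual is already normalised against its own plot's
    references, so pooling across plots (and sites) is legitimate. Albino
    individuals are the conventional choice; protocorms are an alternative.

    Raises
    ------
    ConfigurationError
        If no record belongs to `baseline_group`.
    """
    eps = [r.eps13C for r in records if r.group == baseline_group]
    if not eps:
        available = sorted({r.group for r in records})
        raise ConfigurationError(
            f"baseline group {baseline_group!r} has no records; "
            f"available groups: {available}"
        )
    sd = float(np.std(eps, ddof=1)) if len(eps) > 1 else None
    return FmhBaseline(
        group=baseline_group,
        eps13C_mean=float(np.mean(eps)),
        eps13C_sd=sd,
        n=len(eps),
    )


def mixing_model(
    records: Sequence[EnrichmentRecord],
    eps_fmh: float,
    clamp: bool = False,
    groups: Iterable[str] | None = None,
) -> list[MixingResult]:
    """Two-source linear mixing model: percent fungal-derived carbon.

    For each individual ``pcdf_i = eps13C_i / eps_fmh * 100``; per group the
    mean and sample SD (n-1 denominator) over individuals are reported.
    Values outside [0, 100] are biologically awkward but arise routinely from
    measurement noise; they are kept as-is unless ``clamp`` is set, in which
    case they are clamped to the interval and the group is flagged.

    Parameters
    ----------
    eps_fmh
        The full-mycoheterotroph 13C enrichment baseline, per mil (> 0).
    groups
        Restrict output to these groups (default: all groups present,
        in sorted order).
    """
    if not (math.isfinite(eps_fmh) and eps_fmh > 0):
        raise InvalidInputError(
            f"eps_fmh baseline must be positive and finite, got {eps_fmh}"
        )
    by_group: dict[str, list[float]] = {}
    for r in records:
        by_group.setdefault(r.group, []).append(r.eps13C / eps_fmh * 100.0)

    wanted = sorted(by_group) if groups is None else list(groups)
    results: list[MixingResult] = []
    for g in wanted:
        if g not in by_group:
            warnings.warn(f"group {g!r} has no records; omitted", UserWarning,
                          stacklevel=2)
            continue
        vals = np.asarray(by_group[g], dtype=float)
        clamped = False
        if clamp:
            out_of_range = (vals < 0.0) | (vals > 100.0)
            if out_of_range.any():
                clamped = True
                vals = np.clip(vals, 0.0, 100.0)
        results.append(
            MixingResult(
                group=g,
                pcdf_mean=float(vals.mean()),
                pcdf_sd=float(vals.std(ddof=1)) if vals.size > 1 else None,
                n=int(vals.size),
                eps_fmh_baseline=eps_fmh,
                clamped=clamped,
            )
        )
    return results


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def samples_to_frame(samples: Sequence[IsotopeSample]) -> pd.DataFrame:
    """Sample list as a tidy DataFrame (one row per individual)."""
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "group": [s.group for s in samples],
            "site_id": [s.site_id for s in samples],
            "plot_id": [s.plot_id for s in samples],
            "role": [s.role for s in samples],
            "tissue": [s.tissue for s in samples],
            "delta13C": [s.delta13C for s in samples],
            "delta15N": [s.delta15N for s in samples],
        }
    )


def records_to_frame(records: Sequence[EnrichmentRecord]) -> pd.DataFrame:
    """Enrichment records as a tidy DataFrame."""
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "group": [r.group for r in records],
            "role": [r.role for r in records],
            "site_id": [r.site_id for r in records],
            "plot_id": [r.plot_id for r in records],
            "eps13C": [r.eps13C for r in records],
            "eps15N": [r.eps15N for r in records],
        }
    )


def group_summary(
    data: Sequence[IsotopeSample] | Sequence[EnrichmentRecord] | pd.DataFrame,
    value_columns: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-group mean and sample SD (n-1 denominator) of isotope values.

    Singleton groups report the mean with SD as NaN, matching the convention
    of summary tables that print a bare mean for n = 1. Accepts sample or
    enrichment-record lists, or a tidy DataFrame with a ``group`` column.

    Returns a DataFrame indexed by group with columns
    ``<value>_mean``, ``<value>_sd`` for each value column, plus ``n``.
    """
    if not isinstance(data, pd.DataFrame):
        seq = list(data)
        if not seq:
            raise InvalidInputError("group_summary needs at least one observation")
        if isinstance(seq[0], IsotopeSample):
            data = samples_to_frame(seq)  # type: ignore[arg-type]
        else:
            data = records_to_frame(seq)  # type: ignore[arg-type]
    if value_columns is None:
        value_columns = [
            c for c in ("delta13C", "delta15N", "eps13C", "eps15N")
            if c in data.columns
        ]
    grouped = data.groupby("group", sort=True)
    out = pd.DataFrame({"n": grouped.size()})
    for col in value_columns:
        out[f"{col}_mean"] = grouped[col].mean()
        out[f"{col}_sd"] = grouped[col].std(ddof=1)  # NaN for n = 1
    empty = out.index[out["n"] == 0]
    if len(empty):
        warnings.warn(f"empty groups omitted: {list(empty)}", UserWarning,
                      stacklevel=2)
        out = out.drop(index=empty)
    return out
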