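"""OTU-table post-processing and a small greedy centroid clusterer.

Covers the downstream steps of a mycorrhizal metabarcoding analysis once
reads have been denoised: removing singleton OTUs, restricting the table to
trophic guilds of interest (typically the known orchid-mycorrhizal partner
guilds), computing relative abundances per sample or per plant group, and
ranking OTUs by dominance. A deterministic abundance-ranked greedy clusterer
at a fixed identity threshold (default 97 %) stands in for the upstream OTU
clustering step on small read sets.

Identity convention
-------------------
Clustering tools disagree on what "97 % identity" means. Here identity is
``matches / alignment_length`` over a global end-to-end alignment chosen to
maximise the number of matches and, among such alignments, minimise the
alignment length (end gaps count). This is implemented exactly via
Needleman-Wunsch scoring: match = B - 1, mismatch = -1, gap = -1 with
B = len(a) + len(b) + 1, so the optimal score is ``matches * B - length``
and both quantities can be recovered from it. Comparison against the
threshold is >=.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from Bio import Align

from .errors import InvalidInputError

logger = logging.getLogger(__name__)

__all__ = [
    "OtuTable",
    "ReadRecord",
    "ReadSet",
    "ClusterAssignment",
    "GUILDS",
    "filter_otu_table",
    "relative_abundance",
    "dominance_summary",
    "pairwise_identity",
    "greedy_cluster",
    "round_half_up",
]

#: Recognised trophic guild labels for OTU metadata.
GUILDS = ("orchid_mycorrhizal", "ectomycorrhizal", "saprotrophic", "other")

#: Default guild whitelist: guilds containing known orchid mycorrhizal
#: partners (the user may override; the literature-derived list is an input,
#: not hard-coded knowledge).
DEFAULT_GUILD_WHITELIST = frozenset(
    {"orchid_mycorrhizal", "ectomycorrhizal", "saprotrophic"}
)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class OtuTable:
    """Samples x OTUs read-count matrix with OTU and sample metadata.

    Attributes
    ----------
    counts
        DataFrame indexed by sample_id with one integer column per OTU.
    otu_meta
        DataFrame indexed by otu_id with columns ``genus``, ``family``,
        ``guild`` (one of :data:`GUILDS`).
    sample_meta
        DataFrame indexed by sample_id with a ``group`` column.
    """

    counts: pd.DataFrame
    otu_meta: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        c = self.counts
        if c.columns.duplicated().any():
            raise InvalidInputError("duplicate OTU ids in count matrix")
        arr = c.to_numpy()
        if arr.size and (arr < 0).any():
            raise InvalidInputError("counts must be non-negative")
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise InvalidInputError("counts must be integers")
            self.counts = c.astype(np.int64)
        missing = set(c.columns) - set(self.otu_meta.index)
        if missing:
            raise InvalidInputError(f"OTUs without metadata: {sorted(missing)}")
        bad = set(self.otu_meta["guild"]) - set(GUILDS)
        if bad:
            raise InvalidInputError(f"unknown guild labels: {sorted(bad)}")
        missing_s = set(c.index) - set(self.sample_meta.index)
        if missing_s:
            raise InvalidInputError(f"samples without metadata: {sorted(missing_s)}")

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    def subset_otus(self, otu_ids: Sequence[str]) -> "OtuTable":
        return OtuTable(
            counts=self.counts.loc[:, list(otu_ids)].copy(),
            otu_meta=self.otu_meta.loc[list(otu_ids)].copy(),
            sample_meta=self.sample_meta.copy(),
        )

    def group_totals(self) -> pd.DataFrame:
        """Counts pooled by sample group (groups x OTUs)."""
        groups = self.sample_meta.loc[self.counts.index, "group"]
        return self.counts.groupby(groups).sum()


@dataclass(frozen=True)
class ReadRecord:
    read_id: str
    sequence: str
    abundance: int = 1

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InvalidInputError(f"read {self.read_id!r}: empty sequence")
        if self.abundance < 1:
            raise InvalidInputError(f"read {self.read_id!r}: abundance must be >= 1")


@dataclass
class ReadSet:
    """Dereplicated reads with abundance annotations (vsearch ``;size=N``)."""

    records: list[ReadRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass
class ClusterAssignment:
    """Result of greedy centroid clustering.

    ``centroids`` lists centroid read ids in creation (processing) order;
    ``membership`` maps every read id to its centroid's read id.
    """

    centroids: list[str]
    membership: dict[str, str]
    threshold: float

    @property
    def n_clusters(self) -> int:
        return len(self.centroids)

    def members(self, centroid_id: str) -> list[str]:
        return sorted(r for r, c in self.membership.items() if c == centroid_id)


# ---------------------------------------------------------------------------
# table operations
# ---------------------------------------------------------------------------

def filter_otu_table(
    table: OtuTable,
    drop_singletons: bool = True,
    guild_whitelist: Iterable[str] | None = DEFAULT_GUILD_WHITELIST,
) -> OtuTable:
    """Remove singleton OTUs, then OTUs outside the guild whitelist.

    A singleton OTU has a total of exactly one read across all samples.
    Passing ``guild_whitelist=None`` skips guild filtering. Removed OTU ids
    are logged; an empty result warns but is returned.
    """
    keep = pd.Series(True, index=table.counts.columns)
    if drop_singletons:
        totals = table.counts.sum(axis=0)
        singles = totals == 1
        if singles.any():
            logger.info("removing singleton OTUs: %s",
                        sorted(totals.index[singles]))
        keep &= ~singles
    if guild_whitelist is not None:
        wl = set(guild_whitelist)
        guilds = table.otu_meta.loc[table.counts.columns, "guild"]
        out = ~guilds.isin(wl)
        if out.any():
            logger.info("removing OTUs outside guild whitelist %s: %s",
                        sorted(wl), sorted(guilds.index[out]))
        keep &= ~out.to_numpy()
    kept = [o for o in table.counts.columns if keep[o]]
    if not kept:
        warnings.warn("all OTUs were filtered out; returning an empty table",
                      UserWarning, stacklevel=2)
    return table.subset_otus(kept)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (3.005 -> 3.01), as used for printed percentages."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def relative_abundance(
    table: OtuTable,
    by: Literal["sample", "group"] = "group",
    ndigits: int | None = 2,
) -> pd.DataFrame:
    """Percent read share of each OTU per sample or per pooled group.

    Group percentages pool raw counts over the group's samples before
    dividing (not a mean of per-sample percentages). Units with zero total
    reads are excluded with a warning. Percentages are half-up rounded to
    ``ndigits`` decimals (``None`` disables rounding); per unit they sum to
    100 exactly before rounding.

    Returns a tidy DataFrame with columns ``unit``, ``otu_id``, ``reads``,
    ``percent``.
    """
    if by == "group":
        mat = table.group_totals()
    elif by == "sample":
        mat = table.counts
    else:
        raise InvalidInputError(f"by must be 'sample' or 'group', got {by!r}")

    totals = mat.sum(axis=1)
    zero = totals == 0
    if zero.any():
        warnings.warn(f"units with zero reads excluded: {sorted(mat.index[zero])}",
                      UserWarning, stacklevel=2)
        mat = mat.loc[~zero]
        totals = totals.loc[~zero]

    rows = []
    for unit in mat.index:
        for otu in mat.columns:
            reads = int(mat.loc[unit, otu])
            pct = reads / float(totals.loc[unit]) * 100.0
            if ndigits is not None:
                pct = round_half_up(pct, ndigits)
            rows.append({"unit": unit, "otu_id": otu, "reads": reads,
                         "percent": pct})
    return pd.DataFrame(rows)


def dominance_summary(
    table: OtuTable, by: Literal["sample", "group"] = "group"
) -> pd.DataFrame:
    """Rank OTUs by read share within each unit, with cumulative percentages.

    Intended for filtered tables; returns a tidy DataFrame with columns
    ``unit``, ``rank``, ``otu_id``, ``reads``, ``percent``,
    ``cumulative_percent`` (unrounded). Ties in reads break lexicographically
    by otu_id for determinism.
    """
    ra = relative_abundance(table, by=by, ndigits=None)
    out = []
    for unit, sub in ra.groupby("unit", sort=True):
        sub = sub.sort_values(["percent", "otu_id"],
                              ascending=[False, True]).reset_index(drop=True)
        cum = sub["percent"].cumsum()
        for rank, (row, c) in enumerate(zip(sub.itertuples(index=False), cum), 1):
            out.append({
                "unit": unit, "rank": rank, "otu_id": row.otu_id,
                "reads": row.reads, "percent": row.percent,
                "cumulative_percent": float(c),
            })
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# sequence identity and clustering
# ---------------------------------------------------------------------------

def _make_aligner(big: int) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = big - 1
    aligner.mismatch_score = -1
    # sets internal AND end gaps: a true end-to-end alignment
    aligner.gap_score = -1
    return aligner


def pairwise_identity(a: str, b: str) -> float:
    """Global end-to-end identity: matches / alignment length.

    The alignment maximises matches and, among those, minimises alignment
    length (see module docstring for the exact convention). Symmetric, and
    ``pairwise_identity(a, a) == 1.0`` for any non-empty ``a``.
    """
    if not a or not b:
        raise InvalidInputError("sequences must be non-empty")
    big = len(a) + len(b) + 1
    score = int(_make_aligner(big).score(a, b))
    # score = matches * big - alignment_length, 0 < length < big
    matches = score // big + 1
    length = matches * big - score
    return matches / length


def greedy_cluster(
    reads: ReadSet | Sequence[ReadRecord], threshold: float = 0.97
) -> ClusterAssignment:
    """Abundance-ranked greedy centroid clustering at an identity threshold.

    Reads are processed in decreasing abundance (ties broken lexicographically
    by read id, so the result is independent of input order). Each read joins
    the first existing centroid, in creation order, whose identity to it is
    >= ``threshold``; otherwise it founds a new centroid. The most abundant
    read of a cluster is therefore always its representative.
    """
    records = list(reads.records if isinstance(reads, ReadSet) else reads)
    if not records:
        raise InvalidInputError("read set is empty")
    if not (0.0 < threshold <= 1.0):
        raise InvalidInputError(f"threshold must be in (0, 1], got {threshold}")
    records.sort(key=lambda r: (-r.abundance, r.read_id))

    centroids: list[ReadRecord] = []
    membership: dict[str, str] = {}
    for rec in records:
        for cen in centroids:
            if pairwise_identity(rec.sequence, cen.sequence) >= threshold:
                membership[rec.read_id] = cen.read_id
                break
        else:
            centroids.append(rec)
            membership[rec.read_id] = rec.read_id
    return ClusterAssignment(
        centroids=[c.read_id for c in centroids],
        membership=membership,
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# FASTA helpers
# ---------------------------------------------------------------------------

_SIZE_RE = re.compile(r";size=(\d+)")


def parse_size_annotation(header: str) -> tuple[str, int]:
    """Split a dereplicated-FASTA header into (read_id, abundance).

    The abundance is taken from a ``;size=N`` annotation (1 when absent);
    the annotation is stripped from the returned id.
    """
    m = _SIZE_RE.search(header)
    size = int(m.group(1)) if m else 1
    read_id = _SIZE_RE.sub("", header).rstrip(";")
    return read_id, size
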