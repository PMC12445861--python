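"""Synthetic isotope datasets, OTU tables and read sets.

The generators emulate the field design the analysis assumes: 2 x 2 m plots
each holding at least three autotrophic reference plants, target orchids of
several taxon/phenotype groups with group-specific true fungal-carbon
fractions, Gaussian plot effects shared by all plants in a plot (this is
what plot-wise normalisation removes), and Gaussian residual noise on the
per-mil scale. OTU read counts are Dirichlet-multinomial with one or a few
strongly dominant OTUs per group, the pattern typical of orchid-mycorrhizal
communities.

Generative model per plant (carbon; nitrogen is analogous with a per-group
true 15N enrichment in place of the mixing term)::

    delta_ref    = ref_mean + plot_effect + N(0, ref_sd)
    delta_target = ref_mean + plot_effect + true_pcdf/100 * eps_fmh_true
                   + N(0, residual_sd)

Every generator is a pure function of its configuration (which includes the
seed): the same config yields byte-identical output. The generating truth is
returned alongside the data for parameter-recovery tests and is never used
by the analysis path.

Default values follow the study design this package targets: reference
plants at -34.4 +/- 0.6 per-mil delta13C (-4.5 +/- 0.5 delta15N), a
full-mycoheterotroph 13C enrichment of 8.4 per-mil, plot SD 1.0 per-mil,
residual SD 0.6 per-mil, 4 plots per site with 3 references each, and
groups spanning the autotrophy-mycoheterotrophy continuum (true %Cdf 0,
53, 65, 92 and a 100 % albino baseline).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InvalidInputError
from .isotope import IsotopeSample
from .metabarcoding import OtuTable, ReadRecord, ReadSet

__all__ = [
    "SiteConfig",
    "GroupConfig",
    "OtuDef",
    "OtuProfileConfig",
    "SyntheticConfig",
    "IsotopeTruth",
    "default_config",
    "gen_isotope_dataset",
    "gen_otu_table",
    "gen_read_set",
]

REFERENCE_GROUP = "reference"


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteConfig:
    """One sampling site: a set of plots sharing reference-plant parameters."""

    site_id: str
    n_plots: int = 4
    refs_per_plot: int = 3
    ref_mean_delta13C: float = -34.4   # per mil
    ref_sd: float = 0.6                # per mil, between references in a plot
    plot_sd: float = 1.0               # per mil, between plots
    residual_sd: float = 0.6           # per mil, target residual noise
    ref_mean_delta15N: float = -4.5
    ref_sd_15N: float = 0.5
    plot_sd_15N: float = 0.5
    residual_sd_15N: float = 0.3

    def __post_init__(self) -> None:
        if self.n_plots < 1 or self.refs_per_plot < 1:
            raise ConfigurationError(
                f"site {self.site_id!r}: n_plots and refs_per_plot must be >= 1"
            )
        for name in ("ref_sd", "plot_sd", "residual_sd",
                     "ref_sd_15N", "plot_sd_15N", "residual_sd_15N"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"site {self.site_id!r}: {name} must be >= 0")


@dataclass(frozen=True)
class GroupConfig:
    """A target group with its true fungal-carbon fraction."""

    name: str
    site_id: str
    n: int = 4
    true_pcdf: float = 0.0      # percent, may exceed 100 slightly
    true_eps15N: float = 0.0    # per mil
    tissue: str = "leaf"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigurationError(f"group {self.name!r}: n must be >= 1")
        if not (0.0 <= self.true_pcdf <= 120.0):
            raise ConfigurationError(
                f"group {self.name!r}: true_pcdf must be in [0, 120]"
            )


@dataclass(frozen=True)
class OtuDef:
    otu_id: str
    genus: str
    family: str
    guild: str


@dataclass(frozen=True)
class OtuProfileConfig:
    """Dirichlet-multinomial read-count model.

    ``group_alphas`` maps group name -> {otu_id: Dirichlet weight}; OTUs
    absent from a group's mapping get weight 0 (never observed there).
    """

    otus: tuple[OtuDef, ...]
    group_alphas: dict[str, dict[str, float]]
    n_samples_per_group: int = 3
    reads_per_sample: tuple[int, int] = (8_000, 12_000)

    def __post_init__(self) -> None:
        ids = {o.otu_id for o in self.otus}
        lo, hi = self.reads_per_sample
        if lo < 1 or hi < lo:
            raise ConfigurationError("reads_per_sample range must satisfy 1 <= lo <= hi")
        for g, alphas in self.group_alphas.items():
            unknown = set(alphas) - ids
            if unknown:
                raise ConfigurationError(
                    f"group {g!r} references undefined OTUs: {sorted(unknown)}"
                )
            if any(a <= 0 for a in alphas.values()):
                raise ConfigurationError(f"group {g!r}: Dirichlet weights must be > 0")


@dataclass(frozen=True)
class SyntheticConfig:
    """Full generative configuration; the seed is part of the config."""

    seed: int = 0
    sites: tuple[SiteConfig, ...] = ()
    groups: tuple[GroupConfig, ...] = ()
    eps_fmh_true: float = 8.4  # per mil, true full-mycoheterotroph enrichment
    otu_profile: OtuProfileConfig | None = None

    def __post_init__(self) -> None:
        site_ids = [s.site_id for s in self.sites]
        if len(set(site_ids)) != len(site_ids):
            raise ConfigurationError("duplicate site ids")
        for g in self.groups:
            if g.site_id not in site_ids:
                raise ConfigurationError(
                    f"group {g.name!r} references unknown site {g.site_id!r}"
                )
        if self.eps_fmh_true <= 0:
            raise ConfigurationError("eps_fmh_true must be > 0")

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return dataclasses.replace(self, seed=int(seed))

    def to_json(self, path=None) -> str:
        s = json.dumps(dataclasses.asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s

    @classmethod
    def from_json(cls, source: str) -> "SyntheticConfig":
        """Load from a JSON string or a path to a JSON file."""
        text = source
        if "{" not in source:
            with open(source) as fh:
                text = fh.read()
        d = json.loads(text)
        d["sites"] = tuple(SiteConfig(**s) for s in d.get("sites", ()))
        d["groups"] = tuple(GroupConfig(**g) for g in d.get("groups", ()))
        prof = d.get("otu_profile")
        if prof is not None:
            prof["otus"] = tuple(OtuDef(**o) for o in prof["otus"])
            prof["reads_per_sample"] = tuple(prof["reads_per_sample"])
            d["otu_profile"] = OtuProfileConfig(**prof)
        return cls(**d)


@dataclass(frozen=True)
class IsotopeTruth:
    """Generating truth emitted next to a synthetic dataset."""

    eps_fmh_true: float
    group_true_pcdf: dict[str, float]
    group_true_eps15N: dict[str, float]
    plot_effects_13C: dict[str, float]
    plot_effects_15N: dict[str, float]


def default_config(seed: int = 0) -> SyntheticConfig:
    """The default study-like configuration.

    Two sites of 4 plots x 3 references each; target groups spanning the
    mycoheterotrophy continuum with one individual per plot, including an
    albino group at 100 % that serves as the mixing-model baseline.
    """
    sites = (
        SiteConfig(site_id="hachijo"),
        SiteConfig(site_id="saitama"),
    )
    groups = (
        GroupConfig("autotroph_control", "hachijo", n=4, true_pcdf=0.0,
                    true_eps15N=0.0),
        GroupConfig("O_fissus", "hachijo", n=4, true_pcdf=53.0, true_eps15N=7.2),
        GroupConfig("O_aff_fissus_scale", "hachijo", n=4, true_pcdf=92.0,
                    true_eps15N=8.6),
        GroupConfig("O_nakaianus_green", "saitama", n=4, true_pcdf=65.0,
                    true_eps15N=5.6),
        GroupConfig("O_nakaianus_albino", "saitama", n=4, true_pcdf=100.0,
                    true_eps15N=6.3),
    )
    otus = (
        OtuDef("OTU1", "Ceratobasidium", "Ceratobasidiaceae", "orchid_mycorrhizal"),
        OtuDef("OTU2", "Ceratobasidium", "Ceratobasidiaceae", "orchid_mycorrhizal"),
        OtuDef("OTU3", "Ceratobasidium", "Ceratobasidiaceae", "orchid_mycorrhizal"),
        OtuDef("OTU4", "Russula", "Russulaceae", "ectomycorrhizal"),
        OtuDef("OTU5", "Sebacina", "Sebacinaceae", "ectomycorrhizal"),
        OtuDef("OTU6", "Clitopilus", "Entolomataceae", "saprotrophic"),
        OtuDef("OTU7", "Trichoderma", "Hypocreaceae", "other"),
    )
    group_alphas = {
        # one orchid group keeps several co-dominant partners ...
        "O_aff_fissus_scale": {"OTU1": 12.0, "OTU2": 13.0, "OTU3": 2.0,
                               "OTU6": 3.0, "OTU7": 0.2},
        # ... the others are overwhelmingly dominated by a single OTU
        "O_fissus": {"OTU1": 40.0, "OTU3": 0.5, "OTU7": 0.2},
        "O_nakaianus_green": {"OTU1": 50.0, "OTU4": 0.3, "OTU5": 0.9, "OTU7": 0.1},
        "O_nakaianus_albino": {"OTU1": 50.0, "OTU4": 0.5, "OTU5": 0.1, "OTU7": 0.1},
    }
    return SyntheticConfig(
        seed=seed,
        sites=sites,
        groups=groups,
        eps_fmh_true=8.4,
        otu_profile=OtuProfileConfig(otus=otus, group_alphas=group_alphas),
    )


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def gen_isotope_dataset(
    config: SyntheticConfig,
) -> tuple[list[IsotopeSample], IsotopeTruth]:
    """Draw a synthetic isotope sample table plus its generating truth.

    Plot effects are drawn once per plot and shared by references and targets
    of that plot; targets are assigned to their site's plots round-robin.
    """
    if not config.sites or not config.groups:
        raise ConfigurationError("config needs at least one site and one group")
    rng = np.random.default_rng(config.seed)

    plot_ids: dict[str, list[str]] = {}
    eff13: dict[str, float] = {}
    eff15: dict[str, float] = {}
    samples: list[IsotopeSample] = []

    for site in config.sites:
        ids = [f"{site.site_id}_P{j + 1}" for j in range(site.n_plots)]
        plot_ids[site.site_id] = ids
        for pid in ids:
            eff13[pid] = rng.normal(0.0, site.plot_sd)
            eff15[pid] = rng.normal(0.0, site.plot_sd_15N)
            for k in range(site.refs_per_plot):
                samples.append(
                    IsotopeSample(
                        sample_id=f"{pid}_ref{k + 1}",
                        group=REFERENCE_GROUP,
                        site_id=site.site_id,
                        plot_id=pid,
                        role="reference",
                        delta13C=site.ref_mean_delta13C + eff13[pid]
                        + rng.normal(0.0, site.ref_sd),
                        delta15N=site.ref_mean_delta15N + eff15[pid]
                        + rng.normal(0.0, site.ref_sd_15N),
                    )
                )

    site_by_id = {s.site_id: s for s in config.sites}
    for grp in config.groups:
        site = site_by_id[grp.site_id]
        ids = plot_ids[grp.site_id]
        for i in range(grp.n):
            pid = ids[i % len(ids)]
            samples.append(
                IsotopeSample(
                    sample_id=f"{grp.name}_{i + 1}",
                    group=grp.name,
                    site_id=grp.site_id,
                    plot_id=pid,
                    role="target",
                    tissue=grp.tissue,
                    delta13C=site.ref_mean_delta13C + eff13[pid]
                    + grp.true_pcdf / 100.0 * config.eps_fmh_true
                    + rng.normal(0.0, site.residual_sd),
                    delta15N=site.ref_mean_delta15N + eff15[pid]
                    + grp.true_eps15N
                    + rng.normal(0.0, site.residual_sd_15N),
                )
            )

    truth = IsotopeTruth(
        eps_fmh_true=config.eps_fmh_true,
        group_true_pcdf={g.name: g.true_pcdf for g in config.groups},
        group_true_eps15N={g.name: g.true_eps15N for g in config.groups},
        plot_effects_13C=eff13,
        plot_effects_15N=eff15,
    )
    return samples, truth


def gen_otu_table(config: SyntheticConfig) -> OtuTable:
    """Dirichlet-multinomial OTU counts per sample, grouped as configured."""
    prof = config.otu_profile
    if prof is None:
        raise ConfigurationError("config has no otu_profile")
    rng = np.random.default_rng(config.seed)
    otu_ids = [o.otu_id for o in prof.otus]
    lo, hi = prof.reads_per_sample

    count_rows, sample_ids, groups = [], [], []
    for group in sorted(prof.group_alphas):
        alphas = prof.group_alphas[group]
        idx = [otu_ids.index(o) for o in otu_ids if o in alphas]
        avec = np.array([alphas[otu_ids[i]] for i in idx], dtype=float)
        for s in range(prof.n_samples_per_group):
            depth = int(rng.integers(lo, hi + 1))
            p = rng.dirichlet(avec)
            counts = np.zeros(len(otu_ids), dtype=np.int64)
            counts[idx] = rng.multinomial(depth, p)
            count_rows.append(counts)
            sample_ids.append(f"{group}_s{s + 1}")
            groups.append(group)

    counts = pd.DataFrame(count_rows, index=sample_ids, columns=otu_ids)
    otu_meta = pd.DataFrame(
        {
            "genus": [o.genus for o in prof.otus],
            "family": [o.family for o in prof.otus],
            "guild": [o.guild for o in prof.otus],
        },
        index=pd.Index(otu_ids, name="otu_id"),
    )
    sample_meta = pd.DataFrame(
        {"group": groups}, index=pd.Index(sample_ids, name="sample_id")
    )
    return OtuTable(counts=counts, otu_meta=otu_meta, sample_meta=sample_meta)


_BASES = np.array(list("ACGT"))


def gen_read_set(
    n_families: int = 3,
    reads_per_family: int = 6,
    length: int = 150,
    mutation_rate: float = 0.01,
    seed: int = 0,
) -> tuple[ReadSet, dict[str, str]]:
    """Random sequence families with point mutations, for clustering tests.

    Each family has one exact-centroid read with the family's highest
    abundance; the remaining reads carry Binomial(length, mutation_rate)
    substitutions. Returns the read set and a read_id -> family_id truth map.
    """
    if not (0.0 <= mutation_rate < 0.5):
        raise InvalidInputError("mutation_rate must be in [0, 0.5)")
    if n_families < 1 or reads_per_family < 1 or length < 1:
        raise InvalidInputError("n_families, reads_per_family, length must be >= 1")
    rng = np.random.default_rng(seed)
    records: list[ReadRecord] = []
    truth: dict[str, str] = {}
    for f in range(n_families):
        fam = f"fam{f + 1}"
        centroid = _BASES[rng.integers(0, 4, size=length)]
        records.append(
            ReadRecord(
                read_id=f"{fam}_r0",
                sequence="".join(centroid),
                abundance=1000 * (n_families - f),
            )
        )
        truth[f"{fam}_r0"] = fam
        for r in range(1, reads_per_family):
            seq = centroid.copy()
            n_mut = rng.binomial(length, mutation_rate)
            if n_mut:
                pos = rng.choice(length, size=n_mut, replace=False)
                for p in pos:
                    choices = [b for b in "ACGT" if b != seq[p]]
                    seq[p] = choices[rng.integers(0, 3)]
            rid = f"{fam}_r{r}"
            records.append(
                ReadRecord(
                    read_id=rid,
                    sequence="".join(seq),
                    abundance=int(rng.integers(1, 100)),
                )
            )
            truth[rid] = fam
    return ReadSet(records=records), truth
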