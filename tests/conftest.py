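import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mycomix import IsotopeSample, OtuTable

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_sample(sample_id, group, plot_id, d13, d15=-4.5, role="target",
                site_id="siteA", tissue="leaf"):
    return IsotopeSample(
        sample_id=sample_id, group=group, site_id=site_id, plot_id=plot_id,
        role=role, tissue=tissue, delta13C=d13, delta15N=d15,
    )


@pytest.fixture
def small_plot_samples():
    """One plot: two references around -34.4 and one enriched target."""
    return [
        make_sample("r1", "reference", "P1", -34.0, -4.0, role="reference"),
        make_sample("r2", "reference", "P1", -34.8, -5.0, role="reference"),
        make_sample("t1", "orchid", "P1", -26.7, 4.1),
    ]


def make_otu_table(group_counts: dict, otu_meta: dict | None = None) -> OtuTable:
    """Build a one-sample-per-group OtuTable from {group: {otu: reads}}."""
    otus = sorted({o for counts in group_counts.values() for o in counts})
    counts = pd.DataFrame(
        [[int(group_counts[g].get(o, 0)) for o in otus] for g in group_counts],
        index=[f"{g}_s1" for g in group_counts],
        columns=otus,
        dtype=np.int64,
    )
    if otu_meta is None:
        otu_meta = {o: ("Genus", "Family", "orchid_mycorrhizal") for o in otus}
    meta = pd.DataFrame(
        {
            "genus": [otu_meta[o][0] for o in otus],
            "family": [otu_meta[o][1] for o in otus],
            "guild": [otu_meta[o][2] for o in otus],
        },
        index=pd.Index(otus, name="otu_id"),
    )
    sample_meta = pd.DataFrame(
        {"group": list(group_counts)},
        index=pd.Index([f"{g}_s1" for g in group_counts], name="sample_id"),
    )
    return OtuTable(counts=counts, otu_meta=meta, sample_meta=sample_meta)


@pytest.fixture
def albino_protocorm_table():
    """Published per-phenotype read counts for the dominant mycobiont and
    the low-frequency ectomycorrhizal OTUs."""
    return make_otu_table(
        {
            "albino": {"OTU1": 41821, "Russula": 401, "Sebacina": 75},
            "protocorm": {"OTU1": 26000, "Russula": 58},
        },
        otu_meta={
            "OTU1": ("Ceratobasidium", "Ceratobasidiaceae", "orchid_mycorrhizal"),
            "Russula": ("Russula", "Russulaceae", "ectomycorrhizal"),
            "Sebacina": ("Sebacina", "Sebacinaceae", "ectomycorrhizal"),
        },
    )
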