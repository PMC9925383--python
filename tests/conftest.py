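import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from transtress import SimConfig, TranscriptionalStressModel
from transtress.annotation import GeneCatalog, GeneModel, ReadSet
from transtress.simulate import simulate_dataset

settings.register_profile(
    "default",
    settings(
        derandomize=True,
        deadline=None,
        max_examples=50,
        suppress_health_check=[HealthCheck.too_slow],
    ),
)
settings.load_profile("default")


def make_readset(mids, chrom="chr1", strand="+", assay="EU", group="adult", width=50, **kw):
    """ReadSet whose read midpoints are exactly ``mids``."""
    mids = np.asarray(mids, dtype=np.int64)
    if np.ndim(strand) == 0:
        strands = np.full(len(mids), strand, dtype="U1")
    else:
        strands = np.asarray(strand, dtype="U1")
    start = mids - width // 2
    return ReadSet(
        sample_id=kw.pop("sample_id", "s1"),
        assay=assay,
        group=group,
        replicate=kw.pop("replicate", 1),
        chrom=np.full(len(mids), chrom, dtype=object),
        start=start,
        end=start + width,
        strand=strands,
        **kw,
    )


@pytest.fixture
def toy_gene():
    return GeneModel(
        "gT",
        "chr1",
        "+",
        5_000,
        45_000,
        exons=((5_000, 5_300), (20_000, 20_150), (43_000, 45_000)),
        utr3=(44_000, 45_000),
    )


@pytest.fixture
def toy_catalog(toy_gene):
    g2 = GeneModel(
        "gU",
        "chr1",
        "-",
        100_000,
        140_000,
        exons=((100_000, 101_000), (120_000, 120_150), (139_700, 140_000)),
        utr3=(100_000, 100_600),
    )
    return GeneCatalog([toy_gene, g2], {"chr1": 1_000_000})


@pytest.fixture(scope="session")
def default_sim():
    """One default-configuration simulated dataset (phenomenological)."""
    return simulate_dataset(SimConfig(seed=11))


@pytest.fixture(scope="session")
def default_results(default_sim):
    model = TranscriptionalStressModel.from_dataset_object(default_sim)
    return model.fit(seed=11)


@pytest.fixture(scope="session")
def mech_sim():
    """A mechanistic-mode dataset (lesions, queues, strand dropout)."""
    return simulate_dataset(SimConfig(seed=7, mode="mechanistic"))
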