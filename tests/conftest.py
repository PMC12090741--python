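import numpy as np
import pandas as pd
import pytest

from lifehist import synthetic
from lifehist.rrn import RANKS, AsvTable, RrnReference


def make_table(counts: dict, taxonomy: dict) -> AsvTable:
    """Build an AsvTable from {asv: {sample: count}} and {asv: {rank: name}}."""
    c = pd.DataFrame(counts).T.fillna(0).astype(int)
    tax = pd.DataFrame(taxonomy).T.reindex(columns=list(RANKS)).fillna("")
    return AsvTable(c, tax)


def make_reference(entries: list[dict]) -> RrnReference:
    """Build an RrnReference from partial lineage dicts with copy_number."""
    df = pd.DataFrame(entries).reindex(columns=[*RANKS, "copy_number"])
    df[list(RANKS)] = df[list(RANKS)].fillna("")
    return RrnReference(df)


@pytest.fixture(scope="session")
def small_reference() -> RrnReference:
    return synthetic.gen_reference(50, (1, 15), seed=11)


@pytest.fixture(scope="session")
def community_bundle(small_reference):
    """A small planted-effect community with metadata and truth."""
    return synthetic.gen_communities(
        small_reference, n_sites=4, samples_per_site=2,
        effect=0.6, site_sd=0.1, depth=5000, seed=21,
    )


@pytest.fixture(scope="session")
def codon_background():
    return synthetic.random_background(seed=5)


def random_asv_table(rng: np.random.Generator, n_asv: int = 20, n_samples: int = 4) -> tuple[AsvTable, np.ndarray]:
    """Random counts plus random copy numbers for oracle checks."""
    counts = pd.DataFrame(
        rng.integers(0, 200, size=(n_asv, n_samples)),
        index=[f"a{i}" for i in range(n_asv)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
    counts.iloc[0] += 1  # guarantee assigned reads in every sample
    tax = pd.DataFrame(
        {r: [f"{r}{i}" for i in range(n_asv)] for r in RANKS},
        index=counts.index,
    )
    copies = np.round(rng.uniform(1, 15, n_asv) * 2) / 2
    return AsvTable(counts, tax), copies
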