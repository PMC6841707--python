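import numpy as np
import pandas as pd
import pytest

from floodnet.core import CountTable, SampleHierarchy


@pytest.fixture
def small_counts() -> CountTable:
    """3 taxa x 4 samples with lineage and guild annotations."""
    counts = pd.DataFrame(
        [[50, 6, 2, 0], [25, 2, 2, 5], [25, 0, 0, 5]],
        index=["t1", "t2", "t3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    lineage = pd.Series(
        ["Cyanobacteria;Nostocales;Nostocaceae", "Cyanobacteria;Nostocales;Nostocaceae", "Proteobacteria;Rhodo;FamX"],
        index=counts.index,
    )
    guild = pd.Series(
        ["heterocystous-cyanobacteria", "heterocystous-cyanobacteria", "other"], index=counts.index
    )
    return CountTable(counts, lineage=lineage, guild=guild)


@pytest.fixture
def tiny_hierarchy() -> SampleHierarchy:
    rows = []
    for fp, habs in [("A", ["riffle", "run", "backwater", "pond"]), ("B", ["riffle", "pond"])]:
        for h in habs:
            rows.append(
                {
                    "sample_id": f"{fp}-{h}",
                    "biome": "montane",
                    "floodplain": fp,
                    "zone": "main-channel" if h in ("riffle", "run") else "off-channel",
                    "habitat": h,
                    "x": float(len(rows)) * 100,
                    "y": 0.0,
                }
            )
    return SampleHierarchy(pd.DataFrame(rows).set_index("sample_id"))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260918)


def random_count_table(rng: np.random.Generator, n_taxa: int = 8, n_samples: int = 6, lam: float = 5.0) -> CountTable:
    counts = rng.poisson(lam, size=(n_taxa, n_samples))
    # guard against all-zero columns
    counts[0] += 1
    return CountTable(
        pd.DataFrame(counts, index=[f"t{i}" for i in range(n_taxa)], columns=[f"s{j}" for j in range(n_samples)])
    )
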