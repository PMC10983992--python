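import numpy as np
import pandas as pd
import pytest

from mobnet.config import AnalysisConfig
from mobnet.engagement import Regulon
from mobnet.expression import DeTable


@pytest.fixture
def config():
    return AnalysisConfig()


def make_de_table(up=0, down=0, unchanged=0, prefix="g", condition="cm",
                  timepoint="6h", lfc_up=2.0, lfc_down=-2.0, padj=0.01):
    """A DE table with the requested number of up/down/unchanged genes."""
    rows = []
    i = 0
    for _ in range(up):
        rows.append((f"{prefix}{i:04d}", lfc_up, padj)); i += 1
    for _ in range(down):
        rows.append((f"{prefix}{i:04d}", lfc_down, padj)); i += 1
    for _ in range(unchanged):
        rows.append((f"{prefix}{i:04d}", 0.1, 0.8)); i += 1
    df = pd.DataFrame(rows, columns=["gene", "log2fc", "padj"])
    return DeTable(condition=condition, timepoint=timepoint, data=df)


def regulon_over(table, regulator="RegA"):
    """A regulon containing exactly the genes of a table."""
    return Regulon(regulator=regulator, members=frozenset(table.data["gene"]))


def random_instance(rng, n_genes=300, n_regulons=10):
    """A random DE table plus random regulons for oracle-equivalence tests."""
    genes = [f"g{i:04d}" for i in range(n_genes)]
    lfc = rng.normal(0, 1.6, n_genes)
    padj = rng.uniform(0, 0.2, n_genes)
    df = pd.DataFrame({"gene": genes, "log2fc": lfc, "padj": padj})
    # some missing padj entries
    miss = rng.random(n_genes) < 0.05
    df.loc[miss, "padj"] = np.nan
    table = DeTable(condition="rand", timepoint="6h", data=df)
    members = {}
    for r in range(n_regulons):
        size = int(rng.integers(3, max(4, n_genes // 4)))
        members[f"R{r:02d}"] = set(rng.choice(genes, size, replace=False))
    return table, members
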