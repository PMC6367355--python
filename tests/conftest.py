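import numpy as np
import pandas as pd
import pytest

from refstab.data import CqTable


def make_annotations(samples, group="mock", timepoint="6h"):
    return pd.DataFrame(
        {
            "sample_id": samples,
            "group": group,
            "timepoint": timepoint,
            "bio_rep": range(1, len(samples) + 1),
        }
    )


def wide_to_table(wide: pd.DataFrame, annotations: pd.DataFrame | None = None) -> CqTable:
    """Build a collapsed CqTable from a genes x samples Cq matrix."""
    if annotations is None:
        annotations = make_annotations(list(wide.columns))
    long = wide.reset_index(names="gene").melt(
        id_vars="gene", var_name="sample_id", value_name="cq"
    )
    return CqTable(long[["sample_id", "gene", "cq"]], annotations, collapsed=True)


@pytest.fixture
def small_panel():
    """Deterministic 4-gene x 6-sample Cq matrix with design annotation."""
    rng = np.random.default_rng(7)
    samples = [f"s{i}" for i in range(1, 7)]
    ann = pd.DataFrame(
        {
            "sample_id": samples,
            "group": ["mock"] * 3 + ["Pf"] * 3,
            "timepoint": ["6h"] * 6,
            "bio_rep": [1, 2, 3, 1, 2, 3],
        }
    )
    wide = pd.DataFrame(
        20.0 + rng.normal(0, 0.5, (4, 6)),
        index=pd.Index([f"g{i}" for i in range(1, 5)], name="gene"),
        columns=samples,
    )
    return wide_to_table(wide, ann)


@pytest.fixture
def random_wide():
    """Factory for random genes x samples Cq matrices."""

    def _make(n_genes=5, n_samples=12, seed=0, base=25.0, spread=2.0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            base + rng.uniform(-spread, spread, (n_genes, n_samples)),
            index=pd.Index([f"g{i:02d}" for i in range(n_genes)], name="gene"),
            columns=[f"s{j:02d}" for j in range(n_samples)],
        )

    return _make
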