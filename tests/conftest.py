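"""Shared fixtures: a hand-written 5x4 Visium bundle and the default
synthetic fasting study analyzed end to end (computed once per session)."""

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from zonatlas import pipeline, synthetic_data
from zonatlas.io_visium import SpotDataset, merge_conditions, write_visium

TINY_COUNTS = np.array(
    [
        [5, 0, 1, 0],
        [0, 2, 0, 0],
        [3, 3, 3, 3],
        [0, 0, 0, 7],
        [1, 0, 4, 2],
    ]
)


def make_tiny_dataset(in_tissue=(1, 1, 1, 1)) -> SpotDataset:
    n = len(in_tissue)
    positions = pd.DataFrame(
        {
            "in_tissue": np.asarray(in_tissue, dtype=np.int64),
            "array_row": np.arange(n, dtype=np.int64),
            "array_col": np.arange(n, dtype=np.int64)[::-1].copy(),
            "pxl_row_in_fullres": np.linspace(10.5, 40.25, n),
            "pxl_col_in_fullres": np.linspace(7.75, 31.5, n),
        }
    )
    return SpotDataset(
        counts=sp.csr_matrix(TINY_COUNTS[:, :n]),
        gene_ids=np.array([f"ENSMUSG{i:04d}" for i in range(5)], dtype=object),
        gene_symbols=np.array(["mt-Nd1", "Hba-a1", "Alb", "Glul", "Gx"], dtype=object),
        barcodes=np.array([f"BC{i:02d}" for i in range(n)], dtype=object),
        positions=positions,
    )


@pytest.fixture
def tiny_dataset() -> SpotDataset:
    return make_tiny_dataset()


@pytest.fixture
def tiny_bundle(tmp_path, tiny_dataset):
    return write_visium(tiny_dataset, tmp_path / "bundle")


@dataclass
class DefaultStudy:
    """The default 600-gene / 1000-spot-per-condition synthetic study,
    simulated at seed 1 and analyzed with the default pipeline settings."""

    samples: list
    truths: dict
    ds: SpotDataset
    norm: np.ndarray
    embedding: object
    axis: object
    labels: pd.DataFrame

    def truth_genes(self) -> pd.DataFrame:
        return pd.concat(
            [t.genes for t in self.truths.values()], ignore_index=True
        )

    def spot_truth(self, column: str) -> np.ndarray:
        return np.concatenate(
            [self.truths[c].spots[column].to_numpy() for c in self.truths]
        )


@pytest.fixture(scope="session")
def default_study() -> DefaultStudy:
    samples, truths = synthetic_data.simulate_study(seed=1)
    ds = merge_conditions(samples)
    cfg = pipeline.RunConfig(outdir="unused", seed=0)
    res = pipeline.analyze_dataset(ds, cfg)
    return DefaultStudy(
        samples=samples,
        truths=truths,
        ds=res["ds"],
        norm=res["norm"],
        embedding=res["embedding"],
        axis=res["axis"],
        labels=res["labels"],
    )
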