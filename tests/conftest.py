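import numpy as np
import pandas as pd
import pytest

from dysbiome.diversity import DissimilarityMatrix
from dysbiome.simulate import ExperimentDesign, build_template
from dysbiome.tables import CountTable


@pytest.fixture
def tiny_table() -> CountTable:
    """3 taxa x 3 samples integer count table."""
    df = pd.DataFrame(
        {"s1": [5, 0, 3], "s2": [2, 2, 2], "s3": [0, 7, 1]},
        index=pd.Index(["taxA", "taxB", "taxC"], name="taxon_id"),
    )
    return CountTable(df, unit="counts")


@pytest.fixture
def default_template():
    return build_template({})


@pytest.fixture
def small_design() -> ExperimentDesign:
    return ExperimentDesign(
        individuals=["s1", "s2", "s3"],
        treatments=["CON", "INJ-HI"],
        reference="CON",
        timepoints_h=[0, 24, 72],
    )


def euclidean_dm(points: np.ndarray, ids=None) -> DissimilarityMatrix:
    """Distance matrix of an explicit coordinate configuration."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] == 1:
        pts = pts.T
    diff = pts[:, None, :] - pts[None, :, :]
    D = np.sqrt((diff**2).sum(axis=2))
    np.fill_diagonal(D, 0.0)
    ids = ids or [f"p{i}" for i in range(len(pts))]
    return DissimilarityMatrix((D + D.T) / 2, ids)
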