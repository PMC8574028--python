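"""Shared fixtures: tiny hand-written study files and toy graphs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from overlapnet.data import CountMatrix, SampleSheet
from overlapnet.hlc import LinkGraph


@pytest.fixture()
def small_sheet() -> SampleSheet:
    """Two genotypes × two conditions × two replicates (8 samples)."""
    rows = []
    for g in ("g1", "g2"):
        for cond in ("control", "treatment"):
            for rep in (1, 2):
                rows.append(
                    {"sample": f"{g}_{cond}_{rep}", "genotype": g, "condition": cond, "replicate": rep}
                )
    return SampleSheet(pd.DataFrame(rows))


@pytest.fixture()
def small_counts(small_sheet: SampleSheet) -> CountMatrix:
    rng = np.random.default_rng(7)
    values = rng.integers(1, 200, size=(6, 8))
    return CountMatrix(
        gene_ids=[f"gene{i}" for i in range(1, 7)], samples=small_sheet, values=values
    )


def write_counts_files(tmp_path, counts: CountMatrix):
    counts_path = tmp_path / "counts.tsv"
    counts.to_frame().to_csv(counts_path, sep="\t", index_label="gene_id")
    sheet_path = tmp_path / "samples.csv"
    counts.samples.frame.to_csv(sheet_path, index=False)
    return counts_path, sheet_path


@pytest.fixture()
def counts_files(tmp_path, small_counts):
    return write_counts_files(tmp_path, small_counts)


# -- toy graphs for link clustering ----------------------------------------


@pytest.fixture()
def triangle() -> LinkGraph:
    return LinkGraph([("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture()
def bowtie() -> LinkGraph:
    """Two triangles sharing the single node k."""
    return LinkGraph(
        [("a", "b"), ("a", "k"), ("b", "k"), ("c", "d"), ("c", "k"), ("d", "k")]
    )


@pytest.fixture()
def two_triangles() -> LinkGraph:
    return LinkGraph(
        [("a", "b"), ("b", "c"), ("a", "c"), ("x", "y"), ("y", "z"), ("x", "z")]
    )


@pytest.fixture()
def star3() -> LinkGraph:
    return LinkGraph([("hub", "l1"), ("hub", "l2"), ("hub", "l3")])
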