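"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from spatialtme.gating import PHENOTYPES


def brute_force_census(
    cells: pd.DataFrame,
    ring_edges,
    phenotypes=PHENOTYPES,
    phenotype_column: str = "phenotype",
) -> np.ndarray:
    """O(n^2) double-loop ring census oracle, independent of the k-d-tree
    implementation. Ring membership (lower, upper]; d = 0 -> ring 0; self
    excluded; neighborhoods within sample only."""
    edges = np.asarray(ring_edges, dtype=float)
    P, R = len(phenotypes), len(edges) - 1
    pheno_idx = {p: i for i, p in enumerate(phenotypes)}
    xy = cells[["x_um", "y_um"]].to_numpy(dtype=float)
    samples = cells["sample_id"].to_numpy()
    codes = np.array([pheno_idx[p] for p in cells[phenotype_column].astype(str)])
    n = len(cells)
    counts = np.zeros((n, P, R), dtype=np.int64)
    for i in range(n):
        for j in range(n):
            if i == j or samples[i] != samples[j]:
                continue
            d = float(np.hypot(*(xy[i] - xy[j])))
            if d > edges[-1]:
                continue
            if d == 0.0:
                ring = 0
            else:
                ring = int(np.searchsorted(edges[1:], d, side="left"))
                if ring >= R:
                    continue
            counts[i, codes[j], ring] += 1
    return counts


def make_cells(
    x, y, phenotype=None, sample_id="S1", markers=("NOS2", "COX2", "CD8")
) -> pd.DataFrame:
    """Minimal cell table from coordinate lists."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    df = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(len(x))],
            "sample_id": sample_id,
            "x_um": x,
            "y_um": y,
        }
    )
    if phenotype is not None:
        df["phenotype"] = list(phenotype)
    for m in markers:
        df[m] = 1.0
    return df


def disc_cells(
    radius: float,
    density_per_mm2: float,
    center=(0.0, 0.0),
    seed: int = 0,
    sample_id: str = "S1",
) -> pd.DataFrame:
    """Uniform random cells filling a disc at a given density."""
    rng = np.random.default_rng(seed)
    n = rng.poisson(density_per_mm2 * np.pi * radius**2 / 1e6)
    r = radius * np.sqrt(rng.random(n))
    a = rng.uniform(0, 2 * np.pi, n)
    return make_cells(center[0] + r * np.cos(a), center[1] + r * np.sin(a), sample_id=sample_id)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
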