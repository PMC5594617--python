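"""Shared fixtures and small independent oracles used across the suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


def random_additive_matrix(
    rng: np.random.Generator, n_taxa: int
) -> tuple[pd.DataFrame, None]:
    """Random additive (tree-metric) distance matrix built by joining random
    subtrees with positive branch lengths; independent of the NJ code."""
    maps: list[dict[str, float]] = [{f"t{i}": 0.0} for i in range(n_taxa)]
    dist: dict[tuple[str, str], float] = {}
    while len(maps) > 1:
        i, j = sorted(rng.choice(len(maps), size=2, replace=False))
        la, lb = rng.uniform(0.05, 1.0, size=2)
        a, b = maps[i], maps[j]
        for x, dx in a.items():
            for y, dy in b.items():
                dist[(x, y)] = dist[(y, x)] = dx + la + dy + lb
        merged = {x: dx + la for x, dx in a.items()}
        merged.update({y: dy + lb for y, dy in b.items()})
        maps = [m for k, m in enumerate(maps) if k not in (i, j)] + [merged]
    ids = sorted(maps[0])
    D = pd.DataFrame(0.0, index=ids, columns=ids)
    for x in ids:
        for y in ids:
            if x != y:
                D.loc[x, y] = dist[(x, y)]
    return D, None


@pytest.fixture(scope="session")
def two_group_null_counts():
    """Small null NB count matrix (no planted DE), two groups of six."""
    from holosplit import synthio as sy

    cfg = sy.SynthConfig(
        n_genes=800,
        frac_de=0.0,
        dispersion=0.1,
        seed=42,
        groups=(("healthy", 6), ("ga_affected", 6)),
    )
    counts, meta, _ = sy.simulate_counts(cfg)
    return counts, meta
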