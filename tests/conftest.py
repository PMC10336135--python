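import numpy as np
import pandas as pd
import pytest

import gliograph as gg


def map_from_strings(rows: list[str]) -> gg.graph.CellularMap:
    """Build a cellular map from strings like ["AABBB"] (one char per patch)."""
    labels = np.array([[c for c in row] for row in rows], dtype=object)
    return gg.graph.CellularMap(labels=labels)


def brute_force_pair_counts(labels: np.ndarray) -> dict:
    """Independent oracle: enumerate all node pairs, count class-pair edges
    among pairs at Chebyshev distance <= 2."""
    labels = np.asarray(labels, dtype=object)
    h, w = labels.shape
    pos = [(x, y) for y in range(h) for x in range(w)]
    counts: dict = {}
    for i in range(len(pos)):
        for j in range(i + 1, len(pos)):
            (x1, y1), (x2, y2) = pos[i], pos[j]
            if max(abs(x1 - x2), abs(y1 - y2)) <= 2:
                a, b = sorted([str(labels[y1, x1]), str(labels[y2, x2])])
                counts[(a, b)] = counts.get((a, b), 0) + 1
    return counts


def brute_force_cc(counts: dict, m: str) -> float | None:
    i_mm = counts.get((m, m), 0)
    i_mk = sum(v for (a, b), v in counts.items() if (a == m) != (b == m))
    if i_mm + i_mk == 0:
        return None
    return i_mm / (i_mm + i_mk)


def brute_force_interaction(counts: dict) -> dict:
    total = sum(counts.values())
    return {pair: v / total for pair, v in counts.items()}


@pytest.fixture(scope="session")
def small_sample():
    """One 20x20 tumor sample plus matched reference (session-shared)."""
    cfg = gg.synth.SynthConfig(grid_width=20, grid_height=20, n_genes=1600, seed=3)
    adata, truth = gg.synth.generate_expression_sample(cfg, seed=3)
    ref = gg.synth.generate_reference_sample(cfg, seed=103)
    return cfg, adata, truth, ref


@pytest.fixture(scope="session")
def survival_table():
    rng = np.random.default_rng(7)
    X = pd.DataFrame({"x1": rng.normal(size=500), "x2": rng.normal(size=500)})
    return gg.synth.generate_survival_cohort(
        X, {"x1": 0.5, "x2": -0.3}, 24.0, 0.3, seed=7
    )
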