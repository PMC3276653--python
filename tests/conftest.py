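import numpy as np
import pandas as pd
import pytest

from subtypeqtl import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study shared by read-only tests."""
    cfg = SimulationConfig(n_genes=400, include_fine_mapping_snps=True)
    return simulate_study(cfg, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def brute_force_posterior(positions, obs, query_idx, q_homolog=1):
    """Exact transmission posterior by enumerating all origin vectors.

    positions: sorted cM positions; obs: array with 1/2 observed origin or 0
    unknown at each position; returns P(origin at query == q_homolog | obs).
    Independent oracle for the forward-backward pass (feasible for few
    positions).
    """
    from itertools import product

    from subtypeqtl import haldane_recombination

    positions = np.asarray(positions, dtype=float)
    c = haldane_recombination(np.diff(positions))
    num = den = 0.0
    for path in product((1, 2), repeat=len(positions)):
        ok = all(o == 0 or o == s for o, s in zip(obs, path))
        if not ok:
            continue
        w = 0.5
        for j in range(1, len(path)):
            w *= c[j - 1] if path[j] != path[j - 1] else 1.0 - c[j - 1]
        den += w
        if path[query_idx] == q_homolog:
            num += w
    return num / den if den > 0 else 0.5
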