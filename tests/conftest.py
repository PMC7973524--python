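import numpy as np
import pytest

import hicloops as hl


@pytest.fixture
def triplet_file(tmp_path):
    """3-bin text-fallback matrix with triplets (0,0,5), (0,1,2), (1,2,1)."""
    p = tmp_path / "tiny.txt"
    p.write_text(
        "# chrom=chr1 resolution=10000 n_bins=3 balanced=1\n"
        "0 0 5\n0 1 2\n1 2 1\n"
    )
    return str(p)


@pytest.fixture
def dense_random_cm():
    """Seeded dense random 60x60 matrix (all pixels positive)."""
    rng = np.random.default_rng(42)
    dense = rng.uniform(0.1, 5.0, size=(60, 60))
    dense = np.triu(dense)
    return hl.ContactMatrix.from_dense(dense, chrom="chrT", resolution=5000)


@pytest.fixture(scope="session")
def planted_200():
    """200-bin synthetic matrix with 5 planted loops at fold 8 (seed 7)."""
    spec = hl.place_random_loops(200, 5, fold=8.0, radius=1, seed=7)
    cfg = hl.SyntheticConfig(n_bins=200, seed=7, loop_spec=spec)
    cm, truth = hl.simulate_matrix(cfg)
    return cm, truth


def brute_force_bh(p):
    """Independent step-up BH: q_(i) = min_{m >= i} p_(m) * n / m."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    running = np.inf
    for rank in range(n, 0, -1):
        running = min(running, p[order[rank - 1]] * n / rank)
        q[order[rank - 1]] = min(running, 1.0)
    return q


def brute_force_components(pixels, connectivity=4):
    """Flood-fill connected components of a set of (i, j) pixels."""
    pixels = set(map(tuple, pixels))
    if connectivity == 4:
        steps = [(1, 0), (-1, 0), (0, 1), (0, -1)]
    else:
        steps = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)
                 if (di, dj) != (0, 0)]
    comps = []
    remaining = set(pixels)
    while remaining:
        seed = remaining.pop()
        comp = {seed}
        frontier = [seed]
        while frontier:
            i, j = frontier.pop()
            for di, dj in steps:
                nb = (i + di, j + dj)
                if nb in remaining:
                    remaining.remove(nb)
                    comp.add(nb)
                    frontier.append(nb)
        comps.append(frozenset(comp))
    return comps
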