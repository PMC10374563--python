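import warnings

import numpy as np
import pytest

import svgrank as sv

BENCHMARK_SEED = 0


@pytest.fixture(scope="session")
def benchmark():
    """The shipped synthetic benchmark, run once through the full pipeline.

    40x40 hex lattice, three disjoint regions, 30 planted SVGs, 200 noise
    genes, negative-binomial counts, analytic Moran p-values.
    """
    spec = sv.default_benchmark(seed=BENCHMARK_SEED)
    cm, coords, truth = sv.generate(spec)
    # select as many top SVGs as are planted (the top-500-of-20k selection
    # of real data, scaled to the 230-gene benchmark)
    cfg = sv.RunConfig(n_clusters=3, top_k=30, seed=BENCHMARK_SEED)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sv.run_stages(cm, coords, cfg)
    return {
        "spec": spec,
        "cm": cm,
        "coords": coords,
        "truth": truth,
        "cfg": cfg,
        "res": res,
    }


@pytest.fixture
def hex7():
    """A 7-spot hexagonal patch: one center with 6 equidistant neighbors."""
    s3 = np.sqrt(3.0) / 2.0
    coords = np.array(
        [
            [0.0, 0.0],   # center
            [1.0, 0.0],
            [-1.0, 0.0],
            [0.5, s3],
            [-0.5, s3],
            [0.5, -s3],
            [-0.5, -s3],
        ]
    )
    return coords


@pytest.fixture
def grid5():
    """A 5x5 square grid of spots."""
    xs, ys = np.meshgrid(np.arange(5.0), np.arange(5.0))
    return np.column_stack([xs.ravel(), ys.ravel()])
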