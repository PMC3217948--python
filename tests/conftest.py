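import numpy as np
import pandas as pd
import pytest

import qpdecon as qd


@pytest.fixture(scope="session")
def two_type_system():
    """Blood/breast-style 2-type system: pure profiles, design truth,
    1%-noise mixtures, marker ranking and a selected signature."""
    cfg = qd.SimulationConfig(
        n_types=2, n_genes=2000, markers_per_type=150, seed=101,
        type_labels=["blood", "breast"],
    )
    pure = qd.generate_pure_profiles(cfg)
    truth = qd.benchmark_design("blood_breast")
    mixtures = qd.generate_mixtures(pure, truth, noise_cv=0.01, seed=102)
    ranking = qd.candidate_ranking(pure)
    sizes = list(range(40, min(1000, len(ranking)) + 1, 20))
    signature, trace = qd.select_signature(pure, ranking, size_grid=sizes)
    return {
        "cfg": cfg,
        "pure": pure,
        "truth": truth,
        "mixtures": mixtures,
        "ranking": ranking,
        "signature": signature,
        "trace": trace,
    }


@pytest.fixture(scope="session")
def three_type_system():
    """3-type system with random simplex mixtures for trace/oracle tests."""
    cfg = qd.SimulationConfig(n_types=3, n_genes=1500, markers_per_type=60, seed=11)
    pure = qd.generate_pure_profiles(cfg)
    ranking = qd.candidate_ranking(pure)
    rng = np.random.default_rng(5)
    rows = [rng.dirichlet([1.0, 1.0, 1.0]) for _ in range(12)]
    truth = qd.FractionTable(
        pd.DataFrame(rows, index=[f"s{i}" for i in range(12)], columns=cfg.type_labels)
    )
    mixtures = qd.generate_mixtures(pure, truth, noise_cv=0.01, seed=6)
    return {
        "cfg": cfg,
        "pure": pure,
        "ranking": ranking,
        "truth": truth,
        "mixtures": mixtures,
    }


@pytest.fixture
def tiny_expr():
    """3-gene x 2-sample linear-scale matrix."""
    frame = pd.DataFrame(
        [[10.0, 20.0], [5.0, 2.5], [100.0, 50.0]],
        index=["G1", "G2", "G3"],
        columns=["s1", "s2"],
    )
    return qd.ExpressionMatrix(frame, scale="linear")
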