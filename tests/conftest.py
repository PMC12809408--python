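"""Shared fixtures: tiny hand-built matrices and the simulated benchmarks.

The expensive objects (the medium single-cell benchmark and its trained
model, the gradient benchmark and its trajectories) are session-scoped so
recovery properties and acceptance checks share one computation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from senescore.io import CountMatrix
from senescore.preprocess import cpm_log, zscore_genes
from senescore.sid import CalibrationWarning, score, train_sid
from senescore.synthetic import make_fixture

SPLIT_SEED = 1
TRAIN_FRACTION = 0.7


@pytest.fixture
def tiny_counts() -> CountMatrix:
    values = np.array(
        [
            [0, 5, 10, 2],
            [3, 0, 1, 7],
            [8, 8, 8, 8],
            [1, 2, 3, 4],
        ],
        dtype=np.int64,
    )
    return CountMatrix(values, ["GA", "GB", "GC", "GD"], ["S1", "S2", "S3", "S4"])


@pytest.fixture(scope="session")
def sc_medium():
    matrix, truth, spec = make_fixture("sc_medium")
    return matrix, truth, spec


@pytest.fixture(scope="session")
def sc_medium_split(sc_medium):
    """70/30 split of the medium benchmark with a trained SID model."""
    matrix, truth, _ = sc_medium
    dense = matrix.to_dense()
    rng = np.random.default_rng(SPLIT_SEED)
    perm = rng.permutation(matrix.n_samples)
    n_train = int(TRAIN_FRACTION * matrix.n_samples)
    tr, te = perm[:n_train], perm[n_train:]
    train_cm = CountMatrix(dense[:, tr], matrix.gene_ids, [matrix.sample_ids[i] for i in tr])
    test_cm = CountMatrix(dense[:, te], matrix.gene_ids, [matrix.sample_ids[i] for i in te])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", CalibrationWarning)
        model = train_sid(
            zscore_genes(cpm_log(train_cm)),
            truth.labels[tr],
            n_features_target=100,
            seed=SPLIT_SEED,
        )
    result = score(model, zscore_genes(cpm_log(test_cm)))
    return {
        "model": model,
        "result": result,
        "train_labels": truth.labels[tr],
        "test_labels": truth.labels[te],
        "truth": truth,
    }


@pytest.fixture(scope="session")
def gradient_fx():
    matrix, truth, spec = make_fixture("gradient")
    return matrix, truth, spec


@pytest.fixture(scope="session")
def gradient_trajectories(gradient_fx):
    """SID-anchored and held-out-gene trajectories on the gradient benchmark."""
    from senescore.trajectory import graph_pseudotime, sid_pseudotime

    matrix, truth, _ = gradient_fx
    expr_log = cpm_log(matrix)
    expr_z = zscore_genes(expr_log)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", CalibrationWarning)
        model = train_sid(expr_z, truth.labels, n_features_target=30, seed=0)
    result = score(model, expr_z)
    traj_sid = sid_pseudotime(result)
    held_out = set(model.feature_genes) | set(truth.signature_genes)
    traj_graph = graph_pseudotime(
        expr_z,
        exclude_genes=held_out,
        root_hint=traj_sid.root_cell,
        k_neighbors=15,
        n_components=10,
        seed=0,
    )
    return {
        "truth": truth,
        "model": model,
        "result": result,
        "sid": traj_sid,
        "graph": traj_graph,
        "excluded": held_out,
        "expr_log": expr_log,
    }
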