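import numpy as np
import pytest

import shapecode.shapes as sh
from shapecode.render import build_grid, render_many


@pytest.fixture(scope="session")
def grid():
    return build_grid()


@pytest.fixture(scope="session")
def stimulus_set():
    return sh.enumerate_stimuli()


@pytest.fixture(scope="session")
def stimulus_features_36(stimulus_set):
    return sh.stimulus_features(stimulus_set)


@pytest.fixture(scope="session")
def small_db():
    return sh.sample_database(300, seed=42)


@pytest.fixture(scope="session")
def midscale_pipeline(grid):
    """Shared mid-scale run (1200 shapes): features, 8-D Isomap of the
    derivative channels, and canonical superquadric targets."""
    from shapecode.embedding import isomap_fit
    from shapecode.features import feature_matrix

    n = 1200
    db = sh.sample_database(n, seed=11)
    F = feature_matrix(render_many(db.shapes, grid))
    deriv = F.reshape(n, -1, 5)[:, :, 1:].reshape(n, -1)
    emb = isomap_fit(deriv, k=10, d=8)
    Ys = np.stack([sh.canonicalize(s).params for s in db.shapes])
    return {"db": db, "features": F, "embedding": emb, "sq_targets": Ys}


@pytest.fixture(scope="session")
def desk_pipeline(grid):
    """Shared desk-scale run: 4000 shapes rendered, featurized, embedded
    (Isomap d=8), with an MLP trained on the Isomap targets.

    Session-scoped because rendering and training dominate the suite's
    runtime and several checks read different aspects of the same run.
    """
    from shapecode.features import feature_matrix
    from shapecode.embedding import isomap_fit
    from shapecode.mapping import TrainingSchedule, evaluate, train_mlp

    n = 4000
    db = sh.sample_database(n, seed=0)
    depth = render_many(db.shapes, grid)
    F = feature_matrix(depth)
    deriv = F.reshape(n, -1, 5)[:, :, 1:].reshape(n, -1)
    emb = isomap_fit(deriv, k=10, d=8)
    net = train_mlp(
        F[db.train_idx], emb.coordinates[db.train_idx],
        hidden_sizes=(600, 300), seed=0,
        schedule=TrainingSchedule(max_epochs=80),
        target_space="isomap",
    )
    report = evaluate(net, F[db.val_idx], emb.coordinates[db.val_idx])
    return {"db": db, "depth": depth, "features": F, "embedding": emb,
            "net": net, "report": report}
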