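"""Feedforward CIP-to-AIP mappings.

Multilayer perceptrons regress shape parameters (canonical superquadric
parameters or Isomap coordinates) from the 1280-value CIP-like feature
stacks.  The architecture mirrors the reference setup: two logistic
hidden layers of 600 and 300 units and a linear output layer (linear so
the outputs can serve as the decoded input current to cosine-tuned
downstream neurons).  An NEF-style alternative replaces the trained
hidden layers with a population of cosine-LIF neurons holding random
preferred directions over local feature patches, read out by
regularized least-squares decoders.

The central comparison: networks approximate Isomap coordinates far
more accurately than canonical superquadric parameters, whose
discontinuities at the canonical-angle boundaries resist any smooth
feedforward map.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import h5py
import numpy as np
from sklearn.neural_network import MLPRegressor

from .neurons import fit_decoders, lif_rate, DecoderSet

__all__ = [
    "TrainingSchedule", "RegressionNet", "train_mlp", "EvalReport", "evaluate",
    "LocalKernelSpec", "NEFPopulation", "train_nef_population",
    "PipelineConfig", "run_pipeline",
]


@dataclass(frozen=True)
class TrainingSchedule:
    """Backpropagation hyperparameters (adaptive-moment gradient
    descent; early stopping on a held-out tenth of the training set)."""

    batch_size: int = 64
    max_epochs: int = 200
    patience: int = 10
    learning_rate: float = 1e-3
    validation_fraction: float = 0.1


@dataclass
class RegressionNet:
    """A trained feedforward regressor plus its input standardization."""

    model: MLPRegressor
    input_mean: np.ndarray
    input_scale: np.ndarray
    hidden_sizes: tuple
    seed: int
    loss_curve: list = field(default_factory=list)
    target_space: str = "unspecified"

    def predict(self, features: np.ndarray) -> np.ndarray:
        Z = (np.asarray(features, dtype=float) - self.input_mean) / self.input_scale
        out = self.model.predict(Z)
        return out if out.ndim > 1 else out[:, None]

    def save(self, weights_path, meta_path) -> None:
        with h5py.File(weights_path, "w") as f:
            for i, (W, b) in enumerate(zip(self.model.coefs_, self.model.intercepts_)):
                f.create_dataset(f"W{i}", data=W)
                f.create_dataset(f"b{i}", data=b)
            f.create_dataset("input_mean", data=self.input_mean)
            f.create_dataset("input_scale", data=self.input_scale)
        meta = {
            "hidden_sizes": list(self.hidden_sizes),
            "seed": self.seed,
            "target_space": self.target_space,
            "n_epochs": len(self.loss_curve),
        }
        Path(meta_path).write_text(json.dumps(meta, indent=2))


def train_mlp(
    train_features: np.ndarray,
    train_targets: np.ndarray,
    hidden_sizes: tuple = (600, 300),
    seed: int = 0,
    schedule: TrainingSchedule = TrainingSchedule(),
    standardize: bool = True,
    target_space: str = "unspecified",
) -> RegressionNet:
    """Train an MLP (logistic hidden units, linear output) by
    backpropagation on mean squared error.

    Deterministic given ``seed``.  Inputs are z-scored per feature using
    training statistics by default (raw mode available); targets are
    used as given.
    """
    X = np.asarray(train_features, dtype=float)
    Y = np.asarray(train_targets, dtype=float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise ValueError("non-finite features or targets")
    if standardize:
        mu = X.mean(axis=0)
        sc = X.std(axis=0)
        sc[sc == 0] = 1.0
    else:
        mu = np.zeros(X.shape[1])
        sc = np.ones(X.shape[1])
    Z = (X - mu) / sc
    # R^2-based early stopping is undefined for zero-variance targets;
    # fall back to training-loss stopping there
    use_es = bool(np.any(Y.std(axis=0) > 0))
    model = MLPRegressor(
        hidden_layer_sizes=tuple(hidden_sizes),
        activation="logistic",
        solver="adam",
        batch_size=schedule.batch_size,
        learning_rate_init=schedule.learning_rate,
        max_iter=schedule.max_epochs,
        early_stopping=use_es,
        validation_fraction=schedule.validation_fraction,
        n_iter_no_change=schedule.patience,
        random_state=seed,
    )
    model.fit(Z, Y if Y.ndim > 1 else Y.ravel())
    return RegressionNet(model, mu, sc, tuple(hidden_sizes), seed,
                         list(model.loss_curve_), target_space)


@dataclass
class EvalReport:
    """Validation-set performance of a regression net."""

    correlations: np.ndarray     # per target dimension
    slopes: np.ndarray           # per target dimension
    per_shape_error: np.ndarray  # Euclidean error in target space
    mean_error: float
    normalized_error: float      # mean error / RMS norm of centered targets
    target_space: str

    def to_dict(self) -> dict:
        return {
            "correlations": self.correlations.tolist(),
            "slopes": self.slopes.tolist(),
            "mean_error": self.mean_error,
            "normalized_error": self.normalized_error,
            "target_space": self.target_space,
        }


def evaluate(net: RegressionNet, val_features: np.ndarray, val_targets: np.ndarray) -> EvalReport:
    """Per-dimension scatter statistics and per-shape Euclidean error.

    The headline scalar is the mean Euclidean error; the normalized
    variant divides by the RMS norm of the centered targets so spaces
    of different scale and dimension can be compared.
    """
    Y = np.asarray(val_targets, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    P = net.predict(val_features)
    d = Y.shape[1]
    corrs = np.zeros(d)
    slopes = np.zeros(d)
    for j in range(d):
        if np.std(P[:, j]) == 0 or np.std(Y[:, j]) == 0:
            corrs[j] = 0.0
            slopes[j] = 0.0
        else:
            corrs[j] = np.corrcoef(P[:, j], Y[:, j])[0, 1]
            slopes[j] = np.polyfit(Y[:, j], P[:, j], 1)[0]
    err = np.linalg.norm(P - Y, axis=1)
    rms = float(np.sqrt(np.mean(np.sum((Y - Y.mean(axis=0)) ** 2, axis=1))))
    return EvalReport(corrs, slopes, err, float(err.mean()),
                      float(err.mean() / rms), net.target_space)


# ---------------------------------------------------------------------------
# NEF-style population alternative
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocalKernelSpec:
    """Local receptive fields on the (n, n, c) feature grid: each neuron
    sees one channel over a patch_size x patch_size window."""

    grid_n: int = 16
    n_channels: int = 5
    patch_size: int = 4


@dataclass
class NEFPopulation:
    """Cosine-LIF hidden layer over local feature patches."""

    encoders: np.ndarray   # (n_neurons, n_features), sparse local patterns
    gains: np.ndarray
    biases: np.ndarray
    feature_scale: np.ndarray

    def rates(self, features: np.ndarray) -> np.ndarray:
        Z = np.asarray(features, dtype=float) / self.feature_scale
        I = Z @ self.encoders.T * self.gains + self.biases
        return lif_rate(I)


def train_nef_population(
    features: np.ndarray,
    targets: np.ndarray,
    n_neurons: int = 1000,
    kernel_spec: LocalKernelSpec = LocalKernelSpec(),
    seed: int = 0,
) -> tuple:
    """Random local-kernel LIF population plus optimal linear decoders.

    Each neuron's preferred direction is a random Gaussian pattern over
    one local patch of one feature channel (a local kernel); gains and
    biases are drawn as in standard NEF ensembles so thresholds tile the
    stimulus range.  Decoders come from regularized least squares.
    """
    X = np.asarray(features, dtype=float)
    rng = np.random.default_rng(seed)
    n_feat = X.shape[1]
    scale = np.sqrt(np.mean(X**2, axis=0))
    scale[scale == 0] = 1.0
    Z = X / scale

    gn, nc, ps = kernel_spec.grid_n, kernel_spec.n_channels, kernel_spec.patch_size
    enc = np.zeros((n_neurons, n_feat))
    for i in range(n_neurons):
        c = rng.integers(nc)
        r0 = rng.integers(gn - ps + 1)
        c0 = rng.integers(gn - ps + 1)
        kernel = rng.standard_normal((ps, ps))
        kernel /= np.linalg.norm(kernel)
        idx = [((r0 + u) * gn + (c0 + v)) * nc + c for u in range(ps) for v in range(ps)]
        enc[i, idx] = kernel.ravel()

    proj = Z @ enc.T
    proj_sd = proj.std(axis=0)
    proj_sd[proj_sd == 0] = 1.0
    # normalized projection ~ unit scale; tile intercepts in [-1, 1]
    intercepts = rng.uniform(-1.0, 1.0, n_neurons)
    max_rates = rng.uniform(100.0, 200.0, n_neurons)
    # invert the LIF rate to find the current at which max_rate is reached
    tau_ref, tau_rc = 0.005, 0.02
    I_at_max = 1.0 / (1.0 - np.exp((tau_ref - 1.0 / max_rates) / tau_rc))
    gains = (I_at_max - 1.0) / (1.0 - intercepts) / proj_sd
    biases = 1.0 - gains * intercepts * proj_sd

    pop = NEFPopulation(enc, gains, biases, scale)
    rates = pop.rates(X)
    dec = fit_decoders(rates, targets)
    return pop, dec


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Configuration for the end-to-end run (defaults are the
    desk-scale study conditions; the full-scale run uses n_shapes=40000
    with landmark Isomap)."""

    n_shapes: int = 4000
    seed: int = 0
    isomap_k: int = 10
    isomap_d: int = 8
    hidden_sizes: tuple = (600, 300)
    schedule: TrainingSchedule = field(default_factory=TrainingSchedule)
    targets: str = "isomap"  # isomap | superquadric | both
    out_dir: str = None

    def validate(self) -> None:
        if self.n_shapes < 1:
            raise ValueError("n_shapes must be >= 1")
        if self.isomap_d < 1 or self.isomap_k < 1:
            raise ValueError("isomap_d and isomap_k must be >= 1")
        if self.targets not in ("isomap", "superquadric", "both"):
            raise ValueError(f"unknown target space {self.targets!r}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Generate -> render -> features -> embed -> train -> evaluate.

    Returns a dict of in-memory artifacts; if ``config.out_dir`` is set,
    also writes the database CSV, evaluation reports (JSON) and a
    manifest with the seed and stage record.  Any stage failure aborts
    with an error naming the stage.
    """
    from . import embedding as emb_mod
    from . import features as feat_mod
    from . import render as render_mod
    from . import shapes as shapes_mod

    config.validate()
    artifacts: dict = {"config": config}
    stages = []

    def stage(name):
        stages.append(name)
        return name

    try:
        stage("generate")
        db = shapes_mod.sample_database(config.n_shapes, config.seed)
        artifacts["database"] = db

        stage("render")
        grid = render_mod.build_grid()
        depth = render_mod.render_many(db.shapes, grid)
        artifacts["depth"] = depth

        stage("features")
        F = feat_mod.feature_matrix(depth)
        artifacts["features"] = F

        stage("embed")
        deriv = F.reshape(len(db), -1, 5)[:, :, 1:].reshape(len(db), -1)
        embedding = emb_mod.isomap_fit(deriv, k=config.isomap_k, d=config.isomap_d)
        artifacts["embedding"] = embedding

        stage("train")
        tr, va = db.train_idx, db.val_idx
        reports = {}
        target_sets = {}
        if config.targets in ("isomap", "both"):
            target_sets["isomap"] = embedding.coordinates
        if config.targets in ("superquadric", "both"):
            target_sets["superquadric"] = np.stack(
                [shapes_mod.canonicalize(s).params for s in db.shapes])
        nets = {}
        for name, Y in target_sets.items():
            net = train_mlp(F[tr], Y[tr], config.hidden_sizes, config.seed,
                            config.schedule, target_space=name)
            nets[name] = net
            reports[name] = evaluate(net, F[va], Y[va])
        artifacts["nets"] = nets

        stage("evaluate")
        artifacts["reports"] = reports
        if "isomap" in reports:
            artifacts["histograms"] = emb_mod.distance_histograms(
                embedding.coordinates[va], reports["isomap"].per_shape_error)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stages[-1]!r}: {exc}") from exc

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        db.save(out / "database.csv", out / "database_meta.json")
        report_json = {k: v.to_dict() for k, v in artifacts["reports"].items()}
        (out / "reports.json").write_text(json.dumps(report_json, indent=2))
        manifest = {
            "seed": config.seed,
            "n_shapes": config.n_shapes,
            "stages": stages,
            "targets": config.targets,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return artifacts
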