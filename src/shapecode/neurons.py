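"""Neuron response models.

Three families of models live here:

* cosine-tuned leaky integrate-and-fire (LIF) neurons — the driving
  current is I = phi^T x + b for stimulus vector x and preferred
  direction phi, and the normalized LIF rate is
  r = 1 / (tau_ref - tau_rc * ln(1 - 1/I)) for I > 1, else 0.
  An optional Gaussian background-noise variant replaces the closed
  form with a simulated rate looked up from a (I, sigma) table, which
  smooths the threshold and can make the rate function sigmoidal or
  nearly linear;

* a nonlinear dendritic-branch model — 50 branches, each cosine-tuned
  to a small depth patch through a random linear kernel followed by a
  logistic sigmoid, with a least-squares readout obtained from a
  truncated-SVD pseudoinverse;

* linear population decoders in the Neural Engineering Framework (NEF)
  style — a decoding matrix Phi maps presynaptic rates to parameter
  estimates, and synaptic weights for any downstream cosine-tuned
  neuron compose exactly as w^T = phi^T Phi.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "CosineLIF", "drive_current", "lif_rate",
    "NoisyRateTable", "build_noisy_table", "noisy_rate",
    "DendriticModel", "make_dendritic_model", "dendritic_response",
    "fit_dendritic_readout",
    "DecoderSet", "fit_decoders", "compose_weights",
]

TAU_REF_DEFAULT = 0.005
TAU_RC_DEFAULT = 0.02


def lif_rate(I, tau_ref: float = TAU_REF_DEFAULT, tau_rc: float = TAU_RC_DEFAULT):
    """Normalized-LIF steady-state spike rate (spikes/s).

    Zero at and below the unit threshold, strictly increasing above it,
    and saturating at 1/tau_ref as I -> inf.
    """
    if tau_ref <= 0 or tau_rc <= 0:
        raise ValueError("time constants must be positive")
    I = np.asarray(I, dtype=float)
    out = np.zeros_like(I)
    above = I > 1.0
    with np.errstate(divide="ignore"):
        out[above] = 1.0 / (tau_ref - tau_rc * np.log1p(-1.0 / I[above]))
    return out if out.ndim else float(out)


@dataclass
class CosineLIF:
    """A cosine-tuned LIF neuron.

    phi is the preferred-direction vector (per-unit-stimulus current),
    b the bias current; sigma_noise = 0 selects the closed-form rate.
    """

    phi: np.ndarray
    b: float
    tau_rc: float = TAU_RC_DEFAULT
    tau_ref: float = TAU_REF_DEFAULT
    sigma_noise: float = 0.0

    def current(self, x: np.ndarray) -> np.ndarray:
        return drive_current(x, self)

    def rate(self, x: np.ndarray, table: "NoisyRateTable" = None) -> np.ndarray:
        I = self.current(x)
        if self.sigma_noise > 0:
            if table is None:
                raise ValueError("noisy neuron needs a NoisyRateTable")
            return noisy_rate(I, self.sigma_noise, table)
        return lif_rate(I, self.tau_ref, self.tau_rc)


def drive_current(x, neuron: CosineLIF):
    """Net driving current I = phi^T x + b.

    ``x`` may be a single stimulus vector or an (N, d) matrix.
    """
    x = np.asarray(x, dtype=float)
    phi = np.asarray(neuron.phi, dtype=float)
    if x.shape[-1] != phi.shape[0]:
        raise ValueError(
            f"stimulus dimension {x.shape[-1]} != preferred-direction dimension {phi.shape[0]}"
        )
    return x @ phi + neuron.b


# ---------------------------------------------------------------------------
# Noisy-LIF rate table
# ---------------------------------------------------------------------------

@dataclass
class NoisyRateTable:
    """Simulated spike rates on a (sigma, I) grid with bilinear lookup."""

    I_grid: np.ndarray
    sigma_grid: np.ndarray
    rates: np.ndarray  # (n_sigma, n_I)
    dt: float
    duration: float

    def __post_init__(self):
        self._interp = RegularGridInterpolator(
            (self.sigma_grid, self.I_grid), self.rates,
            method="linear", bounds_error=True,
        )


def build_noisy_table(
    I_grid=None,
    sigma_grid=None,
    dt: float = 1e-4,
    duration: float = 5.0,
    seed: int = 0,
    tau_rc: float = TAU_RC_DEFAULT,
    tau_ref: float = TAU_REF_DEFAULT,
) -> NoisyRateTable:
    """Simulate the noisy normalized LIF over a grid of currents and
    noise amplitudes.

    Per grid cell the membrane follows Euler steps of
    tau_rc * dV = (-V + I + sigma * xi) dt with iid standard-normal xi
    per step, unit threshold, reset to 0 and a tau_ref hold.  The same
    noise draws are shared across all cells (common random numbers), so
    rates are monotone in I along each row up to threshold-crossing
    discretization.
    """
    if I_grid is None:
        I_grid = np.arange(0.0, 4.0 + 1e-9, 0.05)
    if sigma_grid is None:
        sigma_grid = np.arange(0.0, 2.0 + 1e-9, 0.1)
    I_grid = np.asarray(I_grid, dtype=float)
    sigma_grid = np.asarray(sigma_grid, dtype=float)
    if np.any(np.diff(I_grid) <= 0) or np.any(np.diff(sigma_grid) <= 0):
        raise ValueError("grids must be strictly increasing")

    rng = np.random.default_rng(seed)
    nS, nI = len(sigma_grid), len(I_grid)
    I = np.broadcast_to(I_grid[None, :], (nS, nI))
    sig = np.broadcast_to(sigma_grid[:, None], (nS, nI))

    V = np.zeros((nS, nI))
    refrac = np.zeros((nS, nI))
    spikes = np.zeros((nS, nI))
    n_steps = int(round(duration / dt))
    a = dt / tau_rc
    xi_path = rng.standard_normal(n_steps)
    for step in range(n_steps):
        xi = xi_path[step]  # one shared noise path: rates couple monotonically in I
        dV = a * (-V + I + sig * xi)
        active = refrac <= 0
        V = np.where(active, V + dV, 0.0)
        refrac = np.maximum(refrac - dt, 0.0)
        fired = V >= 1.0
        spikes += fired
        V = np.where(fired, 0.0, V)
        refrac = np.where(fired, tau_ref, refrac)
    return NoisyRateTable(I_grid, sigma_grid, spikes / duration, dt, duration)


def noisy_rate(I, sigma: float, table: NoisyRateTable):
    """Bilinear lookup of the simulated rate at (I, sigma).

    Raises for queries outside the table grid.
    """
    scalar = np.ndim(I) == 0
    I = np.atleast_1d(np.asarray(I, dtype=float))
    pts = np.stack([np.full_like(I, sigma), I], axis=-1)
    out = table._interp(pts)
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# Nonlinear dendritic-branch model
# ---------------------------------------------------------------------------

def _sigmoid(u):
    return 1.0 / (1.0 + np.exp(-u))


@dataclass
class DendriticModel:
    """Branches cosine-tuned to a depth patch, sigmoid output per
    branch, linear readout across branches."""

    kernels: np.ndarray            # (n_branches, patch_size)
    weights: np.ndarray = None     # (n_branches,)
    n_singular: int = None

    @property
    def n_branches(self) -> int:
        return self.kernels.shape[0]

    def branch_outputs(self, stimuli: np.ndarray) -> np.ndarray:
        """(N, n_branches) sigmoid branch activations; ``stimuli`` is
        (N, patch_size) or a single flattened patch."""
        S = np.atleast_2d(np.asarray(stimuli, dtype=float).reshape(-1, self.kernels.shape[1]))
        return _sigmoid(S @ self.kernels.T)


def make_dendritic_model(n_branches: int = 50, patch_shape=(3, 3), seed: int = 0) -> DendriticModel:
    """Random standard-normal branch kernels (the 'preferred
    directions' of the branches)."""
    rng = np.random.default_rng(seed)
    return DendriticModel(rng.standard_normal((n_branches, int(np.prod(patch_shape)))))


def dendritic_response(stimulus, model: DendriticModel, rectify: bool = True):
    """Spike rate: weighted sum of sigmoid branch outputs, rectified at
    zero for reporting."""
    if model.weights is None:
        raise ValueError("model readout not fitted")
    r = model.branch_outputs(stimulus) @ model.weights
    if rectify:
        r = np.maximum(r, 0.0)
    return r if np.ndim(stimulus) > 1 else float(r[0])


def fit_dendritic_readout(
    stimuli: np.ndarray,
    target_rates: np.ndarray,
    n_singular: int = 14,
    model: DendriticModel = None,
    n_branches: int = 50,
    seed: int = 0,
) -> DendriticModel:
    """Least-squares readout weights via a truncated-SVD pseudoinverse.

    Exactly ``n_singular`` singular values are retained, regularizing
    the fit when stimuli are few relative to branches.
    """
    if model is None:
        patch = np.atleast_2d(stimuli).shape[1]
        model = make_dendritic_model(n_branches, (patch,), seed=seed)
    H = model.branch_outputs(stimuli)
    if n_singular > min(H.shape):
        raise ValueError(f"n_singular={n_singular} exceeds rank bound {min(H.shape)}")
    U, s, Vt = np.linalg.svd(H, full_matrices=False)
    k = n_singular
    w = Vt[:k].T @ ((U[:, :k].T @ np.asarray(target_rates, dtype=float)) / s[:k])
    model.weights = w
    model.n_singular = n_singular
    return model


# ---------------------------------------------------------------------------
# NEF decoding and weight composition
# ---------------------------------------------------------------------------

@dataclass
class DecoderSet:
    """Linear decoders: p_hat = Phi @ r_pre."""

    Phi: np.ndarray  # (d, n_neurons)

    def decode(self, rates: np.ndarray) -> np.ndarray:
        return np.asarray(rates, dtype=float) @ self.Phi.T


def fit_decoders(rates: np.ndarray, targets: np.ndarray, reg: float = None) -> DecoderSet:
    """Regularized least-squares decoders from population rates.

    Ridge parameter defaults to 0.1 x the mean diagonal of the Gram
    matrix (the NEF noise-term convention), which keeps decoders finite
    even for silent or duplicated neurons.
    """
    R = np.atleast_2d(np.asarray(rates, dtype=float))
    P = np.asarray(targets, dtype=float)
    if P.ndim == 1:
        P = P[:, None]
    G = R.T @ R
    if reg is None:
        reg = 0.1 * float(np.mean(np.diag(G)))
    if reg <= 0:
        reg = 1e-12  # silent population: decoders collapse to ~0 but stay finite
    Phi = np.linalg.solve(G + reg * np.eye(G.shape[0]), R.T @ P).T
    return DecoderSet(Phi)


def compose_weights(phi: np.ndarray, decoders: DecoderSet) -> np.ndarray:
    """Synaptic weights w^T = phi^T Phi for one postsynaptic neuron.

    By associativity w^T r_pre equals phi^T (Phi r_pre) exactly, so a
    cosine tuning curve over decoded parameters is realized directly in
    the weight matrix.
    """
    return decoders.Phi.T @ np.asarray(phi, dtype=float)
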