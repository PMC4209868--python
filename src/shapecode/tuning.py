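"""Augmented AIP tuning curves and cosine-LIF tuning-curve fitting.

Published AIP tuning curves contain fewer stimuli than even a simple
cosine-tuned neuron model has parameters.  Augmented tuning curves
extend a base shape-tuning profile (one rate per base shape) across the
36-stimulus shape x size x orientation grid using aggregate selectivity
assumptions: orientation tuning that is roughly Gaussian and fairly
narrow, and size responses that are either invariant or increase
monotonically with size.

Fitting minimizes the squared difference between target rates and
cosine-LIF model rates over the preferred direction phi, bias b, and
either the membrane constant tau_rc (noise-free mode) or the background
noise amplitude sigma (noisy mode, rates looked up from a simulation
table).  The problem is non-convex, so a bounded trust-region local
solver is restarted from many random initial points and the best fit is
kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from .neurons import (
    TAU_REF_DEFAULT,
    TAU_RC_DEFAULT,
    CosineLIF,
    NoisyRateTable,
    lif_rate,
    noisy_rate,
)
from .shapes import StimulusSet

__all__ = [
    "TuningCurve", "AugmentationSpec", "augment", "murata_archetypes",
    "FitResult", "fit_cosine_lif", "error_stats", "levene_test",
]


@dataclass
class TuningCurve:
    """Stimuli paired with target spike rates (one rate per stimulus)."""

    stimuli: object  # StimulusSet or an (N, d) feature matrix
    rates: np.ndarray

    def __post_init__(self):
        self.rates = np.asarray(self.rates, dtype=float)
        if np.any(self.rates < 0):
            raise ValueError("spike rates must be nonnegative")
        if len(self.rates) != len(self.stimuli):
            raise ValueError("one rate per stimulus required")


@dataclass(frozen=True)
class AugmentationSpec:
    """How a base shape-tuning profile extends over sizes and poses.

    size_mode 'invariant' keeps rates constant across sizes;
    'monotone' scales them linearly up to 1 at the largest size.
    Orientation tuning is Gaussian in the pose angle around the
    preferred orientation (axis-like, so distances wrap at 180 deg).
    """

    size_mode: str = "invariant"
    orientation_pref: int = 0          # index into the kept orientations
    orientation_sd_deg: float = 45.0
    baseline: float = 0.0              # spikes/s


def _orientation_distance_deg(psi_a: np.ndarray, psi_b: float) -> np.ndarray:
    d = np.rad2deg(np.abs(psi_a - psi_b))
    return np.minimum(d, 180.0 - d)


def augment(base_shape_rates, spec: AugmentationSpec, stimuli: StimulusSet) -> TuningCurve:
    """Extend per-shape base rates over the full stimulus grid.

    rate = baseline + (base - baseline) * size_factor * orient_factor,
    so the base-shape stimuli at the reference pose (preferred
    orientation, largest size) reproduce ``base_shape_rates`` exactly.
    """
    base = np.asarray(base_shape_rates, dtype=float)
    if np.any(base < 0):
        raise ValueError("base shape rates must be nonnegative")
    if len(base) != len(stimuli.shape_names):
        raise ValueError("one base rate per base shape required")

    amp = base[stimuli.shape_id] - spec.baseline
    if spec.size_mode == "invariant":
        size_factor = np.ones(len(stimuli))
    elif spec.size_mode == "monotone":
        scales = np.asarray(stimuli.sizes)
        size_factor = scales[stimuli.size_id] / scales.max()
    else:
        raise ValueError(f"unknown size_mode {spec.size_mode!r}")

    from .shapes import ORIENTATION_ANGLES

    psi = stimuli.orientation_angle
    psi_pref = ORIENTATION_ANGLES[spec.orientation_pref]
    d = _orientation_distance_deg(psi, psi_pref)
    orient_factor = np.exp(-0.5 * (d / spec.orientation_sd_deg) ** 2)

    rates = spec.baseline + amp * size_factor * orient_factor
    return TuningCurve(stimuli, np.maximum(rates, 0.0))


def murata_archetypes() -> dict:
    """Synthetic stand-ins for the published AIP shape-tuning profiles.

    Base rates (sphere, cube, plate, cylinder; spikes/s) are constructed
    to represent the selectivity classes described for object-type
    visual-dominant AIP neurons — e.g. one weakly responsive cell, one
    highly cylinder-selective, one broadly tuned with a cylinder
    preference, one responding to plates and cylinders but not cubes or
    spheres — not digitized from any figure.  Each profile is offered
    size-selective and size-invariant; the final archetype responds
    equally to cylinders and plates.
    """
    profiles = {
        1: [6.0, 4.0, 5.0, 8.0],        # low rates overall
        2: [20.0, 35.0, 15.0, 10.0],    # cube preference
        3: [5.0, 8.0, 12.0, 55.0],      # highly cylinder-selective
        4: [30.0, 18.0, 25.0, 40.0],    # broad, mild cylinder preference
        5: [15.0, 20.0, 30.0, 45.0],    # broad with cylinder preference
        6: [4.0, 6.0, 45.0, 50.0],      # plates + cylinders only
    }
    out = {}
    for k, rates in profiles.items():
        out[f"neuron{k}-size-selective"] = (
            rates, AugmentationSpec(size_mode="monotone", orientation_pref=0))
        out[f"neuron{k}-size-invariant"] = (
            rates, AugmentationSpec(size_mode="invariant", orientation_pref=0))
    # orientation selective, equal response to plates and cylinders
    out["plate-cylinder-equal"] = (
        [8.0, 10.0, 40.0, 40.0], AugmentationSpec(size_mode="invariant", orientation_pref=0))
    return out


# ---------------------------------------------------------------------------
# Cosine-LIF fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Outcome of a multistart cosine-LIF fit."""

    neuron: CosineLIF
    model_rates: np.ndarray
    errors: np.ndarray  # target - model
    error_mean: float
    error_sd: float
    n_restarts: int
    sse: float

    def to_dict(self) -> dict:
        return {
            "phi": self.neuron.phi.tolist(),
            "b": self.neuron.b,
            "tau_rc": self.neuron.tau_rc,
            "tau_ref": self.neuron.tau_ref,
            "sigma_noise": self.neuron.sigma_noise,
            "error_mean": self.error_mean,
            "error_sd": self.error_sd,
            "n_restarts": self.n_restarts,
        }


def _finish(curve, X, phi, b, tau_rc, sigma, table, n_restarts, sse):
    neuron = CosineLIF(phi, b, tau_rc=tau_rc, sigma_noise=sigma)
    if sigma > 0:
        I = np.clip(neuron.current(X), table.I_grid[0], table.I_grid[-1])
        model = noisy_rate(I, sigma, table)
    else:
        model = neuron.rate(X)
    errors = curve.rates - model
    return FitResult(
        neuron, model, errors,
        float(np.mean(errors)), float(np.std(errors, ddof=1)),
        n_restarts, float(sse),
    )


def fit_cosine_lif(
    curve: TuningCurve,
    stimulus_features: np.ndarray,
    n_restarts: int = 200,
    noise_mode: str = "off",
    table: NoisyRateTable = None,
    seed: int = 0,
    stop_sse: float = None,
) -> FitResult:
    """Least-squares cosine-LIF fit with random multistart.

    Noise off: optimize phi, b and tau_rc in [0.02, 0.2] s against the
    closed-form LIF rate.  Noise on: optimize phi, b and sigma with
    tau_rc = 0.02 s and tau_ref = 0.005 s fixed, rates interpolated from
    ``table``.  Features are standardized internally; the returned
    preferred direction is in original feature units.  ``stop_sse``
    optionally ends the restart loop early once the summed squared error
    falls below it (the best fit so far is always the one returned).
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    X = np.asarray(stimulus_features, dtype=float)
    y = curve.rates
    n, d = X.shape
    rng = np.random.default_rng(seed)

    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd

    noisy = noise_mode == "on"
    if noisy and table is None:
        raise ValueError("noise_mode='on' requires a NoisyRateTable")

    if noisy:
        sig_lo = max(float(table.sigma_grid[0]), 1e-6)
        sig_hi = float(table.sigma_grid[-1])
        I_lo, I_hi = float(table.I_grid[0]), float(table.I_grid[-1])

        def model_rates(p):
            I = np.clip(Z @ p[:d] + p[d], I_lo, I_hi)
            return noisy_rate(I, float(p[d + 1]), table)

        lb = np.r_[np.full(d, -np.inf), -np.inf, sig_lo]
        ub = np.r_[np.full(d, np.inf), np.inf, sig_hi]

        def draw():
            return np.r_[rng.standard_normal(d), rng.uniform(-2, 2),
                         rng.uniform(sig_lo, sig_hi)]
    else:

        def model_rates(p):
            return lif_rate(Z @ p[:d] + p[d], TAU_REF_DEFAULT, float(p[d + 1]))

        lb = np.r_[np.full(d, -np.inf), -np.inf, 0.02]
        ub = np.r_[np.full(d, np.inf), np.inf, 0.2]

        def draw():
            return np.r_[rng.standard_normal(d), rng.uniform(-2, 2),
                         rng.uniform(0.02, 0.2)]

    def residuals(p):
        return model_rates(p) - y

    best_p, best_sse = None, np.inf
    for _ in range(n_restarts):
        p0 = draw()
        try:
            res = least_squares(residuals, p0, bounds=(lb, ub), method="trf",
                                xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=400)
        except Exception:
            continue
        sse = float(2 * res.cost)
        if sse < best_sse:
            best_sse, best_p = sse, res.x
        if stop_sse is not None and best_sse < stop_sse:
            break

    p = best_p
    phi_z = p[:d]
    phi = phi_z / sd
    b = float(p[d] - np.sum(phi_z * mu / sd))
    if noisy:
        return _finish(curve, X, phi, b, TAU_RC_DEFAULT, float(p[d + 1]),
                       table, n_restarts, best_sse)
    return _finish(curve, X, phi, b, float(p[d + 1]), 0.0, None, n_restarts, best_sse)


def error_stats(fit: FitResult) -> tuple:
    """Sample mean and SD (n-1 denominator) of target - model errors."""
    return float(np.mean(fit.errors)), float(np.std(fit.errors, ddof=1))


def levene_test(*groups):
    """Classical Levene test (mean-centered) for equality of variances.

    Computes W as a one-way ANOVA F statistic on absolute deviations
    from group means; p comes from F(k-1, N-k).  Returns
    (W, p, (df1, df2)).  Raises if every group has zero within-group
    spread, where the statistic is undefined.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs at least 2 observations")
    k = len(groups)
    N = sum(len(g) for g in groups)
    Z = [np.abs(g - g.mean()) for g in groups]
    zbars = np.array([z.mean() for z in Z])
    zbar = np.concatenate(Z).mean()
    ss_between = sum(len(z) * (zb - zbar) ** 2 for z, zb in zip(Z, zbars))
    ss_within = sum(((z - zb) ** 2).sum() for z, zb in zip(Z, zbars))
    if ss_within == 0:
        if ss_between == 0:
            raise ValueError("Levene statistic undefined: no spread in any group")
        return float("inf"), 0.0, (k - 1, N - k)
    W = (N - k) / (k - 1) * ss_between / ss_within
    p = float(stats.f.sf(W, k - 1, N - k))
    return float(W), p, (k - 1, N - k)
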