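"""CIP-like feature extraction from depth maps.

CIP neurons are driven by depth and its first and second spatial
derivatives.  The feature stack therefore holds five channels per
shape — depth z, dz/dx, dz/dy, d2z/dx2, d2z/dy2 — each 16 x 16, for
1280 values in total.  Derivatives are approximated by correlating the
depth map with separable 3 x 3 kernels in grid-index space
([1 1 1]^T [1 0 -1] for the first derivative and [1 1 1]^T [0.5 -1 0.5]
for the second), with replicate padding; the sign convention is that
[1 0 -1] responds positively to depth decreasing with column index.

The module also provides the curved-surface stimulus family
z = (K1 x^2 + K2 y^2) / 2 together with the curvedness / shape-index
decomposition of its principal curvatures, the expanded quadratic
tuning variables (3 X^2 - 1)/2, and a 7-channel model of V3A disparity
tuning (five Gaussian channels for tuned near/zero/far cells and two
complementary sigmoidal near/far channels).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .render import DepthMap, OBJECT_DEPTH

__all__ = [
    "FeatureStack", "derivative_stack", "feature_matrix",
    "surface_depth", "CurvedSurfaceStimulus",
    "principal_curvature_x", "curvature_from_gradients",
    "curvedness", "shape_index",
    "legendre_expand", "V3AParams", "v3a_channels",
]

CHANNEL_NAMES = ("z", "dz/dx", "dz/dy", "d2z/dx2", "d2z/dy2")

_K_DX = np.outer([1.0, 1.0, 1.0], [1.0, 0.0, -1.0])
_K_DXX = np.outer([1.0, 1.0, 1.0], [0.5, -1.0, 0.5])


@dataclass
class FeatureStack:
    """Depth plus four derivative channels, shape (5, n, n)."""

    channels: np.ndarray
    channel_names: tuple = CHANNEL_NAMES

    @property
    def n(self) -> int:
        return self.channels.shape[-1]

    def flat(self) -> np.ndarray:
        """Row-major, channel-last flattening (n*n*5 values; 1280 for the
        default 16 x 16 grid).  This ordering is the fixed contract for
        network inputs."""
        return np.transpose(self.channels, (1, 2, 0)).ravel()


def _correlate(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    return ndimage.correlate(img, kernel, mode="nearest")


def derivative_stack(dm) -> FeatureStack:
    """Build the 5-channel CIP-like feature stack from a depth map.

    Accepts a :class:`~shapecode.render.DepthMap` or a bare 2D array.
    Kernels act on grid indices (x = column, y = row), matching how the
    16 x 16 maps are convolved directly; no warped-grid metric correction
    is applied.
    """
    z = dm.values if isinstance(dm, DepthMap) else np.asarray(dm, dtype=float)
    chans = np.stack([
        z,
        _correlate(z, _K_DX),
        _correlate(z, _K_DX.T),
        _correlate(z, _K_DXX),
        _correlate(z, _K_DXX.T),
    ])
    if not np.all(np.isfinite(chans)):
        raise ValueError("non-finite values in feature stack")
    return FeatureStack(chans)


def feature_matrix(depth_values: np.ndarray) -> np.ndarray:
    """Flattened feature stacks for a (N, n, n) stack of depth maps,
    returned as an (N, n*n*5) matrix."""
    return np.stack([derivative_stack(d).flat() for d in depth_values])


# ---------------------------------------------------------------------------
# Curved-surface stimuli and curvature formulas
# ---------------------------------------------------------------------------

def surface_depth(K1: float, K2: float, x, y):
    """Curved-surface stimulus depth profile z = (K1 x^2 + K2 y^2) / 2."""
    return 0.5 * (K1 * np.asarray(x) ** 2 + K2 * np.asarray(y) ** 2)


def curvature_from_gradients(zx, zxx):
    """Principal curvature along one axis from the first and second
    derivatives of depth: K = zxx / (1 + zx^2)^(3/2)."""
    return np.asarray(zxx) / (1.0 + np.asarray(zx) ** 2) ** 1.5


def principal_curvature_x(z_field: np.ndarray, spacing: float = 1.0) -> np.ndarray:
    """Principal curvature along x for a sampled depth field.

    At the center of a ``surface_depth`` stimulus dz/dx = 0, so the
    curvature reduces to the raw second derivative (Kx = K1 there).
    """
    zx = np.gradient(z_field, spacing, axis=1)
    zxx = np.gradient(zx, spacing, axis=1)
    return curvature_from_gradients(zx, zxx)


def curvedness(K1: float, K2: float) -> float:
    """Curvature magnitude C = sqrt((Kmax^2 + Kmin^2) / 2)."""
    kmax, kmin = max(K1, K2), min(K1, K2)
    return float(np.sqrt((kmax**2 + kmin**2) / 2.0))


def shape_index(K1: float, K2: float) -> float:
    """Shape index SI = (2/pi) arctan((Kmax + Kmin) / (Kmax - Kmin)).

    SI lives in [-1, 1]: -1 for a symmetric concavity, 0 for a saddle,
    +1 for a symmetric cap.  The symmetric case Kmax = Kmin is defined
    as the limit +/- 1 (0 for a flat surface).
    """
    kmax, kmin = max(K1, K2), min(K1, K2)
    if kmax == kmin:
        return float(np.sign(kmax))
    return float(2.0 / np.pi * np.arctan((kmax + kmin) / (kmax - kmin)))


@dataclass(frozen=True)
class CurvedSurfaceStimulus:
    """A curved-surface stimulus parameterized by its two curvatures.

    Rendered as a depth offset around the fixation depth so it can feed
    depth-based neuron models directly.
    """

    K1: float
    K2: float

    @property
    def C(self) -> float:
        return curvedness(self.K1, self.K2)

    @property
    def SI(self) -> float:
        return shape_index(self.K1, self.K2)

    def depth_patch(self, half_width: float = 0.05, n: int = 3,
                    fixation: float = OBJECT_DEPTH) -> np.ndarray:
        """Depth values on an n x n grid spanning +/- half_width meters."""
        ax = np.linspace(-half_width, half_width, n)
        X, Y = np.meshgrid(ax, ax)
        return fixation + surface_depth(self.K1, self.K2, X, Y)


# ---------------------------------------------------------------------------
# Expanded tuning variables and the V3A input model
# ---------------------------------------------------------------------------

def legendre_expand(stack: FeatureStack) -> FeatureStack:
    """Append the quadratic tuning variables (3 X^2 - 1)/2 and
    (3 Y^2 - 1)/2 computed from the second-derivative channels.

    These are the nonlinear functions of X and Y that linear readout
    from a population of neurons cosine-tuned to X and Y reconstructs
    most accurately, which motivates offering them as extra tuning
    variables.
    """
    X = stack.channels[3]
    Y = stack.channels[4]
    extra = np.stack([0.5 * (3.0 * X**2 - 1.0), 0.5 * (3.0 * Y**2 - 1.0)])
    return FeatureStack(
        np.concatenate([stack.channels, extra]),
        stack.channel_names + ("P2(d2z/dx2)", "P2(d2z/dy2)"),
    )


@dataclass(frozen=True)
class V3AParams:
    """Disparity-tuning channel parameters for the V3A input model.

    Centers straddle the fixation depth (tuned near / zero / far);
    sigmoid slopes are in 1/m and give complementary near/far channels
    that sum to one at every depth.
    """

    gaussian_centers: tuple = (0.65, 0.70, 0.75, 0.80, 0.85)
    gaussian_sd: float = 0.05
    sigmoid_center: float = OBJECT_DEPTH
    sigmoid_slope: float = 25.0


def v3a_channels(dm, params: V3AParams = V3AParams()) -> np.ndarray:
    """Apply the 7 pointwise V3A tuning functions to a depth map.

    Returns (7, n, n): five Gaussian channels then the near and far
    sigmoids.
    """
    z = dm.values if isinstance(dm, DepthMap) else np.asarray(dm, dtype=float)
    chans = [np.exp(-0.5 * ((z - c) / params.gaussian_sd) ** 2)
             for c in params.gaussian_centers]
    u = params.sigmoid_slope * (z - params.sigmoid_center)
    near = 1.0 / (1.0 + np.exp(u))
    chans += [near, 1.0 - near]
    return np.stack(chans)
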