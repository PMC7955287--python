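"""Signal field, flow vectors, spatial derivatives, and noisy sensing.

Particles broadcast their identity beliefs as a 4-channel chemical
signal that decays with a Gaussian kernel ``exp(-|dx|^2 / 2)`` in phase
space.  Rather than sensing raw intensities, each particle senses the
*flow vector* of every channel — the proportional intensity gradient
``grad(m) / m`` — which points at the intensity-weighted signal source
with magnitude equal to the weighted distance to it.  That magnitude is
the quantity the generative model holds priors over.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core_model import EnsembleState, N_IDENTITIES

__all__ = [
    "SensorySample",
    "FlowField",
    "signal_intensity",
    "flow_vectors",
    "flow_vectors_numeric",
    "spatial_flow_jacobian",
    "sense",
    "ensemble_flow",
    "ensemble_flow_jacobian",
    "saturate_magnitude",
    "effective_magnitude",
]


def saturate_magnitude(R: np.ndarray, r_sat: float) -> np.ndarray:
    """Sensor saturation ``r_sat * tanh(R / r_sat)`` for flow magnitudes.

    Keeps sensed distances bounded a little beyond the farthest distance
    the generative model represents; identity for ``r_sat = inf``.
    """
    if not np.isfinite(r_sat):
        return np.asarray(R, dtype=float)
    return r_sat * np.tanh(np.asarray(R, dtype=float) / r_sat)


def effective_magnitude(R: np.ndarray, m: np.ndarray, params) -> np.ndarray:
    """Flow magnitude as actually sensed: saturated, and defaulting to far.

    Raw magnitudes pass through the saturating nonlinearity; channels
    whose local intensity ``m`` falls below ``params.intensity_floor``
    blend smoothly toward ``r_sat``, so an empty channel reads as a
    source beyond sensing range rather than one at distance zero.
    """
    R = np.asarray(R, dtype=float)
    sat = saturate_magnitude(R, params.r_sat)
    floor = params.intensity_floor
    if floor <= 0 or not np.isfinite(params.r_sat):
        return sat
    alpha = m / (m + floor)
    return alpha * sat + (1.0 - alpha) * params.r_sat


@dataclass
class SensorySample:
    """One particle's sensory state: own-signal and flow magnitudes."""

    s_psi: np.ndarray  # (4,) sensed own emitter
    s_R: np.ndarray  # (4,) sensed flow-vector magnitudes


@dataclass
class FlowField:
    """Per-channel flow vectors (2, 4) and their magnitudes (4,)."""

    vectors: np.ndarray
    magnitudes: np.ndarray


def _kernel_weights(x: np.ndarray, queries: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise offsets and Gaussian weights from queries to sources.

    Returns ``diffs`` with shape (..., N, 2) where ``diffs[..., j, :]``
    is ``x_j - query``, and weights ``exp(-|diffs|^2 / 2)`` of shape
    (..., N).
    """
    diffs = x - queries[..., None, :]
    w = np.exp(-0.5 * np.einsum("...jd,...jd->...j", diffs, diffs))
    return diffs, w


def signal_intensity(
    ensemble: EnsembleState,
    query: np.ndarray,
    exclude: Optional[int] = None,
) -> np.ndarray:
    """Local 4-channel signal intensity at one or many query points.

    ``m_k = sum_j a_psi[j, k] * exp(-|x_j - query|^2 / 2)``, summed over
    all particles, optionally excluding one emitter (used when a particle
    evaluates the field it does not itself generate).
    """
    query = np.asarray(query, dtype=float)
    _, w = _kernel_weights(ensemble.x, query)
    if exclude is not None:
        w = w.copy()
        w[..., exclude] = 0.0
    return w @ ensemble.a_psi


def flow_vectors(ensemble: EnsembleState, i: int) -> FlowField:
    """Closed-form flow vectors sensed by particle ``i``.

    Per channel k the flow vector is the emitter-weighted mean offset to
    the other particles,

        R_k = sum_{j != i} dx_j * a_psi[j, k] * w_j / (m_k + eps),

    with ``w_j`` the Gaussian kernel weight and ``m_k`` the (self
    excluded) channel intensity.  It points at the intensity-weighted
    source; its norm is the weighted distance to that source.
    """
    n = ensemble.n
    if not -n <= i < n:
        raise IndexError(f"particle index {i} out of range for N={n}")
    vec, mag, _ = ensemble_flow(ensemble)
    return FlowField(vectors=vec[i], magnitudes=mag[i])


def ensemble_flow(ensemble: EnsembleState) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flow vectors for every particle at once (self-excluded).

    Returns ``vectors`` (N, 2, 4), raw ``magnitudes`` (N, 4), and the
    self-excluded channel ``intensities`` (N, 4) at each particle.
    """
    diffs, w = _kernel_weights(ensemble.x, ensemble.x)  # (N, N, 2), (N, N)
    np.fill_diagonal(w, 0.0)
    a = ensemble.a_psi
    m = w @ a  # (N, 4)
    num = np.einsum("ijd,ij,jk->idk", diffs, w, a)  # (N, 2, 4)
    vec = num / (m[:, None, :] + ensemble.params.eps_reg)
    mag = np.linalg.norm(vec, axis=1)
    return vec, mag, m


def _magnitudes_at(
    ensemble: EnsembleState,
    queries: np.ndarray,
    exclude: np.ndarray,
    effective: bool = False,
) -> np.ndarray:
    """Flow magnitudes at query points (M, P, 2), row r excluding particle exclude[r]."""
    diffs, w = _kernel_weights(ensemble.x, queries)  # (M, P, N, 2), (M, P, N)
    rows = np.arange(queries.shape[0])
    w[rows, :, exclude] = 0.0
    a = ensemble.a_psi
    m = w @ a  # (M, P, 4)
    num = np.einsum("ipjd,ipj,jk->ipdk", diffs, w, a)
    vec = num / (m[:, :, None, :] + ensemble.params.eps_reg)
    mag = np.linalg.norm(vec, axis=2)  # (M, P, 4)
    if effective:
        mag = effective_magnitude(mag, m, ensemble.params)
    return mag


def flow_vectors_numeric(ensemble: EnsembleState, i: int, h: float) -> np.ndarray:
    """Brute-force flow vectors via central differences of ``grad(m)/m``.

    Evaluates the (self-excluded) intensity field around ``x_i`` and
    forms the proportional gradient numerically.  Serves as the
    independent oracle for :func:`flow_vectors`.
    """
    if h <= 0:
        raise ValueError("finite-difference step h must be > 0")
    x0 = ensemble.x[i]
    m0 = signal_intensity(ensemble, x0, exclude=i)
    grad = np.empty((2, N_IDENTITIES))
    for d in range(2):
        e = np.zeros(2)
        e[d] = h
        m_plus = signal_intensity(ensemble, x0 + e, exclude=i)
        m_minus = signal_intensity(ensemble, x0 - e, exclude=i)
        grad[d] = (m_plus - m_minus) / (2.0 * h)
    return grad / (m0 + ensemble.params.eps_reg)


def spatial_flow_jacobian(ensemble: EnsembleState, i: int, h: Optional[float] = None) -> np.ndarray:
    """Derivative (2, 4) of raw flow magnitudes w.r.t. particle i's position.

    Central finite differences with step ``h`` (default
    ``params.fd_step``); validated against the exact two-particle case
    where the magnitude is the inter-particle distance.
    """
    if h is None:
        h = ensemble.params.fd_step
    if h <= 0:
        raise ValueError("finite-difference step h must be > 0")
    jac = ensemble_flow_jacobian(ensemble, h, indices=np.array([i]), effective=False)
    return jac[0]


def ensemble_flow_jacobian(
    ensemble: EnsembleState,
    h: Optional[float] = None,
    indices: Optional[np.ndarray] = None,
    effective: bool = True,
) -> np.ndarray:
    """Spatial flow-magnitude Jacobians (N, 2, 4) for all particles.

    With ``effective`` (the default used by the dynamics) the derivative
    is taken through the sensor model (saturation and empty-channel
    floor), so unsensed channels exert no force.
    """
    if h is None:
        h = ensemble.params.fd_step
    offsets = np.array([[h, 0.0], [-h, 0.0], [0.0, h], [0.0, -h]])
    if indices is None:
        indices = np.arange(ensemble.n)
    x = ensemble.x[indices]
    queries = x[:, None, :] + offsets[None, :, :]  # (M, 4, 2)
    mags = _magnitudes_at(ensemble, queries, exclude=indices, effective=effective)
    jac = np.stack(
        [
            (mags[:, 0] - mags[:, 1]) / (2.0 * h),
            (mags[:, 2] - mags[:, 3]) / (2.0 * h),
        ],
        axis=1,
    )  # (M, 2, 4)
    return jac


def sense(
    ensemble: EnsembleState,
    i: int,
    rng: Optional[np.random.Generator] = None,
) -> SensorySample:
    """Noisy sensory sample of particle ``i``.

    The particle senses its own emitter and the (saturated) flow
    magnitudes, each corrupted by Gaussian fluctuations of variance
    ``1 / precision`` per channel (no noise on zero-precision channels,
    nor when the model is in its noise-free limit).
    """
    n = ensemble.n
    if not -n <= i < n:
        raise IndexError(f"particle index {i} out of range for N={n}")
    vec, mag, m = ensemble_flow(ensemble)
    s_psi = ensemble.a_psi[i].copy()
    s_R = effective_magnitude(mag[i], m[i], ensemble.params)
    p = ensemble.params
    if not p.noise_free:
        if rng is None:
            raise ValueError("rng required unless params.noise_free is set")
        s_psi = s_psi + _noise(rng, p.prec_psi_vec)
        s_R = s_R + _noise(rng, p.prec_R_vec)
    return SensorySample(s_psi=s_psi, s_R=s_R)


def _noise(rng: np.random.Generator, prec: np.ndarray, shape: Optional[tuple] = None) -> np.ndarray:
    shape = prec.shape if shape is None else shape
    std = np.where(prec > 0, 1.0 / np.sqrt(np.where(prec > 0, prec, 1.0)), 0.0)
    return rng.standard_normal(shape) * std
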