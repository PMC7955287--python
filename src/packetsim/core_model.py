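"""Shared generative model and belief geometry.

Every particle ("neuron") carries the same generative model of what it
expects to sense given its identity.  Identities live on a 4-simplex with
fixed role semantics:

    index 0  ``internal_A``  internal state of superordinate ensemble A
    index 1  ``blanket_A``   blanket state of ensemble A
    index 2  ``blanket_B``   blanket state of ensemble B
    index 3  ``internal_B``  internal state of ensemble B

Beliefs are parameterised by a log-evidence vector ``mu`` in R^4; the
belief distribution is ``psi = softmax(mu)``.  The model's distance prior
is a 4x4 template of expected flow-vector magnitudes: identity *i*
expects the channel-*k* signal source at distance ``template[i, k]``
(either ``D`` or ``2 D``), which encodes the compatibility of spatial
proximity between the four roles and hence the blanket structure of the
superordinate ensembles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.special import softmax as _softmax

__all__ = [
    "GenerativeModelParams",
    "ParticleState",
    "EnsembleState",
    "build_distance_template",
    "softmax_beliefs",
    "belief_jacobian",
    "expected_flow",
    "init_ensemble",
]

N_IDENTITIES = 4
SIMPLEX_ATOL = 1e-9


def build_distance_template(D: float) -> np.ndarray:
    """Expected flow magnitudes per (own identity, sensed channel).

    Row = own identity, column = sensed signal channel.  Internal states
    of one ensemble expect the opposing ensemble at distance ``2 D``;
    blanket states tolerate proximity (``D``) to the opposing blanket.

    Parameters
    ----------
    D : float
        Length scale of the proximity prior, in phase-space (kernel) units.
    """
    D = float(D)
    if not np.isfinite(D) or D < 0:
        raise ValueError(f"distance scale D must be finite and >= 0, got {D}")
    return np.array(
        [
            [D, D, 2 * D, 2 * D],
            [D, D, D, 2 * D],
            [2 * D, D, D, D],
            [2 * D, 2 * D, D, D],
        ]
    )


@dataclass
class GenerativeModelParams:
    """Parameters of the shared generative model.

    Attributes
    ----------
    D : float
        Proximity length scale (phase-space units).  The signalling
        kernel ``exp(-|dx|^2 / 2)`` has unit scale, so ``D`` is measured
        in kernel units.
    prec_R : float or (4,) array
        Sensory precision (inverse variance) of flow-magnitude channels.
    prec_psi : float or (4,) array
        Precision of the self-sensed emitter signal.
    prec_mu : float
        Evidence-decay precision: log evidence leaks at rate
        ``prec_mu * mu``.
    prec_x : float
        Friction precision; fixed at 0 (friction neglected).
    lambda_smooth : float
        Autocorrelation of fluctuations; scales the second-order
        (acceleration) term of the motion update.
    stim_gain : float
        Evidence-injection gain kappa (log-evidence per unit time) of the
        external stimulus drive.
    eps_reg : float
        Regulariser added to channel intensities before division — a
        pure 0/0 guard for channels with exactly zero mass.  Kept far
        below any physical intensity so it never biases the sensed
        magnitude (the two-particle magnitude equals the distance to
        1e-10 even for near-vertex beliefs).
    fd_step : float
        Central-difference step used for spatial flow derivatives.
    noise_free : bool
        When True, all Gaussian fluctuations are suppressed (the
        infinite-precision limit); used for fixed-point analysis.
    diagonal_jacobian : bool
        Use the diagonal shorthand ``diag(psi * (1 - psi))`` for the
        softmax derivative instead of the full Jacobian.
    emitter_noise_std : bool
        Scale emitter noise by ``1/sqrt(prec_psi)`` (standard-deviation
        convention) instead of the default precision scaling.
    r_sat : float, optional
        Sensor-saturation scale for flow magnitudes: magnitudes are
        sensed through ``r_sat * tanh(R / r_sat)``.  Defaults to
        ``2.12 * D``, just beyond the farthest distance (``2 D``) the
        distance priors represent, so sources beyond the kernel's reach
        read as "far" instead of injecting unbounded gradients, and the
        internal/blanket belief crossovers sit comfortably outside the
        blanket-test interaction radius.  Set to ``inf`` to sense raw
        magnitudes.
    intensity_floor : float
        Channel intensity below which the sensed magnitude blends
        toward ``r_sat``, making a channel with no appreciable signal
        read as maximally far rather than as a source at distance zero.
        Off (0) by default: the blanket rings at ensemble interfaces
        are sustained by weak residual emitters, and treating
        low-intensity channels as far destabilises them.
    mu_max : float
        Evidence saturation: bound on the ensemble-membership contrast
        (the gap between the ensemble-A and ensemble-B pair means of the
        log evidence) and on the within-pair role contrasts.  Saturating
        the membership contrast bounds the hysteresis of A/B beliefs, so
        a relocated stimulus can reverse them within a few tens of
        steps; the within-pair differences that carry the
        internal-vs-blanket structure are preserved exactly up to the
        same bound.  At the default 15 beliefs are decisive (residual
        ~ 1e-13 across ensembles).
    """

    D: float = 1.25
    prec_R: float | np.ndarray = 2.0
    prec_psi: float | np.ndarray = 0.05
    prec_mu: float = 0.10
    prec_x: float = 0.0
    lambda_smooth: float = 0.3
    stim_gain: float = 8.0
    eps_reg: float = 1e-300
    fd_step: float = 1e-5
    noise_free: bool = False
    diagonal_jacobian: bool = False
    emitter_noise_std: bool = False
    r_sat: Optional[float] = None
    intensity_floor: float = 0.0
    mu_max: float = 15.0
    distance_template: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.r_sat is None:
            self.r_sat = 2.12 * self.D
        if self.r_sat <= 0:
            raise ValueError("r_sat must be > 0 (use inf to disable saturation)")
        if self.intensity_floor < 0:
            raise ValueError("intensity_floor must be >= 0")
        if self.mu_max <= 0:
            raise ValueError("mu_max must be > 0 (use inf to disable)")
        if self.distance_template is None:
            self.distance_template = build_distance_template(self.D)
        else:
            self.distance_template = np.asarray(self.distance_template, dtype=float)
            self._check_template()
        if self.eps_reg <= 0:
            raise ValueError("eps_reg must be > 0")
        if self.fd_step <= 0:
            raise ValueError("fd_step must be > 0")
        if self.prec_x != 0:
            raise ValueError("friction is neglected: prec_x must be 0")
        for name in ("prec_R", "prec_psi", "prec_mu"):
            if np.any(np.asarray(getattr(self, name)) < 0):
                raise ValueError(f"{name} must be non-negative")

    def _check_template(self) -> None:
        T = self.distance_template
        if T.shape != (N_IDENTITIES, N_IDENTITIES):
            raise ValueError("distance_template must be 4x4")
        if not np.allclose(T, T.T):
            raise ValueError("distance_template must be symmetric")
        if not np.allclose(np.diag(T), self.D):
            raise ValueError("distance_template diagonal must equal D")

    @property
    def prec_R_vec(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.prec_R, dtype=float), (N_IDENTITIES,))

    @property
    def prec_psi_vec(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.prec_psi, dtype=float), (N_IDENTITIES,))

    def to_dict(self) -> dict:
        return {
            "D": self.D,
            "prec_R": np.asarray(self.prec_R).tolist(),
            "prec_psi": np.asarray(self.prec_psi).tolist(),
            "prec_mu": self.prec_mu,
            "prec_x": self.prec_x,
            "lambda_smooth": self.lambda_smooth,
            "stim_gain": self.stim_gain,
            "eps_reg": self.eps_reg,
            "fd_step": self.fd_step,
            "noise_free": self.noise_free,
            "diagonal_jacobian": self.diagonal_jacobian,
            "emitter_noise_std": self.emitter_noise_std,
            "r_sat": self.r_sat,
            "intensity_floor": self.intensity_floor,
            "mu_max": self.mu_max,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GenerativeModelParams":
        d = dict(d)
        for key in ("prec_R", "prec_psi"):
            if key in d and isinstance(d[key], list):
                v = np.asarray(d[key], dtype=float)
                d[key] = float(v) if v.ndim == 0 else v
        return cls(**d)

    def copy(self, **changes) -> "GenerativeModelParams":
        if "D" in changes and "distance_template" not in changes:
            changes["distance_template"] = None
        return replace(self, **changes)


@dataclass
class ParticleState:
    """State of a single agent: position, log evidence, chemical emitter."""

    x: np.ndarray  # (2,) position in phase space
    mu: np.ndarray  # (4,) log evidence for each identity
    a_psi: np.ndarray  # (4,) chemical-emitter signal

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        self.a_psi = np.asarray(self.a_psi, dtype=float)
        for arr, nm in ((self.x, "x"), (self.mu, "mu"), (self.a_psi, "a_psi")):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite {nm} in ParticleState")

    @property
    def psi(self) -> np.ndarray:
        return softmax_beliefs(self.mu)


@dataclass
class EnsembleState:
    """All particle states at one time index, stored as arrays.

    ``x`` is (N, 2), ``mu`` and ``a_psi`` are (N, 4).  Array storage keeps
    the field computations vectorised; :meth:`particle` gives a per-agent
    view when one is needed.
    """

    x: np.ndarray
    mu: np.ndarray
    a_psi: np.ndarray
    t: int
    params: GenerativeModelParams

    def __post_init__(self) -> None:
        self.x = np.atleast_2d(np.asarray(self.x, dtype=float))
        self.mu = np.atleast_2d(np.asarray(self.mu, dtype=float))
        self.a_psi = np.atleast_2d(np.asarray(self.a_psi, dtype=float))
        n = self.x.shape[0]
        if n < 2:
            raise ValueError("an ensemble needs at least 2 particles")
        if self.x.shape != (n, 2) or self.mu.shape != (n, N_IDENTITIES) \
                or self.a_psi.shape != (n, N_IDENTITIES):
            raise ValueError("inconsistent ensemble array shapes")
        if self.t < 0:
            raise ValueError("time index must be non-negative")

    @property
    def n(self) -> int:
        return self.x.shape[0]

    @property
    def psi(self) -> np.ndarray:
        """Belief distributions, (N, 4)."""
        return softmax_beliefs(self.mu)

    def particle(self, i: int) -> ParticleState:
        return ParticleState(self.x[i], self.mu[i], self.a_psi[i])

    @classmethod
    def from_particles(
        cls, particles: Sequence[ParticleState], t: int, params: GenerativeModelParams
    ) -> "EnsembleState":
        return cls(
            x=np.stack([p.x for p in particles]),
            mu=np.stack([p.mu for p in particles]),
            a_psi=np.stack([p.a_psi for p in particles]),
            t=t,
            params=params,
        )

    def copy(self) -> "EnsembleState":
        return EnsembleState(
            self.x.copy(), self.mu.copy(), self.a_psi.copy(), self.t, self.params
        )


def saturate_evidence(mu: np.ndarray, mu_max: float) -> np.ndarray:
    """Structured log-evidence saturation.

    Decomposes ``mu`` (shift-invariantly) into the ensemble-membership
    contrast ``h`` — half the gap between the pair means of identities
    (1, 2) and (3, 4) — and the two within-pair role contrasts, clips
    each at ``mu_max``, and recomposes around a zero mean.  Clipping the
    membership contrast bounds belief hysteresis without touching the
    internal-vs-blanket structure.
    """
    mu = np.asarray(mu, dtype=float)
    if not np.isfinite(mu_max):
        return mu
    m_a = 0.5 * (mu[..., 0] + mu[..., 1])
    m_b = 0.5 * (mu[..., 2] + mu[..., 3])
    h = np.clip(0.5 * (m_a - m_b), -mu_max, mu_max)
    d_a = np.clip(mu[..., 0] - mu[..., 1], -mu_max, mu_max)
    d_b = np.clip(mu[..., 2] - mu[..., 3], -mu_max, mu_max)
    return np.stack(
        [h + 0.5 * d_a, h - 0.5 * d_a, -h + 0.5 * d_b, -h - 0.5 * d_b],
        axis=-1,
    )


def softmax_beliefs(mu: np.ndarray) -> np.ndarray:
    """Map log evidence to a belief distribution on the simplex.

    Works on a single (4,) vector or a batch (..., 4); invariant to
    adding a constant to ``mu``.
    """
    mu = np.asarray(mu, dtype=float)
    if not np.all(np.isfinite(mu)):
        raise ValueError("mu must be finite")
    return _softmax(mu, axis=-1)


def _check_simplex(psi: np.ndarray, atol: float = SIMPLEX_ATOL) -> np.ndarray:
    psi = np.asarray(psi, dtype=float)
    if psi.shape[-1] != N_IDENTITIES:
        raise ValueError("beliefs must have 4 components")
    if np.any(psi < -atol) or np.any(np.abs(psi.sum(axis=-1) - 1.0) > atol):
        raise ValueError("beliefs are off the probability simplex")
    return psi


def belief_jacobian(psi: np.ndarray) -> np.ndarray:
    """Derivative of the softmax map, ``d psi / d mu = diag(psi) - psi psi^T``.

    Symmetric, positive semidefinite, rows sum to zero.  Batched: (..., 4)
    beliefs give (..., 4, 4) Jacobians.
    """
    psi = _check_simplex(psi)
    eye = np.eye(N_IDENTITIES)
    return psi[..., :, None] * (eye - psi[..., None, :])


def diagonal_belief_jacobian(psi: np.ndarray) -> np.ndarray:
    """Diagonal shorthand ``diag(psi * (1 - psi))`` for the softmax slope."""
    psi = _check_simplex(psi)
    d = psi * (1.0 - psi)
    return d[..., :, None] * np.eye(N_IDENTITIES)


def expected_flow(psi: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Bayesian model average of identity-conditional flow expectations.

    ``R_k = sum_i psi_i * template[i, k]`` — the belief-weighted mixture
    of the per-identity distance expectations.  Batched over leading axes.
    """
    psi = _check_simplex(psi)
    template = np.asarray(template, dtype=float)
    if template.shape != (N_IDENTITIES, N_IDENTITIES):
        raise ValueError("template must be 4x4")
    return psi @ template


def init_ensemble(config, rng: np.random.Generator) -> EnsembleState:
    """Build the initial ensemble for a simulation.

    All particles start with uniform beliefs (``mu = 0``) and emitters
    equal to their beliefs.  Positions come from the configured
    initialiser: ``uniform`` scatters particles in a centred square box,
    ``grid`` places them on a deterministic lattice (for tests).
    """
    n = int(config.N)
    if n < 2:
        raise ValueError("config.N must be >= 2")
    init = dict(config.init)
    kind = init.get("kind", "uniform")
    box = float(init.get("box_size", default_box_size(n)))
    half = box / 2.0
    if kind == "uniform":
        x = rng.uniform(-half, half, size=(n, 2))
    elif kind == "grid":
        side = int(np.ceil(np.sqrt(n)))
        lin = np.linspace(-half, half, side)
        xx, yy = np.meshgrid(lin, lin)
        x = np.column_stack([xx.ravel(), yy.ravel()])[:n]
    else:
        raise ValueError(f"unknown initializer kind {kind!r}")
    mu = np.zeros((n, N_IDENTITIES))
    a_psi = softmax_beliefs(mu)
    return EnsembleState(x=x, mu=mu, a_psi=a_psi, t=0, params=config.model)


def default_box_size(n: int, spacing: float = 1.0) -> float:
    """Box side giving mean nearest-neighbour spacing ~ ``spacing``.

    For a uniform scatter of n points in a square of side L the mean
    nearest-neighbour distance is about ``L / (2 sqrt(n))``.
    """
    return 2.0 * spacing * float(np.sqrt(n))
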