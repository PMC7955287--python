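"""Prediction-error flows and the time-stepping loop.

Perception and action both descend precision-weighted prediction errors
(a first-order reduction of the variational free-energy gradient flows):

* log evidence:   ``mu_dot = J (T Pi_R eps_R) + J (Pi_psi eps_psi)
  - Pi_mu mu + drive``, with ``J`` the softmax Jacobian and ``T`` the
  distance template, so beliefs move toward identities whose distance
  expectations better explain the sensed flow magnitudes;
* emitter:        reset each step to the current belief plus a
  precision-scaled Gaussian increment (a minimal memory);
* motion:         ``x_dot = -grad(R) . (Pi_R eps_R)`` descends the
  flow-magnitude error in space, with a second-order correction
  ``x_ddot = grad(R) . (lambda Pi_R R_dot)``.

States update synchronously from the time-t field with the Taylor step
``x += x_dot dt + x_ddot dt^2 / 2``, ``mu += mu_dot dt``.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .core_model import (
    EnsembleState,
    GenerativeModelParams,
    belief_jacobian,
    diagonal_belief_jacobian,
    expected_flow,
    init_ensemble,
    saturate_evidence,
    softmax_beliefs,
)
from .field_signaling import (
    SensorySample,
    _noise,
    effective_magnitude,
    ensemble_flow,
    ensemble_flow_jacobian,
)
from .stimulus import StimulusProtocol

__all__ = [
    "RateBundle",
    "Trajectory",
    "IntegrationError",
    "prediction_errors",
    "belief_rate",
    "emitter_update",
    "motion_rates",
    "step",
    "run",
    "free_energy_proxy",
]


class IntegrationError(RuntimeError):
    """The state became non-finite during integration."""


@dataclass
class RateBundle:
    """Instantaneous rates and errors for one particle."""

    mu_dot: np.ndarray
    a_dot: np.ndarray
    x_dot: np.ndarray
    x_ddot: np.ndarray
    eps_psi: np.ndarray
    eps_R: np.ndarray


@dataclass
class Trajectory:
    """Time-ordered ensemble snapshots plus the config that produced them."""

    snapshots: list
    config: SimulationConfig
    seed: int
    wall_clock: float = 0.0

    @property
    def times(self) -> np.ndarray:
        return np.array([s.t for s in self.snapshots])

    def __len__(self) -> int:
        return len(self.snapshots)

    def to_dataframe(self) -> pd.DataFrame:
        """Flat per-snapshot table: t, particle, position, mu, psi, a_psi."""
        rows = []
        for snap in self.snapshots:
            psi = snap.psi
            n = snap.n
            block = {
                "t": np.full(n, snap.t),
                "particle": np.arange(n),
                "x1": snap.x[:, 0],
                "x2": snap.x[:, 1],
            }
            for k in range(4):
                block[f"mu{k + 1}"] = snap.mu[:, k]
            for k in range(4):
                block[f"psi{k + 1}"] = psi[:, k]
            for k in range(4):
                block[f"a_psi{k + 1}"] = snap.a_psi[:, k]
            rows.append(pd.DataFrame(block))
        return pd.concat(rows, ignore_index=True)

    def save(self, directory) -> None:
        from pathlib import Path
        import json

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.to_dataframe().to_csv(directory / "trajectory.csv", index=False)
        manifest = {
            "config": self.config.to_dict(),
            "seed": self.seed,
            "wall_clock_s": self.wall_clock,
            "snapshots": len(self.snapshots),
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")

    @classmethod
    def load(cls, directory) -> "Trajectory":
        from pathlib import Path
        import json

        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        config = SimulationConfig.from_dict(manifest["config"])
        df = pd.read_csv(directory / "trajectory.csv")
        snapshots = []
        for t, grp in df.groupby("t", sort=True):
            grp = grp.sort_values("particle")
            snapshots.append(
                EnsembleState(
                    x=grp[["x1", "x2"]].to_numpy(),
                    mu=grp[[f"mu{k}" for k in range(1, 5)]].to_numpy(),
                    a_psi=grp[[f"a_psi{k}" for k in range(1, 5)]].to_numpy(),
                    t=int(t),
                    params=config.model,
                )
            )
        return cls(snapshots=snapshots, config=config, seed=manifest["seed"],
                   wall_clock=manifest.get("wall_clock_s", 0.0))


def prediction_errors(
    sample: SensorySample, psi: np.ndarray, R_expected: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Sensory prediction errors: sensed minus expected, per channel."""
    eps_psi = np.asarray(sample.s_psi, dtype=float) - psi
    eps_R = np.asarray(sample.s_R, dtype=float) - R_expected
    return eps_psi, eps_R


def _jacobian(psi: np.ndarray, params: GenerativeModelParams) -> np.ndarray:
    if params.diagonal_jacobian:
        return diagonal_belief_jacobian(psi)
    return belief_jacobian(psi)


def belief_rate(
    errors: tuple[np.ndarray, np.ndarray],
    mu: np.ndarray,
    params: GenerativeModelParams,
    stim_drive: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Rate of change of log evidence.

    Gradient ascent on model evidence: prediction errors are pulled back
    through the softmax Jacobian (``grad_mu R = J T``, ``grad_mu psi =
    J``), log evidence leaks at rate ``prec_mu``, and the stimulus adds
    its drive directly in log-evidence space.  Batched over particles.
    """
    eps_psi, eps_R = errors
    mu = np.asarray(mu, dtype=float)
    psi = softmax_beliefs(mu)
    J = _jacobian(psi, params)
    T = params.distance_template
    v = (params.prec_R_vec * eps_R) @ T.T + params.prec_psi_vec * eps_psi
    mu_dot = np.einsum("...ij,...j->...i", J, v) - params.prec_mu * mu
    if stim_drive is not None:
        mu_dot = mu_dot + stim_drive
    return mu_dot


def emitter_update(
    psi: np.ndarray,
    params: GenerativeModelParams,
    rng: Optional[np.random.Generator],
    dt: float,
) -> np.ndarray:
    """Next emitter value: current belief plus a noisy increment.

    The default follows the update ``a = psi + prec_psi * Omega * dt``
    with standard-normal ``Omega``; set ``params.emitter_noise_std`` to
    scale by ``1/sqrt(prec_psi)`` instead.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    psi = np.asarray(psi, dtype=float)
    if params.noise_free:
        return psi.copy()
    if rng is None:
        raise ValueError("rng required unless params.noise_free is set")
    prec = params.prec_psi_vec
    omega = rng.standard_normal(psi.shape)
    if params.emitter_noise_std:
        scale = np.where(prec > 0, 1.0 / np.sqrt(np.where(prec > 0, prec, 1.0)), 0.0)
    else:
        scale = prec
    return psi + scale * omega * dt


def motion_rates(
    ensemble: EnsembleState,
    i: int,
    errors: tuple[np.ndarray, np.ndarray],
    mu_dot: np.ndarray,
    params: GenerativeModelParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Velocity and acceleration of particle ``i``.

    Velocity descends the precision-weighted flow-magnitude error along
    its spatial gradient; the acceleration term anticipates the change
    of expectations ``R_dot = T' J mu_dot`` with smoothness ``lambda``.
    The gradient is taken through the sensor model (saturation and
    empty-channel floor), so channels beyond the kernel's reach exert no
    force.
    """
    grad = ensemble_flow_jacobian(ensemble, indices=np.array([i]))[0]  # (2, 4)
    return _motion_from_grad(grad, ensemble.psi[i], errors, mu_dot, params)


def _motion_from_grad(grad, psi, errors, mu_dot, params):
    _, eps_R = errors
    x_dot = -np.einsum("...dk,...k->...d", grad, params.prec_R_vec * eps_R)
    J = _jacobian(psi, params)
    psi_dot = np.einsum("...ij,...j->...i", J, mu_dot)
    R_dot = psi_dot @ params.distance_template
    x_ddot = np.einsum(
        "...dk,...k->...d", grad, params.lambda_smooth * params.prec_R_vec * R_dot
    )
    return x_dot, x_ddot


def step(
    ensemble: EnsembleState,
    protocol: Optional[StimulusProtocol],
    rng: Optional[np.random.Generator],
    dt: float = 0.1,
) -> EnsembleState:
    """Advance the ensemble one step, synchronously from the time-t field.

    Every particle senses the same (time-t) field, computes its rates,
    and all states are then updated together, so the result is invariant
    to particle ordering.
    """
    p = ensemble.params
    psi = ensemble.psi  # (N, 4)
    _, R_raw, m = ensemble_flow(ensemble)  # deterministic magnitudes (N, 4)
    grad = ensemble_flow_jacobian(ensemble)  # (N, 2, 4), through the sensor model

    s_psi = ensemble.a_psi.copy()
    s_R = effective_magnitude(R_raw, m, p)
    if not p.noise_free:
        if rng is None:
            raise ValueError("rng required unless params.noise_free is set")
        s_psi = s_psi + _noise(rng, p.prec_psi_vec, shape=s_psi.shape)
        s_R = s_R + _noise(rng, p.prec_R_vec, shape=s_R.shape)

    R_expected = expected_flow(psi, p.distance_template)
    sample = SensorySample(s_psi=s_psi, s_R=s_R)
    errors = prediction_errors(sample, psi, R_expected)

    drive = None
    if protocol is not None:
        drive = protocol.drive(ensemble.x, ensemble.t, p.stim_gain)
    mu_dot = belief_rate(errors, ensemble.mu, p, stim_drive=drive)
    x_dot, x_ddot = _motion_from_grad(grad, psi, errors, mu_dot, p)

    x_new = ensemble.x + x_dot * dt + 0.5 * x_ddot * dt**2
    mu_new = saturate_evidence(ensemble.mu + mu_dot * dt, p.mu_max)
    a_new = emitter_update(psi, p, rng, dt)

    for arr, name in ((x_new, "position"), (mu_new, "evidence"), (a_new, "emitter")):
        if not np.all(np.isfinite(arr)):
            bad = int(np.argwhere(~np.isfinite(arr))[0][0])
            raise IntegrationError(
                f"non-finite {name} for particle {bad} at step {ensemble.t + 1}"
            )
    return EnsembleState(x=x_new, mu=mu_new, a_psi=a_new, t=ensemble.t + 1, params=p)


def particle_rates(
    ensemble: EnsembleState,
    i: int,
    sample: SensorySample,
    params: Optional[GenerativeModelParams] = None,
    stim_drive: Optional[np.ndarray] = None,
    dt: float = 0.1,
    rng: Optional[np.random.Generator] = None,
) -> RateBundle:
    """Full rate bundle for one particle (convenience for diagnostics)."""
    p = params or ensemble.params
    psi = ensemble.psi[i]
    R_expected = expected_flow(psi, p.distance_template)
    errors = prediction_errors(sample, psi, R_expected)
    mu_dot = belief_rate(errors, ensemble.mu[i], p, stim_drive=stim_drive)
    x_dot, x_ddot = motion_rates(ensemble, i, errors, mu_dot, p)
    a_next = emitter_update(psi, p, rng, dt)
    return RateBundle(
        mu_dot=mu_dot,
        a_dot=(a_next - ensemble.a_psi[i]) / dt,
        x_dot=x_dot,
        x_ddot=x_ddot,
        eps_psi=errors[0],
        eps_R=errors[1],
    )


def run(config: SimulationConfig) -> Trajectory:
    """Run a full simulation: init, repeated steps, strided snapshots."""
    t0 = time.perf_counter()
    rng = np.random.default_rng(config.seed)
    ensemble = init_ensemble(config, rng)
    protocol = config.protocol()
    stride = config.stride
    snapshots = [ensemble]
    for _ in range(config.steps):
        try:
            ensemble = step(ensemble, protocol, rng, dt=config.dt)
        except IntegrationError as exc:
            raise IntegrationError(f"{exc} (seed {config.seed})") from exc
        if ensemble.t % stride == 0 or ensemble.t == config.steps:
            snapshots.append(ensemble)
    # drop a duplicate final snapshot when stride divides steps exactly
    if len(snapshots) >= 2 and snapshots[-1].t == snapshots[-2].t:
        snapshots.pop()
    return Trajectory(
        snapshots=snapshots,
        config=config,
        seed=config.seed,
        wall_clock=time.perf_counter() - t0,
    )


def free_energy_proxy(ensemble: EnsembleState) -> float:
    """Mean precision-weighted squared prediction error over particles.

    Evaluated noise-free (the deterministic field), this tracks the
    variational free energy up to constants and is the quantity expected
    to fall as the ensemble self-organises.
    """
    p = ensemble.params
    psi = ensemble.psi
    _, R_raw, m = ensemble_flow(ensemble)
    R_expected = expected_flow(psi, p.distance_template)
    eps_R = effective_magnitude(R_raw, m, p) - R_expected
    eps_psi = ensemble.a_psi - psi
    per_particle = (p.prec_R_vec * eps_R**2).sum(axis=1) + (
        p.prec_psi_vec * eps_psi**2
    ).sum(axis=1)
    return float(per_particle.mean())
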