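"""External stimulus fields and experiment presets.

The stimulus is a scalar field ``f(x, t)`` in [0, 1] — a stand-in for
afferent drive from sensory epithelia.  Its value at a particle's
position sets the log-evidence drive the particle receives: intensity
``f`` is evidence for membership in ensemble A (identities 1, 2) and the
complement ``1 - f`` is evidence for ensemble B (identities 3, 4).

Three experiment presets are provided:

1. a static disc of stimulation switched on at step 10;
2. the disc relocated at step 200 to a disjoint site;
3. the disc relocated at step 200 to an overlapping site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

__all__ = [
    "StimulusProtocol",
    "disc_stimulus",
    "stimulus_evidence",
    "switching_protocol",
    "static_protocol",
    "preset_experiment",
]

FieldFn = Callable[[np.ndarray], np.ndarray]


def disc_stimulus(center, radius: float, softness: float = 0.0) -> FieldFn:
    """Disc-shaped stimulus: 1 inside the disc, smooth shoulder outside.

    The falloff outside the disc edge is a Gaussian shoulder of scale
    ``softness / 2``, so the intensity is ~0.14 one softness-length past
    the edge and negligible a few lengths out.  ``softness = 0`` gives
    the exact indicator of the disc.
    """
    center = np.asarray(center, dtype=float)
    if radius <= 0:
        raise ValueError("disc radius must be > 0")
    if softness < 0:
        raise ValueError("softness must be >= 0")

    def f(pos: np.ndarray) -> np.ndarray:
        pos = np.asarray(pos, dtype=float)
        d = np.linalg.norm(pos - center, axis=-1)
        if softness == 0:
            return (d <= radius).astype(float)
        excess = np.maximum(d - radius, 0.0)
        return np.exp(-0.5 * (excess / (softness / 2.0)) ** 2)

    f.center = center  # type: ignore[attr-defined]
    f.radius = radius  # type: ignore[attr-defined]
    f.softness = softness  # type: ignore[attr-defined]
    return f


def stimulus_evidence(f, gain: float) -> np.ndarray:
    """Log-evidence drive for one intensity value (or batch).

    ``kappa * (f, f, 1-f, 1-f)``: the intensity supports ensemble-A
    identities, its complement supports ensemble-B identities, so the
    total drive is constant across space.
    """
    f = np.asarray(f, dtype=float)
    if np.any(f < 0) or np.any(f > 1):
        raise ValueError("stimulus intensity must lie in [0, 1]")
    return gain * np.stack([f, f, 1.0 - f, 1.0 - f], axis=-1)


@dataclass
class StimulusProtocol:
    """Time-gated stimulus: zero before onset, optional field switch.

    ``field_a`` applies on ``[t_onset, t_switch)`` and ``field_b`` from
    ``t_switch`` on (half-open convention: the new field applies at
    exactly the switch step).  With no switch, ``field_a`` persists.
    """

    field_a: FieldFn
    t_onset: int
    t_switch: Optional[int] = None
    field_b: Optional[FieldFn] = None
    spec: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.t_switch is not None:
            if self.field_b is None:
                raise ValueError("t_switch given without a second field")
            if not self.t_onset < self.t_switch:
                raise ValueError("t_onset must precede t_switch")

    def active(self, t: int) -> bool:
        return t >= self.t_onset

    def intensity(self, pos: np.ndarray, t: int) -> np.ndarray:
        pos = np.asarray(pos, dtype=float)
        if t < self.t_onset:
            return np.zeros(pos.shape[:-1])
        if self.t_switch is not None and t >= self.t_switch:
            return self.field_b(pos)
        return self.field_a(pos)

    def drive(self, pos: np.ndarray, t: int, gain: float) -> np.ndarray:
        """Per-position 4-vector log-evidence drive; zero before onset."""
        pos = np.asarray(pos, dtype=float)
        if not self.active(t):
            return np.zeros(pos.shape[:-1] + (4,))
        return stimulus_evidence(self.intensity(pos, t), gain)

    def current_field(self, t: int) -> Optional[FieldFn]:
        if t < self.t_onset:
            return None
        if self.t_switch is not None and t >= self.t_switch:
            return self.field_b
        return self.field_a


def static_protocol(field_fn: FieldFn, t_onset: int = 10) -> StimulusProtocol:
    """A single stimulus field that persists after onset."""
    return StimulusProtocol(field_a=field_fn, t_onset=t_onset)


def switching_protocol(
    field_a: FieldFn, field_b: FieldFn, t_onset: int, t_switch: int
) -> StimulusProtocol:
    """Stimulus that relocates from ``field_a`` to ``field_b`` at ``t_switch``."""
    return StimulusProtocol(
        field_a=field_a, t_onset=t_onset, t_switch=t_switch, field_b=field_b
    )


def preset_geometry(n: int, box_size: float) -> dict:
    """Default disc geometry for the experiment presets.

    The static disc covers ~25 % of the initial box.  The relocation
    protocols use a smaller disc (~13 % coverage) so that two genuinely
    disjoint stimulus sites both fit well inside the populated arena,
    the displaced centre sitting two radii plus a margin wider than the
    soft shoulder away.  The overlapping relocation displaces by 0.75
    radii.
    """
    radius_static = box_size * float(np.sqrt(0.25 / np.pi))
    radius_moving = box_size * float(np.sqrt(0.13 / np.pi))
    soft = 0.5
    half_gap = radius_moving + 0.2 + 0.6 * soft  # disjoint with margin
    return {
        "radius_static": radius_static,
        "radius_moving": radius_moving,
        "softness": soft,
        "center_static": (0.0, 0.0),
        "centers_disjoint": ((-half_gap, 0.0), (half_gap, 0.0)),
        "centers_overlap": ((-0.375 * radius_moving, 0.0), (0.375 * radius_moving, 0.0)),
    }


def build_protocol(spec: dict) -> StimulusProtocol:
    """Build a protocol from its serialisable description."""
    spec = dict(spec)
    kind = spec.get("kind", "disc")
    if kind != "disc":
        raise ValueError(f"unknown stimulus kind {kind!r}")
    t_onset = int(spec.get("t_onset", 10))
    radius = float(spec["radius"])
    softness = float(spec.get("softness", 0.0))
    field_a = disc_stimulus(spec["center_a"], radius, softness)
    if spec.get("t_switch") is None:
        proto = static_protocol(field_a, t_onset)
    else:
        field_b = disc_stimulus(spec["center_b"], radius, softness)
        proto = switching_protocol(field_a, field_b, t_onset, int(spec["t_switch"]))
    proto.spec = spec
    return proto


def preset_experiment(experiment_id: int, N: int = 256, seed: int = 0, **overrides):
    """Simulation config for one of the three stimulation experiments.

    1: static disc (onset step 10); 2: disc relocated at step 200 to a
    disjoint site; 3: relocated to an overlapping site.  ``overrides``
    are forwarded to :class:`~packetsim.config.SimulationConfig`.
    """
    from .config import SimulationConfig  # local import to avoid a cycle
    from .core_model import default_box_size

    if experiment_id not in (1, 2, 3):
        raise ValueError(f"unknown experiment id {experiment_id!r}")
    box = float(overrides.pop("box_size", default_box_size(N)))
    geom = preset_geometry(N, box)
    stim: dict = {
        "kind": "disc",
        "t_onset": 10,
        "softness": geom["softness"],
    }
    if experiment_id == 1:
        stim["radius"] = geom["radius_static"]
        stim["center_a"] = list(geom["center_static"])
        stim["t_switch"] = None
    else:
        key = "centers_disjoint" if experiment_id == 2 else "centers_overlap"
        ca, cb = geom[key]
        stim["radius"] = geom["radius_moving"]
        stim.update(center_a=list(ca), center_b=list(cb), t_switch=200)
    return SimulationConfig(
        N=N,
        seed=seed,
        init={"kind": "uniform", "box_size": box},
        stimulus=stim,
        **overrides,
    )
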