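"""Role classification and Markov-blanket structure diagnostics.

After the ensemble self-organises, each particle is labelled by its
maximum-a-posteriori identity and the blanket claim is checked as a
graph property: on the geometric graph of particles within interaction
range, deleting all blanket-role nodes must disconnect every
``internal_A`` particle from every ``internal_B`` particle.  This
operationalises conditional independence between the internal states of
the two superordinate ensembles given their blanket states — the
Gaussian signalling kernel makes influence beyond a couple of kernel
units negligible, so signal reach defines the edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import networkx as nx
import numpy as np
from scipy.spatial.distance import pdist, squareform

from .core_model import EnsembleState
from .field_signaling import signal_intensity

__all__ = [
    "ROLES",
    "BlanketReport",
    "EvidenceTrace",
    "map_identity",
    "classify_roles",
    "blanket_test",
    "evidence_trace",
    "signal_field_map",
    "reformation_time",
    "count_violating_paths",
]

ROLES = ("internal_A", "blanket_A", "blanket_B", "internal_B")
INTERNAL_A, BLANKET_A, BLANKET_B, INTERNAL_B = range(4)
LOW_CONFIDENCE = 0.4
DEFAULT_RADIUS = 2.0  # kernel units; intensity factor exp(-2) ~ 0.135


@dataclass
class BlanketReport:
    """Outcome of the blanket separation test on one ensemble state."""

    roles: list  # per-particle role label
    radius: float
    separated: bool
    violating_pairs: int  # internal_A/internal_B pairs connected without blanket nodes
    census: dict  # role -> count
    reason: Optional[str] = None
    low_confidence: int = 0  # particles with max belief < 0.4

    def to_dict(self) -> dict:
        return {
            "roles": list(self.roles),
            "radius": self.radius,
            "separated": bool(self.separated),
            "violating_pairs": int(self.violating_pairs),
            "census": dict(self.census),
            "reason": self.reason,
            "low_confidence": int(self.low_confidence),
        }


@dataclass
class EvidenceTrace:
    """Ensemble-mean belief per identity over time."""

    times: np.ndarray
    mean_belief: np.ndarray  # (T, 4), rows sum to 1
    mean_log_evidence: np.ndarray  # (T, 4) mean mu, for reference

    def to_dict(self) -> dict:
        return {
            "times": self.times.tolist(),
            "mean_belief": self.mean_belief.tolist(),
            "mean_log_evidence": self.mean_log_evidence.tolist(),
        }


def map_identity(psi: np.ndarray) -> str:
    """MAP role of one belief vector; ties break to the lowest index."""
    psi = np.asarray(psi, dtype=float)
    return ROLES[int(np.argmax(psi))]


def classify_roles(psi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Batched MAP role indices and a low-confidence mask (max belief < 0.4)."""
    psi = np.asarray(psi, dtype=float)
    idx = np.argmax(psi, axis=-1)
    low = np.max(psi, axis=-1) < LOW_CONFIDENCE
    return idx, low


def _radius_graph(x: np.ndarray, radius: float) -> nx.Graph:
    dist = squareform(pdist(x))
    g = nx.Graph()
    g.add_nodes_from(range(len(x)))
    ii, jj = np.nonzero(np.triu(dist <= radius, k=1))
    g.add_edges_from(zip(ii.tolist(), jj.tolist()))
    return g


def blanket_test(
    ensemble: EnsembleState,
    radius: float = DEFAULT_RADIUS,
    roles: Optional[np.ndarray] = None,
) -> BlanketReport:
    """Check geometric separation of the two internal-state populations.

    Builds the radius graph, deletes every blanket-role node, and asks
    whether any connected component still contains both an ``internal_A``
    and an ``internal_B`` particle.  Separation requires at least one
    particle of each internal role; a missing role fails with a reason
    code rather than passing vacuously.
    """
    if radius <= 0:
        raise ValueError("interaction radius must be > 0")
    psi = ensemble.psi
    if roles is None:
        roles, low = classify_roles(psi)
    else:
        roles = np.asarray(roles)
        low = np.zeros(len(roles), dtype=bool)
    census = {ROLES[k]: int(np.sum(roles == k)) for k in range(4)}
    labels = [ROLES[int(r)] for r in roles]

    has_a = census["internal_A"] > 0
    has_b = census["internal_B"] > 0
    if not (has_a and has_b):
        missing = [r for r, ok in (("internal_A", has_a), ("internal_B", has_b)) if not ok]
        return BlanketReport(
            roles=labels, radius=radius, separated=False, violating_pairs=0,
            census=census, reason=f"missing internal roles: {missing}",
            low_confidence=int(low.sum()),
        )

    g = _radius_graph(ensemble.x, radius)
    blanket_nodes = [i for i in g.nodes if roles[i] in (BLANKET_A, BLANKET_B)]
    g.remove_nodes_from(blanket_nodes)
    violating = 0
    for comp in nx.connected_components(g):
        n_a = sum(1 for i in comp if roles[i] == INTERNAL_A)
        n_b = sum(1 for i in comp if roles[i] == INTERNAL_B)
        violating += n_a * n_b
    return BlanketReport(
        roles=labels, radius=radius, separated=violating == 0,
        violating_pairs=violating, census=census,
        low_confidence=int(low.sum()),
    )


def count_violating_paths(
    x: np.ndarray, roles: np.ndarray, radius: float
) -> int:
    """Enumerate simple internal_A -> internal_B paths avoiding blanket nodes.

    Exhaustive path enumeration; intended as an oracle for
    :func:`blanket_test` on small configurations (<= 12 nodes or so).
    """
    g = _radius_graph(np.asarray(x, dtype=float), radius)
    roles = np.asarray(roles)
    keep = [i for i in g.nodes if roles[i] not in (BLANKET_A, BLANKET_B)]
    sub = g.subgraph(keep)
    sources = [i for i in keep if roles[i] == INTERNAL_A]
    targets = {i for i in keep if roles[i] == INTERNAL_B}
    count = 0
    for s in sources:
        for t in targets:
            count += sum(1 for _ in nx.all_simple_paths(sub, s, t))
    return count


def evidence_trace(
    trajectory,
    mask_fn: Optional[Callable[[np.ndarray], np.ndarray]] = None,
) -> EvidenceTrace:
    """Per-snapshot mean belief (and mean log evidence) over particles.

    ``mask_fn`` maps positions (N, 2) to a boolean mask, e.g. to restrict
    the average to the stimulus support; snapshots where the mask is
    empty fall back to the full ensemble.
    """
    if len(trajectory.snapshots) == 0:
        raise ValueError("trajectory has no snapshots")
    times, means, mus = [], [], []
    for snap in trajectory.snapshots:
        sel = np.ones(snap.n, dtype=bool)
        if mask_fn is not None:
            sel = np.asarray(mask_fn(snap.x), dtype=bool)
            if not sel.any():
                sel = np.ones(snap.n, dtype=bool)
        times.append(snap.t)
        means.append(snap.psi[sel].mean(axis=0))
        mus.append(snap.mu[sel].mean(axis=0))
    return EvidenceTrace(
        times=np.array(times),
        mean_belief=np.array(means),
        mean_log_evidence=np.array(mus),
    )


def signal_field_map(
    ensemble: EnsembleState,
    extent: tuple[float, float, float, float],
    shape: tuple[int, int] = (100, 100),
    normalize: bool = False,
) -> tuple[np.ndarray, dict]:
    """Rasterise the 4-channel signal field over a rectangular grid.

    Returns an (ny, nx, 4) array (row-major, row 0 at ymin) and grid
    metadata.  With ``normalize``, each grid node's channel vector is
    scaled to unit sum where any signal is present.
    """
    xmin, xmax, ymin, ymax = extent
    ny, nx_ = shape
    if nx_ < 1 or ny < 1:
        raise ValueError("grid shape must be positive")
    gx = np.linspace(xmin, xmax, nx_)
    gy = np.linspace(ymin, ymax, ny)
    xx, yy = np.meshgrid(gx, gy)
    pts = np.stack([xx, yy], axis=-1)  # (ny, nx, 2)
    raster = signal_intensity(ensemble, pts.reshape(-1, 2)).reshape(ny, nx_, 4)
    if normalize:
        total = raster.sum(axis=-1, keepdims=True)
        raster = np.divide(raster, total, out=np.zeros_like(raster), where=total > 0)
    meta = {"extent": list(extent), "shape": [ny, nx_]}
    return raster, meta


def reformation_time(
    trajectory,
    radius: float = DEFAULT_RADIUS,
    region: Optional[Callable[[np.ndarray], np.ndarray]] = None,
) -> Optional[int]:
    """First post-switch time at which a blanket encloses the new stimulus.

    Scans snapshots from the protocol's switch step and returns the first
    time index where the separation test passes *and* the centroid of the
    ``internal_A`` particles lies inside the new stimulus support
    (``region``; defaults to the protocol's post-switch field at
    intensity >= 1/2).  Returns None if the ensemble never reorganises.
    """
    protocol = trajectory.config.protocol()
    if protocol is None or protocol.t_switch is None:
        raise ValueError("trajectory has no stimulus switch")
    t_switch = protocol.t_switch
    if trajectory.snapshots[-1].t < t_switch:
        raise ValueError("trajectory ends before the stimulus switch")
    if region is None:
        field_b = protocol.field_b
        region = lambda pos: field_b(pos) >= 0.5  # noqa: E731
    for snap in trajectory.snapshots:
        if snap.t < t_switch:
            continue
        report = blanket_test(snap, radius)
        if not report.separated:
            continue
        roles, _ = classify_roles(snap.psi)
        inside = snap.x[roles == INTERNAL_A]
        if len(inside) == 0:
            continue
        centroid = inside.mean(axis=0)
        if np.asarray(region(centroid[None, :]))[0]:
            return int(snap.t)
    return None
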