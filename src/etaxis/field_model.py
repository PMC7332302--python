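"""Lumped electrical and hydraulic model of a multi-field microfluidic chip.

The chip creates several electric field strengths in one device by
routing current through a resistor-ladder network of medium-filled
channels (an R-2R ladder yields the designed 5.25:2.5:1:0 section
ratio).  Instead of a finite-element continuum simulation, each channel
segment is a lumped resistor

    R = L / (σ w h)

(length L, conductivity σ, rectangular cross-section w × h), and node
potentials follow from Kirchhoff's current law.  The same geometry gives
the hydraulic resistance of a rectangular duct in the shallow-channel
approximation

    R_h = 12 μ L / (w h³ (1 − 0.63 h/w)),   h ≤ w,

which quantifies why thin interconnecting channels suppress advective
chemical transport between main channels.

Section field strengths scale linearly with the source, so the design
ratio can be rescaled exactly to any maximum field (e.g. 5.25:2.5:1:0
scaled to 300 V/m gives 300, 142.9, 57.1, 0 V/m).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import InvalidSegmentError, SingularNetworkError

__all__ = [
    "ChannelSegment",
    "ChannelNetwork",
    "SectionField",
    "NetworkSolution",
    "electrical_resistance",
    "hydraulic_resistance",
    "solve_network",
    "section_efs",
    "scale_to_max",
    "make_r2r_ladder",
]

#: Default culture-medium conductivity, S/m (MEMα + 10% FBS).
MEDIUM_CONDUCTIVITY = 1.536
#: Default culture-medium dynamic viscosity, Pa·s.
MEDIUM_VISCOSITY = 0.946e-3


@dataclass(frozen=True)
class ChannelSegment:
    """A straight channel segment with rectangular cross-section (SI units)."""

    length: float                       # m
    width: float                        # m
    height: float                       # m
    conductivity: float = MEDIUM_CONDUCTIVITY   # S/m
    viscosity: float = MEDIUM_VISCOSITY          # Pa·s

    def __post_init__(self) -> None:
        for name in ("length", "width", "height", "conductivity", "viscosity"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise InvalidSegmentError(f"{name} must be positive, got {v!r}")

    @property
    def cross_section(self) -> float:
        """Cross-sectional area, m²."""
        return self.width * self.height


@dataclass(frozen=True)
class ChannelNetwork:
    """A resistive network with one current or voltage source.

    ``edges`` are (node_a, node_b, resistance_Ω) triples.  The source
    drives current from ``source[0]`` to ``source[1]``; ``ground`` fixes
    the potential reference.
    """

    edges: tuple[tuple[str, str, float], ...]
    source: tuple[str, str]
    ground: str
    current: float | None = None        # A, current source magnitude
    voltage: float | None = None        # V, voltage source magnitude

    def __post_init__(self) -> None:
        if (self.current is None) == (self.voltage is None):
            raise ValueError("specify exactly one of current or voltage")
        for a, b, r in self.edges:
            if not (math.isfinite(r) and r > 0):
                raise InvalidSegmentError(f"resistance {r!r} on edge {a}-{b}")

    @property
    def nodes(self) -> list[str]:
        seen: dict[str, None] = {}
        for a, b, _ in self.edges:
            seen.setdefault(a)
            seen.setdefault(b)
        seen.setdefault(self.source[0])
        seen.setdefault(self.source[1])
        seen.setdefault(self.ground)
        return list(seen)


@dataclass(frozen=True)
class SectionField:
    """Electric field strength in one chip section."""

    section_id: str
    efs: float      # V/m


@dataclass(frozen=True)
class NetworkSolution:
    potentials: dict[str, float]            # V per node
    edge_currents: tuple[float, ...]        # A per edge, a→b positive
    source_current: float                   # A through the source
    kcl_residual: float                     # max |Σ I| over non-source nodes


def electrical_resistance(seg: ChannelSegment) -> float:
    """Ohmic resistance of a medium-filled channel, Ω: L/(σ·w·h)."""
    return seg.length / (seg.conductivity * seg.width * seg.height)


def hydraulic_resistance(seg: ChannelSegment) -> float:
    """Hydraulic resistance of a rectangular duct, Pa·s/m³.

    Shallow-channel approximation R_h = 12μL / (w h³ (1 − 0.63 h/w)),
    valid for h ≤ w (about 13% low in the square limit, adequate for
    order-of-magnitude channel-network design).
    """
    if seg.height > seg.width:
        raise InvalidSegmentError(
            "hydraulic formula requires height <= width; swap the dimensions")
    h, w = seg.height, seg.width
    return 12.0 * seg.viscosity * seg.length / (w * h**3 * (1.0 - 0.63 * h / w))


def _connected(nodes: Sequence[str], edges, a: str, b: str) -> bool:
    adj: dict[str, set[str]] = {n: set() for n in nodes}
    for x, y, _ in edges:
        adj[x].add(y)
        adj[y].add(x)
    stack, seen = [a], {a}
    while stack:
        n = stack.pop()
        if n == b:
            return True
        for m in adj[n] - seen:
            seen.add(m)
            stack.append(m)
    return False


def solve_network(net: ChannelNetwork) -> NetworkSolution:
    """Solve node potentials and edge currents by nodal analysis.

    Builds the conductance matrix G (modified nodal analysis for a
    voltage source), grounds the reference node, and solves G·V = I.
    Kirchhoff's current law holds at every non-source node; the maximum
    residual is returned for verification.

    Raises
    ------
    SingularNetworkError
        If the source terminals are not connected through the network.
    """
    nodes = net.nodes
    if not _connected(nodes, net.edges, net.source[0], net.source[1]):
        raise SingularNetworkError("source terminals are not connected")
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    G = np.zeros((n, n))
    for a, b, r in net.edges:
        g = 1.0 / r
        ia, ib = idx[a], idx[b]
        G[ia, ia] += g
        G[ib, ib] += g
        G[ia, ib] -= g
        G[ib, ia] -= g
    sp, sn = idx[net.source[0]], idx[net.source[1]]
    gi = idx[net.ground]
    if net.current is not None:
        rhs = np.zeros(n)
        rhs[sp] += net.current
        rhs[sn] -= net.current
        A = G.copy()
        A[gi, :] = 0.0
        A[gi, gi] = 1.0
        rhs[gi] = 0.0
        v = np.linalg.solve(A, rhs)
        i_src = net.current
    else:
        # MNA: extra unknown = current through the voltage source
        A = np.zeros((n + 1, n + 1))
        A[:n, :n] = G
        A[sp, n] = 1.0
        A[sn, n] = -1.0
        A[n, sp] = 1.0
        A[n, sn] = -1.0
        rhs = np.zeros(n + 1)
        rhs[n] = net.voltage
        A[gi, :] = 0.0
        A[gi, gi] = 1.0
        rhs[gi] = 0.0
        sol = np.linalg.solve(A, rhs)
        v, i_src = sol[:n], -float(sol[n])
    currents = tuple(
        float((v[idx[a]] - v[idx[b]]) / r) for a, b, r in net.edges)
    # KCL residual at non-source nodes, relative to total injected current
    residual = np.zeros(n)
    for (a, b, _), i_e in zip(net.edges, currents):
        residual[idx[a]] -= i_e
        residual[idx[b]] += i_e
    residual[sp] += i_src
    residual[sn] -= i_src
    denom = max(abs(i_src), 1e-300)
    kcl = float(np.abs(residual).max()) / denom
    potentials = {node: float(v[idx[node]]) for node in nodes}
    return NetworkSolution(potentials, currents, float(i_src), kcl)


def section_efs(
    currents: Mapping[str, float],
    segments: Mapping[str, ChannelSegment],
) -> list[SectionField]:
    """Field strength in each section: E = I / (σ A_cross), V/m.

    ``currents`` maps section id to the current flowing through that
    section's main channel; ``segments`` supplies geometry.
    """
    out = []
    for sec, i in currents.items():
        seg = segments[sec]
        out.append(SectionField(sec, abs(i) / (seg.conductivity * seg.cross_section)))
    return out


def scale_to_max(ratio: Sequence[float], max_efs: float) -> np.ndarray:
    """Scale a section-field ratio so its maximum equals ``max_efs`` (V/m).

    Preserves the ratio exactly; the design ratio 5.25:2.5:1:0 scaled to
    300 V/m yields (300, 142.86, 57.14, 0).
    """
    r = np.asarray(ratio, dtype=float)
    if max_efs < 0:
        raise ValueError("max_efs must be >= 0")
    if r.size == 0 or np.any(r < 0):
        raise ValueError("ratio must be non-negative and non-empty")
    peak = r.max()
    if peak == 0 or max_efs == 0:
        return np.zeros_like(r)
    return r * (max_efs / peak)


def make_r2r_ladder(
    n_rungs: int, r_unit: float, r_load: float | None = None
) -> ChannelNetwork:
    """Generic R-2R ladder: series arms R, shunt rungs 2R, driven by 1 A.

    Nodes are ``n0 .. n{k}`` along the ladder with shunt rungs to
    ``gnd``; the source injects current at ``n0``.  Successive rung
    currents halve in an ideal semi-infinite ladder; a finite ladder
    terminated by ``r_load`` (default 2R) approximates it.
    """
    if n_rungs < 1:
        raise ValueError("need at least one rung")
    if r_unit <= 0:
        raise InvalidSegmentError("r_unit must be positive")
    edges: list[tuple[str, str, float]] = []
    for k in range(n_rungs):
        if k > 0:
            edges.append((f"n{k - 1}", f"n{k}", r_unit))
        edges.append((f"n{k}", "gnd", 2.0 * r_unit))
    # termination 2R in parallel with the last rung makes the halving exact
    term = 2.0 * r_unit if r_load is None else r_load
    edges.append((f"n{n_rungs - 1}", "gnd", term))
    return ChannelNetwork(edges=tuple(edges), source=("n0", "gnd"),
                          ground="gnd", current=1.0)
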