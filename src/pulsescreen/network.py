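"""Arterial network data model.

A network is a tree of 1D vessel segments.  Each vessel carries a linearly
tapered reference cross-sectional area and a tube-law stiffness coefficient
beta (pressure–area relation ``p = p_ext + (beta/A_d) (sqrt(A) - sqrt(A_d))``).
Terminal vessels couple to three-element Windkessel outlets.  Named *chains*
(contiguous runs of segments: common carotid, subclavian, iliac–femoral–
popliteal, abdominal aorta) host disease, and named measurement sites define
where pressure/flow waveforms are recorded.

Configs are plain JSON with explicit unit annotations (cm, cm², mmHg, s).
The packaged default is a symmetric reduced network hosting all four disease
chains and all six bilateral measurement sites.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Callable

import numpy as np

__all__ = [
    "Vessel",
    "WindkesselOutlet",
    "VesselChain",
    "MeasurementSite",
    "InflowWaveform",
    "NetworkTopology",
    "NetworkConfigError",
    "load_network",
    "default_network",
    "chain_coordinate",
]

CHAIN_KINDS = ("CA", "SA", "PA", "AA")
SITE_NAMES = ("P1", "P2", "P3", "Q1", "Q2", "Q3")


class NetworkConfigError(ValueError):
    """Raised when a network description fails structural validation."""


@dataclass
class Vessel:
    """One arterial segment.

    Areas are reference (healthy, zero-transmural-pressure) values in cm²,
    linearly tapered from the proximal to the distal end.  ``area_scale`` is
    an optional multiplicative profile of the local coordinate in [0, 1]
    (1 everywhere when absent) used to impose disease geometry.
    """

    id: str
    length: float  # cm
    ref_area_proximal: float  # cm^2
    ref_area_distal: float  # cm^2
    beta: float  # mmHg*cm tube-law stiffness coefficient
    area_scale: Callable[[np.ndarray], np.ndarray] | None = None
    #: cell-size cap (cm) requested by a non-trivial area profile so the
    #: solver grid resolves it; None keeps the solver's default spacing
    refine_dx: float | None = None
    #: anatomical side, used for left/right asymmetry in subject sampling
    side: str = "none"  # "left" | "right" | "none"

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise NetworkConfigError(f"vessel {self.id!r}: length must be > 0")
        if self.ref_area_proximal <= 0 or self.ref_area_distal <= 0:
            raise NetworkConfigError(f"vessel {self.id!r}: reference areas must be > 0")
        if self.beta <= 0:
            raise NetworkConfigError(f"vessel {self.id!r}: beta must be > 0")

    def reference_area(self, xi: np.ndarray) -> np.ndarray:
        """Reference area at local coordinate xi in [0, 1], disease included."""
        xi = np.asarray(xi, dtype=float)
        a = self.ref_area_proximal + (self.ref_area_distal - self.ref_area_proximal) * xi
        if self.area_scale is not None:
            m = np.asarray(self.area_scale(xi), dtype=float)
            if np.any(m <= 0):
                raise ValueError(f"vessel {self.id!r}: area multiplier must be > 0")
            a = a * m
        return a


@dataclass
class WindkesselOutlet:
    """Three-element Windkessel terminal model (RCR)."""

    r_proximal: float  # mmHg*s/mL
    compliance: float  # mL/mmHg
    r_distal: float  # mmHg*s/mL
    outflow_pressure: float = 0.0  # mmHg

    def __post_init__(self) -> None:
        if self.r_proximal < 0 or self.r_distal < 0:
            raise NetworkConfigError("Windkessel resistances must be >= 0")
        if self.compliance <= 0:
            raise NetworkConfigError("Windkessel compliance must be > 0")


@dataclass
class VesselChain:
    """Contiguous, ordered run of segments hosting one disease form."""

    name: str  # CA, SA, PA, AA
    side: str  # "left" | "right" | "none"
    segments: tuple[str, ...]
    lengths: tuple[float, ...]

    @property
    def total_length(self) -> float:
        return float(sum(self.lengths))


@dataclass
class MeasurementSite:
    """A pressure or flow sampling point: vessel + fractional position."""

    name: str  # P1..P3, Q1..Q3
    side: str  # "left" | "right"
    vessel: str
    position: float  # fractional, in [0, 1]

    @property
    def quantity(self) -> str:
        return "pressure" if self.name.startswith("P") else "flow"

    @property
    def key(self) -> str:
        return f"{self.name}_{'R' if self.side == 'right' else 'L'}"

    def __post_init__(self) -> None:
        if not 0.0 <= self.position <= 1.0:
            raise NetworkConfigError(f"site {self.name}: position must be in [0, 1]")
        if self.name not in SITE_NAMES:
            raise NetworkConfigError(f"unknown measurement site name {self.name!r}")


@dataclass
class InflowWaveform:
    """Periodic volumetric inflow prescribed at the network inlet.

    The shape is stored on a normalised time grid s in [0, 1); for a subject
    with cardiac period T the physical waveform is Q(s*T) in mL/s.
    """

    phase: np.ndarray  # normalised time in [0, 1)
    flow: np.ndarray  # mL/s
    period: float  # s, reference cardiac period

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        self.flow = np.asarray(self.flow, dtype=float)
        if self.phase.ndim != 1 or self.phase.shape != self.flow.shape:
            raise NetworkConfigError("inflow phase/flow must be 1D arrays of equal length")
        if self.period <= 0:
            raise NetworkConfigError("inflow period must be > 0")

    def sample(self, phase: np.ndarray) -> np.ndarray:
        """Interpolate the flow at normalised phases (periodic)."""
        p = np.mod(np.asarray(phase, dtype=float), 1.0)
        xp = np.concatenate([self.phase, [1.0]])
        fp = np.concatenate([self.flow, [self.flow[0]]])
        return np.interp(p, xp, fp)

    @property
    def mean_flow(self) -> float:
        return float(np.trapezoid(np.concatenate([self.flow, [self.flow[0]]]),
                                  np.concatenate([self.phase, [1.0]])))


@dataclass
class NetworkTopology:
    """Validated arterial tree with chains, measurement sites and outlets."""

    vessels: dict[str, Vessel]
    children: dict[str, tuple[str, ...]]  # parent id -> child ids (junctions)
    inlet: str
    inflow: InflowWaveform
    outlets: dict[str, WindkesselOutlet]
    chains: dict[tuple[str, str], VesselChain] = field(default_factory=dict)
    sites: dict[str, MeasurementSite] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._validate()

    # -- structure ---------------------------------------------------------
    @property
    def parent(self) -> dict[str, str]:
        return {c: p for p, cs in self.children.items() for c in cs}

    @property
    def terminals(self) -> tuple[str, ...]:
        return tuple(v for v in self.vessels if not self.children.get(v))

    def chain(self, name: str, side: str) -> VesselChain:
        try:
            return self.chains[(name, side)]
        except KeyError:
            raise KeyError(f"network has no chain {name!r} on side {side!r}") from None

    def site(self, name: str, side: str) -> MeasurementSite:
        key = f"{name}_{'R' if side == 'right' else 'L'}"
        try:
            return self.sites[key]
        except KeyError:
            raise KeyError(f"network has no measurement site {key!r}") from None

    def copy(self) -> "NetworkTopology":
        return copy.deepcopy(self)

    def _validate(self) -> None:
        ids = set(self.vessels)
        if self.inlet not in ids:
            raise NetworkConfigError(f"inlet vessel {self.inlet!r} not defined")
        parent = {}
        for p, cs in self.children.items():
            if p not in ids:
                raise NetworkConfigError(f"junction parent {p!r} not defined")
            for c in cs:
                if c not in ids:
                    raise NetworkConfigError(f"junction child {c!r} not defined")
                if c in parent:
                    raise NetworkConfigError(f"vessel {c!r} has multiple parents")
                parent[c] = p
        # connectivity and acyclicity: BFS from inlet must reach every vessel
        seen = {self.inlet}
        stack = [self.inlet]
        while stack:
            v = stack.pop()
            for c in self.children.get(v, ()):
                if c in seen:
                    raise NetworkConfigError(f"cycle detected at vessel {c!r}")
                seen.add(c)
                stack.append(c)
        missing = ids - seen
        if missing:
            raise NetworkConfigError(f"vessels not connected to inlet: {sorted(missing)}")
        if self.inlet in parent:
            raise NetworkConfigError("inlet vessel must not have a parent")
        for t in self.terminals:
            if t not in self.outlets:
                raise NetworkConfigError(f"terminal vessel {t!r} has no outlet")
        for o in self.outlets:
            if o not in ids:
                raise NetworkConfigError(f"outlet attached to unknown vessel {o!r}")
            if self.children.get(o):
                raise NetworkConfigError(f"outlet attached to non-terminal vessel {o!r}")
        for (name, side), chain in self.chains.items():
            prev = None
            for seg in chain.segments:
                if seg not in ids:
                    raise NetworkConfigError(
                        f"chain {name}/{side} references unknown segment {seg!r}")
                if prev is not None and parent.get(seg) != prev:
                    raise NetworkConfigError(
                        f"chain {name}/{side}: segments {prev!r} -> {seg!r} not contiguous")
                prev = seg
            got = tuple(self.vessels[s].length for s in chain.segments)
            if not np.allclose(got, chain.lengths):
                raise NetworkConfigError(f"chain {name}/{side}: segment lengths inconsistent")
        for key, site in self.sites.items():
            if site.vessel not in ids:
                raise NetworkConfigError(f"site {key} references unknown vessel {site.vessel!r}")


def chain_coordinate(chain: VesselChain, x_n: float) -> tuple[str, float]:
    """Map a normalised chain coordinate to (segment id, local position).

    The mapping is proportional to arc length.  Segment boundaries map to the
    downstream segment's local 0 (deterministic tie-break); ``x_n = 1`` maps
    to the last segment's local 1.
    """
    if not 0.0 <= x_n <= 1.0:
        raise ValueError(f"x_n must be in [0, 1], got {x_n}")
    s = x_n * chain.total_length
    acc = 0.0
    for seg, length in zip(chain.segments, chain.lengths):
        if s < acc + length:
            return seg, (s - acc) / length
        acc += length
    return chain.segments[-1], 1.0


# -- config I/O ------------------------------------------------------------

_SIDE = {"left": "left", "right": "right", "none": "none"}


def load_network(source: str | Path | dict) -> NetworkTopology:
    """Build a validated :class:`NetworkTopology` from a JSON config.

    ``source`` may be a path to a JSON file or an already-parsed dict.  The
    schema is documented in the packaged ``data/default_network.json``.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            cfg = json.load(fh)
    else:
        cfg = source

    vessels: dict[str, Vessel] = {}
    for v in cfg["vessels"]:
        vessels[v["id"]] = Vessel(
            id=v["id"],
            length=float(v["length_cm"]),
            ref_area_proximal=float(v["area_proximal_cm2"]),
            ref_area_distal=float(v["area_distal_cm2"]),
            beta=float(v["beta_mmhg_cm"]),
            side=_SIDE[v.get("side", "none")],
        )
    children = {p: tuple(cs) for p, cs in cfg["junctions"].items()}
    inflow_cfg = cfg["inflow"]
    inflow = InflowWaveform(
        phase=np.asarray(inflow_cfg["phase"], dtype=float),
        flow=np.asarray(inflow_cfg["flow_ml_s"], dtype=float),
        period=float(inflow_cfg["period_s"]),
    )
    outlets = {
        o["vessel"]: WindkesselOutlet(
            r_proximal=float(o["r_proximal_mmhg_s_ml"]),
            compliance=float(o["compliance_ml_mmhg"]),
            r_distal=float(o["r_distal_mmhg_s_ml"]),
            outflow_pressure=float(o.get("outflow_pressure_mmhg", 0.0)),
        )
        for o in cfg["outlets"]
    }
    chains = {}
    for c in cfg.get("chains", []):
        side = _SIDE[c.get("side", "none")]
        segs = tuple(c["segments"])
        for s in segs:
            if s not in vessels:
                raise NetworkConfigError(f"chain {c['name']} references unknown segment {s!r}")
        chains[(c["name"], side)] = VesselChain(
            name=c["name"],
            side=side,
            segments=segs,
            lengths=tuple(vessels[s].length for s in segs),
        )
    sites = {}
    for s in cfg.get("measurement_sites", []):
        site = MeasurementSite(
            name=s["name"],
            side=_SIDE[s["side"]],
            vessel=s["vessel"],
            position=float(s.get("position", 0.5)),
        )
        sites[site.key] = site
    return NetworkTopology(
        vessels=vessels,
        children=children,
        inlet=cfg["inlet"],
        inflow=inflow,
        outlets=outlets,
        chains=chains,
        sites=sites,
    )


def default_network() -> NetworkTopology:
    """The packaged symmetric reduced arterial network.

    25 segments: ascending aorta → arch (L/R common carotids, L/R
    subclavian→brachial→radial) → thoracic aorta → 4-segment abdominal aorta
    → L/R iliac→external iliac→femoral×2→popliteal.  Hosts all four disease
    chains (CA, SA, PA bilateral; AA midline) and the six bilateral
    measurement sites (carotid/brachial/radial pressure, carotid/brachial/
    femoral flow).
    """
    ref = resources.files("pulsescreen.data").joinpath("default_network.json")
    with resources.as_file(ref) as path:
        return load_network(path)
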