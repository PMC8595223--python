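"""Nonlinear 1D pulse-wave propagation on an arterial network.

Governing system per vessel (cross-sectional area A, volumetric flow Q):

    dA/dt + dQ/dx = 0
    dQ/dt + d(alpha Q^2 / A)/dx + (A/rho) dp/dx = -f Q / A

closed by the tube law ``p = p_ext + (beta / A_d)(sqrt(A) - sqrt(A_d))``
with spatially varying reference area A_d(x) (disease enters here) and
friction ``f = 2 (gamma + 2) pi mu / rho`` for a power-law axial velocity
profile of order gamma.  Junctions conserve mass and continuity of total
pressure; terminals couple to three-element Windkessels.  The network is
advanced cycle by cycle from rest until consecutive cycles agree to a
relative L-infinity tolerance, and the converged cycle is returned resampled
to a uniform grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from .network import NetworkTopology

__all__ = [
    "SolverSettings",
    "WaveformSet",
    "SolverError",
    "ConvergenceError",
    "simulate",
    "periodicity_residual",
]

MMHG = 1333.22  # dyn/cm^2 per mmHg


class SolverError(RuntimeError):
    """Unphysical state (e.g. negative area) or failed boundary solve."""


class ConvergenceError(SolverError):
    """Periodic steady state not reached within the cycle budget."""

    def __init__(self, residual: float, max_cycles: int):
        super().__init__(
            f"no periodic steady state after {max_cycles} cycles "
            f"(residual {residual:.3e})")
        self.residual = residual
        self.max_cycles = max_cycles


@dataclass
class SolverSettings:
    """Numerical controls for :func:`simulate`.

    dx is the target cell size; the actual size is the vessel length divided
    by a whole number of cells.  The CFL number bounds the explicit time step
    relative to ``dx / (|u| + c)``.  Periodicity is declared when the
    cycle-to-cycle residual (see :func:`periodicity_residual`) drops below
    ``tolerance``.
    """

    dx: float = 1.0  # cm per cell
    cfl: float = 0.9
    max_cycles: int = 20
    tolerance: float = 1e-3
    rho: float = 1.06  # g/cm^3
    mu: float = 0.04  # Poise
    gamma: float = 9.0  # velocity-profile order
    n_samples: int = 64  # uniform samples of the returned cycle
    init_pressure: float = 70.0  # mmHg, uniform initial state
    #: coefficient of the distributed expansion-loss (no-pressure-recovery)
    #: term modelling post-stenotic flow separation; 0 disables it
    expansion_loss: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.cfl <= 1.0:
            raise ValueError("CFL must be in (0, 1]")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.max_cycles < 2:
            raise ValueError("max_cycles must be >= 2")
        if self.dx <= 0 or self.rho <= 0 or self.mu < 0:
            raise ValueError("dx and rho must be > 0, mu >= 0")

    @property
    def alpha(self) -> float:
        """Momentum correction factor for the velocity profile."""
        return (self.gamma + 2.0) / (self.gamma + 1.0)

    @property
    def friction(self) -> float:
        """f = 2 (gamma + 2) pi mu / rho, cm^2/s."""
        return 2.0 * (self.gamma + 2.0) * math.pi * self.mu / self.rho


@dataclass
class WaveformSet:
    """One converged cardiac cycle at the measurement sites.

    ``series`` maps site keys (e.g. ``"Q1_R"``) to uniformly sampled series
    over one period: pressures in mmHg, flows in mL/s.  Sample k corresponds
    to time ``k * T / n_samples``.
    """

    series: dict[str, np.ndarray]
    period: float  # s
    n_samples: int
    n_cycles: int = 0  # cycles run to convergence
    residual: float = float("nan")  # final cycle-to-cycle residual
    junction_residual: float = float("nan")  # max scaled mass defect

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.period / self.n_samples

    def __getitem__(self, key: str) -> np.ndarray:
        return self.series[key]

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.series)
        df.insert(0, "time_s", self.time)
        return df


def periodicity_residual(previous: WaveformSet, current: WaveformSet) -> float:
    """Relative L-infinity change between consecutive cycles.

    For each site the maximum absolute sample difference is scaled by the
    site's pulse amplitude (max minus min over the current cycle, floored to
    avoid division by zero for constant signals); the residual is the
    maximum over sites.  Identical cycles give exactly 0.
    """
    if previous.n_samples != current.n_samples or previous.period != current.period:
        raise ValueError("waveform sets have mismatching grids")
    if set(previous.series) != set(current.series):
        raise ValueError("waveform sets have mismatching sites")
    worst = 0.0
    for key, cur in current.series.items():
        prev = previous.series[key]
        amp = float(np.max(cur) - np.min(cur))
        floor = 1e-2 * max(1.0, float(np.max(np.abs(cur))))
        denom = max(amp, floor)
        diff = float(np.max(np.abs(cur - prev)))
        if diff == 0.0:
            continue
        worst = max(worst, diff / denom)
    return worst


# --------------------------------------------------------------------------


class _Discretisation:
    """Flattened cell arrays (CGS units) for the numba kernels."""

    def __init__(self, network: NetworkTopology, settings: SolverSettings):
        order = list(network.vessels)
        self.order = order
        index = {vid: i for i, vid in enumerate(order)}
        nv = len(order)
        ncell = np.empty(nv, dtype=np.int64)
        dxv = np.empty(nv)
        for i, vid in enumerate(order):
            v = network.vessels[vid]
            dx = settings.dx if v.refine_dx is None else min(settings.dx, v.refine_dx)
            n = min(max(3, int(round(v.length / dx))), 600)
            ncell[i] = n
            dxv[i] = v.length / n
        off = np.zeros(nv, dtype=np.int64)
        total = 0
        for i in range(nv):
            off[i] = total
            total += ncell[i] + 2
        Ad = np.empty(total)
        Be = np.empty(total)
        Ze = np.zeros(total)  # expansion-loss density, 1/cm
        for i, vid in enumerate(order):
            v = network.vessels[vid]
            n = ncell[i]
            xi = (np.arange(n) + 0.5) / n
            a = v.reference_area(xi) * 1.0  # cm^2
            Ad[off[i] + 1: off[i] + n + 1] = a
            Ad[off[i]] = a[0]
            Ad[off[i] + n + 1] = a[-1]
            Be[off[i]: off[i] + n + 2] = v.beta * MMHG  # dyn/cm
            if settings.expansion_loss > 0.0 and n >= 2:
                # zeta = K * max(0, d ln A_d / dx): dynamic pressure is not
                # recovered where the reference lumen widens (flow separation)
                grad = np.gradient(a, dxv[i])
                Ze[off[i] + 1: off[i] + n + 1] = (
                    settings.expansion_loss * np.maximum(0.0, grad) / a)
        self.ncell, self.off, self.dxv = ncell, off, dxv
        self.Ad, self.Be, self.Ze = Ad, Be, Ze
        self.CP = Be / Ad  # tube-law pressure coefficient (static)
        self.SQ = np.sqrt(Ad)
        self.total = total

        junctions = [(p, cs) for p, cs in network.children.items() if cs]
        nj = len(junctions)
        self.jpar = np.array([index[p] for p, _ in junctions], dtype=np.int64)
        self.jnch = np.array([len(cs) for _, cs in junctions], dtype=np.int64)
        self.jch = np.zeros((max(nj, 1), 3), dtype=np.int64)
        for j, (_, cs) in enumerate(junctions):
            if len(cs) > 3:
                raise SolverError(f"junctions with more than 3 children unsupported")
            for i, c in enumerate(cs):
                self.jch[j, i] = index[c]
        if nj == 0:
            self.jpar = np.zeros(0, dtype=np.int64)
            self.jnch = np.zeros(0, dtype=np.int64)
            self.jch = np.zeros((0, 3), dtype=np.int64)

        terms = [t for t in order if t in network.outlets]
        self.ov = np.array([index[t] for t in terms], dtype=np.int64)
        self.oR1 = np.array([network.outlets[t].r_proximal * MMHG for t in terms])
        self.oR2 = np.array([network.outlets[t].r_distal * MMHG for t in terms])
        self.oC = np.array([network.outlets[t].compliance / MMHG for t in terms])
        self.oPout = np.array([network.outlets[t].outflow_pressure * MMHG for t in terms])

        self.inlet_v = index[network.inlet]
        self.T = network.inflow.period
        self.qphase = np.ascontiguousarray(network.inflow.phase)
        self.qflow = np.ascontiguousarray(network.inflow.flow)  # mL/s == cm^3/s

        sites = sorted(network.sites.values(), key=lambda s: s.key)
        self.site_keys = [s.key for s in sites]
        scell = np.empty(len(sites), dtype=np.int64)
        skind = np.empty(len(sites), dtype=np.int64)
        for i, s in enumerate(sites):
            vi = index[s.vessel]
            j = min(int(s.position * ncell[vi]), ncell[vi] - 1)
            scell[i] = off[vi] + 1 + j
            skind[i] = 0 if s.quantity == "pressure" else 1
        self.scell, self.skind = scell, skind


def simulate(network: NetworkTopology, settings: SolverSettings | None = None) -> WaveformSet:
    """Run the network to its periodic state and sample the converged cycle.

    Raises :class:`ConvergenceError` if the periodicity criterion is not met
    within ``settings.max_cycles`` and :class:`SolverError` on unphysical
    states (typically signalling an excessive severity or time step).
    """
    settings = settings or SolverSettings()
    d = _Discretisation(network, settings)
    rho = settings.rho

    # uniform initial state at the configured pressure, zero flow
    p0 = settings.init_pressure * MMHG
    sqrtA = np.sqrt(d.Ad) + p0 * d.Ad / d.Be
    A = sqrtA**2
    Q = np.zeros(d.total)
    pc = np.full(len(d.ov), p0)
    ajunc = np.concatenate([A[d.off[d.jpar] + d.ncell[d.jpar]][:, None],
                            np.ones((len(d.jpar), 3))], axis=1) if len(d.jpar) else np.zeros((0, 4))

    M = settings.n_samples
    tgrid = np.arange(M) / M
    prev_ws: WaveformSet | None = None
    residual = float("inf")
    max_jres = 0.0
    for cycle in range(settings.max_cycles):
        dt_lim = K._min_dt(A, Q, d.Ad, d.Be, d.dxv, d.off, d.ncell, rho)
        dt = settings.cfl * 0.8 * dt_lim  # margin for mid-cycle wave-speed rise
        nsteps = int(math.ceil(d.T / dt))
        dt = d.T / nsteps
        rec = np.empty((len(d.scell), nsteps))
        status, jres = K._run_cycle(
            A, Q, d.Ad, d.Be, d.Ze, d.CP, d.SQ, d.dxv, d.off, d.ncell,
            d.jpar, d.jnch, d.jch,
            d.ov, d.oR1, d.oC, d.oR2, d.oPout, pc,
            d.qphase, d.qflow, d.T, cycle * d.T, dt, nsteps, d.inlet_v,
            d.scell, d.skind, rec,
            rho, settings.alpha, settings.friction, ajunc)
        if status == K.NEGATIVE_AREA:
            raise SolverError("negative cross-sectional area encountered "
                              "(unphysical severity or settings)")
        if status == K.NEWTON_FAIL:
            raise SolverError("junction coupling failed to converge")
        max_jres = max(max_jres, jres)

        # resample the recorded cycle (uniform over [0, T)) to the M-grid
        src = np.arange(nsteps) / nsteps
        series = {}
        for i, key in enumerate(d.site_keys):
            y = rec[i]
            series[key] = np.interp(tgrid, np.concatenate([src, [1.0]]),
                                    np.concatenate([y, [y[0]]]))
            if d.skind[i] == 0:
                series[key] = series[key] / MMHG  # back to mmHg
        ws = WaveformSet(series=series, period=d.T, n_samples=M,
                         n_cycles=cycle + 1, junction_residual=max_jres)
        if prev_ws is not None:
            residual = periodicity_residual(prev_ws, ws)
            ws.residual = residual
            if residual < settings.tolerance:
                return ws
        prev_ws = ws
    raise ConvergenceError(residual, settings.max_cycles)
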