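"""Shared fixtures: toy network configs, fabricated patients, and small
simulated cohorts (session-scoped — cohort generation dominates suite cost).
"""

import numpy as np
import pytest

from pulsescreen import (
    SolverSettings,
    VirtualPatient,
    WaveformSet,
    default_network,
    load_network,
)
from pulsescreen.disease import DiseaseSpec
from pulsescreen.population import SubjectParameters, generate_twin_cohort

SITE_KEYS = [f"{m}_{s}" for m in ("P1", "P2", "P3", "Q1", "Q2", "Q3")
             for s in ("R", "L")]


def tube_config(q0=50.0, r1=0.15, r2=0.45, comp=0.05, pout=10.0,
                length=20.0, area=3.0, beta=800.0, period=0.8,
                phase=None, flow=None):
    """Single uniform tube with an RCR outlet; constant inflow by default."""
    if phase is None:
        phase, flow = [0.0, 0.5], [q0, q0]
    return {
        "inlet": "tube",
        "inflow": {"period_s": period, "phase": list(phase), "flow_ml_s": list(flow)},
        "vessels": [{"id": "tube", "length_cm": length, "area_proximal_cm2": area,
                     "area_distal_cm2": area, "beta_mmhg_cm": beta}],
        "junctions": {},
        "outlets": [{"vessel": "tube", "r_proximal_mmhg_s_ml": r1,
                     "compliance_ml_mmhg": comp, "r_distal_mmhg_s_ml": r2,
                     "outflow_pressure_mmhg": pout}],
        "chains": [],
        "measurement_sites": [
            {"name": "P1", "side": "right", "vessel": "tube", "position": 0.1},
            {"name": "Q1", "side": "right", "vessel": "tube", "position": 0.1},
            {"name": "P2", "side": "right", "vessel": "tube", "position": 0.9},
            {"name": "Q2", "side": "right", "vessel": "tube", "position": 0.9},
        ],
    }


def two_vessel_config():
    """Parent + child toy tree (one junction)."""
    return {
        "inlet": "parent",
        "inflow": {"period_s": 0.8,
                   "phase": list(np.arange(16) / 16),
                   "flow_ml_s": list(30.0 + 20.0 * np.sin(2 * np.pi * np.arange(16) / 16))},
        "vessels": [
            {"id": "parent", "length_cm": 10.0, "area_proximal_cm2": 2.0,
             "area_distal_cm2": 1.8, "beta_mmhg_cm": 700.0},
            {"id": "child", "length_cm": 10.0, "area_proximal_cm2": 1.6,
             "area_distal_cm2": 1.4, "beta_mmhg_cm": 800.0},
        ],
        "junctions": {"parent": ["child"]},
        "outlets": [{"vessel": "child", "r_proximal_mmhg_s_ml": 0.3,
                     "compliance_ml_mmhg": 0.1, "r_distal_mmhg_s_ml": 1.2,
                     "outflow_pressure_mmhg": 20.0}],
        "chains": [{"name": "AA", "side": "none", "segments": ["parent", "child"]}],
        "measurement_sites": [
            {"name": "P1", "side": "right", "vessel": "parent", "position": 0.5},
            {"name": "Q1", "side": "right", "vessel": "child", "position": 0.5},
        ],
    }


def make_fake_patient(subject_id, rng, diseased=False, period=0.9, n=64,
                      signal_sites=(), signal=0.0):
    """A patient with fabricated waveforms (no simulation) for bookkeeping
    and ML plumbing tests.  ``signal`` adds a class-dependent offset at the
    chosen sites so classifiers have something learnable."""
    series = {}
    t = np.arange(n) / n
    for key in SITE_KEYS:
        base = 100.0 if key.startswith("P") else 10.0
        wave = base * (1.0 + 0.2 * np.sin(2 * np.pi * t) + 0.05 * rng.normal(size=n))
        if diseased and key in signal_sites:
            wave = wave * (1.0 + signal)
        series[key] = wave
    ws = WaveformSet(series=series, period=period, n_samples=n)
    spec = DiseaseSpec("aneurysm", 8.0, 0.3, 0.7, 0.5, "AA", "none") if diseased else None
    return VirtualPatient(
        subject_id=subject_id,
        params=SubjectParameters(period=period),
        label="diseased" if diseased else "healthy",
        disease=spec,
        waveforms=ws,
    )


def make_twin_pools(n, rng, signal_sites=("Q1_R", "Q1_L"), signal=0.3):
    healthy = [make_fake_patient(i, rng) for i in range(n)]
    diseased = [make_fake_patient(i, rng, diseased=True,
                                  signal_sites=signal_sites, signal=signal)
                for i in range(n)]
    return healthy, diseased


@pytest.fixture(scope="session")
def reference_network():
    return default_network()


COHORT_PAIRS = 60


@pytest.fixture(scope="session")
def aaa_cohort():
    """AAA twin pairs on the packaged network (shared across tests)."""
    rng = np.random.default_rng(123)
    return generate_twin_cohort(COHORT_PAIRS, "AAA", rng)


@pytest.fixture(scope="session")
def aaal_cohort(aaa_cohort):
    """AAA-L twins of the same healthy subjects (matched AA-chain grid)."""
    healthy, _ = aaa_cohort
    rng = np.random.default_rng(456)
    return generate_twin_cohort(COHORT_PAIRS, "AAA-L", rng, healthy=healthy)
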