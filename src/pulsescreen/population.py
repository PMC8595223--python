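"""Virtual patient cohorts: healthy subject sampling, diseased twins, and
train/validation/test assembly.

A healthy virtual subject is the packaged reference network perturbed by a
small set of global physiological scale factors (cardiac period, inflow
amplitude, vessel areas and stiffness, peripheral resistance and compliance,
mild left/right asymmetry).  Each diseased patient is the *twin* of a healthy
subject: identical subject parameters, plus one randomly sampled lesion,
re-simulated.  Datasets are assembled in three steps: (1) a random half of
the healthy subjects enters as healthy and the diseased twins of the other
half enter as diseased, so no subject appears with both labels; (2) the two
halves are pooled 50/50; (3) the pool is split at random into 2/3 train and
1/3 test (or 50/25/25 train/validation/test when a validation partition is
needed for early stopping).  "Fivefold validation" re-runs step 3 five times
on the same pool.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .disease import (DiseaseSpec, apply_disease, refine_chain, sample_disease,
                      SEVERITY_BANDS)
from .features import fourier_coefficients, FourierFeatures
from .network import InflowWaveform, NetworkTopology, default_network
from .solver import SolverError, SolverSettings, WaveformSet, simulate

__all__ = [
    "SubjectParameters",
    "VariabilityConfig",
    "VirtualPatient",
    "MLDataset",
    "build_subject_network",
    "sample_healthy_subject",
    "generate_vpd",
    "generate_twin_cohort",
    "assemble_ml_dataset",
    "fivefold_resplits",
    "cohort_solver_settings",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SubjectParameters:
    """Global physiological scale factors defining one virtual subject."""

    period: float  # cardiac period T, s
    inflow_scale: float = 1.0  # inflow amplitude multiplier
    area_scale: float = 1.0  # global reference-area multiplier
    stiffness_scale: float = 1.0  # global tube-law beta multiplier
    resistance_scale: float = 1.0  # Windkessel R1, R2 multiplier
    compliance_scale: float = 1.0  # Windkessel C multiplier
    asymmetry_right: float = 1.0  # extra area factor, right-side vessels
    asymmetry_left: float = 1.0

    def __post_init__(self) -> None:
        for name in ("period", "inflow_scale", "area_scale", "stiffness_scale",
                     "resistance_scale", "compliance_scale",
                     "asymmetry_right", "asymmetry_left"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class VariabilityConfig:
    """Sampling bands for subject parameters and the plausibility filter.

    Defaults: +/-20% uniform bands on all global scales, cardiac period
    uniform on 0.7–1.1 s, +/-5% left/right area asymmetry.  A subject is
    accepted only if its right brachial pressure is plausible (systolic in
    [90, 180] mmHg, diastolic in [50, 100] mmHg).  These bands are package
    defaults standing in for a population generator, not literature values.
    """

    period: tuple[float, float] = (0.7, 1.1)
    inflow_scale: tuple[float, float] = (0.8, 1.2)
    area_scale: tuple[float, float] = (0.8, 1.2)
    stiffness_scale: tuple[float, float] = (0.8, 1.2)
    resistance_scale: tuple[float, float] = (0.8, 1.2)
    compliance_scale: tuple[float, float] = (0.8, 1.2)
    asymmetry: tuple[float, float] = (0.95, 1.05)
    systolic_range: tuple[float, float] = (90.0, 180.0)  # mmHg
    diastolic_range: tuple[float, float] = (50.0, 100.0)  # mmHg
    filter_site: str = "P2_R"  # brachial pressure
    max_rejection_rate: float = 0.8  # error beyond this over a batch

    def sample(self, rng: np.random.Generator) -> SubjectParameters:
        u = rng.uniform
        return SubjectParameters(
            period=u(*self.period),
            inflow_scale=u(*self.inflow_scale),
            area_scale=u(*self.area_scale),
            stiffness_scale=u(*self.stiffness_scale),
            resistance_scale=u(*self.resistance_scale),
            compliance_scale=u(*self.compliance_scale),
            asymmetry_right=u(*self.asymmetry),
            asymmetry_left=u(*self.asymmetry),
        )

    def passes(self, waveforms: WaveformSet) -> bool:
        p = waveforms[self.filter_site]
        sys_ok = self.systolic_range[0] <= p.max() <= self.systolic_range[1]
        dia_ok = self.diastolic_range[0] <= p.min() <= self.diastolic_range[1]
        return bool(sys_ok and dia_ok)


@dataclass
class VirtualPatient:
    """One simulated subject: parameters, optional lesion, waveforms."""

    subject_id: int
    params: SubjectParameters
    label: str  # "healthy" | "diseased"
    disease: DiseaseSpec | None
    waveforms: WaveformSet
    _fourier: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if (self.label == "diseased") != (self.disease is not None):
            raise ValueError("diseased patients carry a DiseaseSpec, healthy do not")

    def fourier(self, site: str, order: int = 5) -> FourierFeatures:
        """Memoised Fourier features of one site's waveform."""
        key = (site, order)
        if key not in self._fourier:
            self._fourier[key] = fourier_coefficients(
                self.waveforms[site], self.waveforms.period, order, site=site)
        return self._fourier[key]


def cohort_solver_settings() -> SolverSettings:
    """Solver settings used for cohort generation.

    Warm initial pressure near the working mean shortens the transient, and
    the larger cycle budget accommodates the slow filling transient of
    high-severity wide aneurysms.
    """
    return SolverSettings(init_pressure=95.0, max_cycles=80)


def _warm_settings(net: NetworkTopology, settings: SolverSettings) -> SolverSettings:
    """Initialise at the subject's estimated working mean pressure.

    The converged periodic state does not depend on the initial state; a
    start near mean inflow x parallel outlet resistance just cuts several
    relaxation cycles per subject.  The 1.15 factor absorbs the pulsatile /
    nonlinear offset between that DC estimate and the realised cycle mean.
    """
    r_par = 1.0 / sum(1.0 / (o.r_proximal + o.r_distal)
                      for o in net.outlets.values())
    p_out = np.mean([o.outflow_pressure for o in net.outlets.values()])
    p0 = float(np.clip(p_out + 1.15 * net.inflow.mean_flow * r_par, 60.0, 140.0))
    return replace(settings, init_pressure=p0)


def build_subject_network(base: NetworkTopology, params: SubjectParameters) -> NetworkTopology:
    """Instantiate the reference network for one subject."""
    net = base.copy()
    asym = {"right": params.asymmetry_right, "left": params.asymmetry_left, "none": 1.0}
    for v in net.vessels.values():
        f = params.area_scale * asym[v.side]
        v.ref_area_proximal *= f
        v.ref_area_distal *= f
        v.beta *= params.stiffness_scale
    for o in net.outlets.values():
        o.r_proximal *= params.resistance_scale
        o.r_distal *= params.resistance_scale
        o.compliance *= params.compliance_scale
    net.inflow = InflowWaveform(
        phase=base.inflow.phase.copy(),
        flow=base.inflow.flow * params.inflow_scale,
        period=params.period,
    )
    return net


class RejectionRateExceeded(RuntimeError):
    """Plausibility filter rejected too many candidates (mis-specified bands)."""


def sample_healthy_subject(
    rng: np.random.Generator,
    base: NetworkTopology | None = None,
    variability: VariabilityConfig | None = None,
    settings: SolverSettings | None = None,
    subject_id: int = 0,
    max_tries: int | None = None,
    refine_form: str | None = None,
) -> VirtualPatient:
    """Draw subject parameters, simulate, and apply the plausibility filter.

    Candidates failing the filter (or the solver) are redrawn; exceeding
    ``max_tries`` raises :class:`RejectionRateExceeded`.  ``refine_form``
    pre-refines that form's chain grid so the subject is directly comparable
    with a diseased twin (see :func:`~pulsescreen.disease.refine_chain`);
    healthy and diseased twins are always simulated on identical grids.
    """
    base = base if base is not None else default_network()
    variability = variability or VariabilityConfig()
    settings = settings or cohort_solver_settings()
    if max_tries is None:
        # enough attempts that exceeding them implies the realised rejection
        # rate is far beyond the configured cap
        max_tries = max(3, int(math.ceil(8.0 / (1.0 - variability.max_rejection_rate))))
    for _ in range(max_tries):
        params = variability.sample(rng)
        net = build_subject_network(base, params)
        if refine_form is not None:
            refine_chain(net, SEVERITY_BANDS[refine_form][0])
        try:
            ws = simulate(net, _warm_settings(net, settings))
        except SolverError as exc:
            log.info("subject %d candidate failed solver: %s", subject_id, exc)
            continue
        if variability.passes(ws):
            return VirtualPatient(subject_id=subject_id, params=params,
                                  label="healthy", disease=None, waveforms=ws)
        log.debug("subject %d candidate rejected by plausibility filter", subject_id)
    raise RejectionRateExceeded(
        f"no plausible subject in {max_tries} draws; variability bands "
        "are likely mis-specified")


def _diseased_twin(
    healthy: VirtualPatient,
    form: str,
    rng: np.random.Generator,
    base: NetworkTopology,
    settings: SolverSettings,
    severity_band: tuple[float, float] | None = None,
) -> VirtualPatient:
    spec = sample_disease(rng, form, severity_band)
    net = build_subject_network(base, healthy.params)
    refine_chain(net, SEVERITY_BANDS[form][0])  # grid identical to the twin's
    net = apply_disease(net, spec)
    ws = simulate(net, _warm_settings(net, settings))
    return VirtualPatient(subject_id=healthy.subject_id, params=healthy.params,
                          label="diseased", disease=spec, waveforms=ws)


def generate_twin_cohort(
    n: int,
    form: str,
    rng: np.random.Generator,
    base: NetworkTopology | None = None,
    variability: VariabilityConfig | None = None,
    settings: SolverSettings | None = None,
    severity_band: tuple[float, float] | None = None,
    healthy: list[VirtualPatient] | None = None,
    max_failure_rate: float = 0.05,
) -> tuple[list[VirtualPatient], list[VirtualPatient]]:
    """n twin pairs (healthy subject, diseased counterpart) for one form.

    If a healthy pool is supplied its subjects are reused; a solver failure
    on a diseased twin resamples that subject's lesion (and, for generated
    subjects, the subject itself), keeping pairing exact.  Failures beyond
    ``max_failure_rate`` of the requested pairs abort.
    """
    if form not in SEVERITY_BANDS:
        raise ValueError(f"unknown disease form {form!r}")
    base = base if base is not None else default_network()
    variability = variability or VariabilityConfig()
    settings = settings or cohort_solver_settings()
    healthy_out: list[VirtualPatient] = []
    diseased_out: list[VirtualPatient] = []
    failures = 0
    max_failures = max(1, int(math.ceil(max_failure_rate * n * 4)))
    for i in range(n):
        while True:
            if healthy is not None:
                h = healthy[i]
            else:
                h = sample_healthy_subject(rng, base, variability, settings,
                                           subject_id=i, refine_form=form)
            try:
                d = _diseased_twin(h, form, rng, base, settings, severity_band)
                break
            except SolverError as exc:
                failures += 1
                log.info("diseased twin of subject %d failed (%s); resampling", i, exc)
                if failures > max_failures:
                    raise SolverError(
                        f"{failures} solver failures while building {form} cohort "
                        "(exceeds failure budget)") from exc
        healthy_out.append(h)
        diseased_out.append(d)
    if failures:
        log.warning("%s cohort: %d lesion resample(s) due to solver failures",
                    form, failures)
    return healthy_out, diseased_out


def generate_vpd(
    n: int,
    form: str,
    rng: np.random.Generator,
    base: NetworkTopology | None = None,
    variability: VariabilityConfig | None = None,
    settings: SolverSettings | None = None,
    healthy: list[VirtualPatient] | None = None,
) -> list[VirtualPatient]:
    """Generate a virtual patient database of one form.

    ``form="none"`` gives healthy subjects; disease forms give the diseased
    twins of the supplied (or freshly generated) healthy subjects.  AAA-L
    uses the low-severity band 3.0–7.0.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if form == "none":
        base = base if base is not None else default_network()
        variability = variability or VariabilityConfig()
        settings = settings or cohort_solver_settings()
        return [sample_healthy_subject(rng, base, variability, settings, subject_id=i)
                for i in range(n)]
    _, diseased = generate_twin_cohort(
        n, form, rng, base, variability, settings, healthy=healthy)
    return diseased


# -- dataset assembly ------------------------------------------------------


@dataclass
class MLDataset:
    """Subject-level partitions of one assembled 50/50 pool."""

    train: list[VirtualPatient]
    test: list[VirtualPatient]
    validation: list[VirtualPatient] | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def pool(self) -> list[VirtualPatient]:
        out = list(self.train)
        if self.validation:
            out.extend(self.validation)
        out.extend(self.test)
        return out

    def check_twin_exclusivity(self) -> None:
        labels: dict[int, str] = {}
        for p in self.pool:
            if labels.setdefault(p.subject_id, p.label) != p.label:
                raise ValueError(
                    f"subject {p.subject_id} appears as both healthy and diseased")


def _step12_pool(
    healthy: list[VirtualPatient],
    diseased: list[VirtualPatient],
    rng: np.random.Generator,
) -> list[VirtualPatient]:
    """Steps 1–2: split subjects in half, healthy half + diseased twins of
    the other half, pooled with exact 50/50 class balance."""
    if len(healthy) != len(diseased):
        raise ValueError("healthy and diseased pools must be twin-paired (equal size)")
    d_by_id = {p.subject_id: p for p in diseased}
    for h in healthy:
        if h.subject_id not in d_by_id:
            raise ValueError(f"subject {h.subject_id} has no diseased twin")
    n = len(healthy)
    half = n // 2  # floor rule for odd pools: both halves get floor(n/2)
    perm = rng.permutation(n)
    healthy_half = [healthy[i] for i in perm[:half]]
    diseased_half = [d_by_id[healthy[i].subject_id] for i in perm[half:half + half]]
    return healthy_half + diseased_half


def _split(pool, rng, early_stopping):
    n = len(pool)
    perm = rng.permutation(n)
    if early_stopping:  # 50/25/25 with floor on the held-out parts
        n_val = n // 4
        n_test = n // 4
        n_train = n - n_val - n_test
        train = [pool[i] for i in perm[:n_train]]
        val = [pool[i] for i in perm[n_train:n_train + n_val]]
        test = [pool[i] for i in perm[n_train + n_val:]]
        return train, val, test
    n_test = n // 3  # floor on the test set
    test = [pool[i] for i in perm[:n_test]]
    train = [pool[i] for i in perm[n_test:]]
    return train, None, test


def assemble_ml_dataset(
    healthy: list[VirtualPatient],
    diseased: list[VirtualPatient],
    rng: np.random.Generator,
    early_stopping: bool = False,
) -> MLDataset:
    """Steps 1–3: build one train/(validation/)test dataset from twin pools."""
    pool = _step12_pool(healthy, diseased, rng)
    train, val, test = _split(pool, rng, early_stopping)
    ds = MLDataset(train=train, test=test, validation=val,
                   provenance={"n_pairs": len(healthy),
                               "early_stopping": early_stopping})
    ds.check_twin_exclusivity()
    return ds


def fivefold_resplits(
    healthy: list[VirtualPatient],
    diseased: list[VirtualPatient],
    rng: np.random.Generator,
    n_folds: int = 5,
    early_stopping: bool = False,
) -> list[MLDataset]:
    """Five independent step-3 resplits of one step-2 pool.

    All folds share the identical pool (one step-1 draw); only the
    train/test partition is redrawn per fold.
    """
    pool = _step12_pool(healthy, diseased, rng)
    out = []
    for fold in range(n_folds):
        train, val, test = _split(pool, rng, early_stopping)
        ds = MLDataset(train=train, test=test, validation=val,
                       provenance={"fold": fold + 1, "n_pairs": len(healthy),
                                   "early_stopping": early_stopping})
        ds.check_twin_exclusivity()
        out.append(ds)
    return out
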