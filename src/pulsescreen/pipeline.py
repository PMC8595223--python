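"""Seeded end-to-end runs: generate → featurize → evaluate → report.

A run is fully specified by a :class:`RunConfig` plus a master seed; every
numeric artifact is reproducible from those alone.  Stages write plain
delimited tables plus a JSON manifest (config hash, seed, stage inputs), so
a rerun with the same config and seed is byte-identical and completed stages
are reused on resume.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classifiers import DESK_GRIDS, FULL_GRIDS, ClassifierConfig
from .disease import SEVERITY_BANDS
from .evaluation import (
    combination_search,
    measurement_importance,
    q1_partition,
    summarise_by_count,
)
from .features import MEASUREMENTS, MeasurementCombination, assemble_features
from .network import default_network, load_network
from .population import (
    VariabilityConfig,
    cohort_solver_settings,
    generate_twin_cohort,
)

__all__ = ["RunConfig", "run_stage", "run_all", "STAGES"]

log = logging.getLogger(__name__)

STAGES = ("generate", "featurize", "evaluate", "report")
#: generation simulates in one pass and evaluation trains the classifiers,
#: so the finer-grained stage names resolve onto the owning stage
STAGE_ALIASES = {"simulate": "generate", "train": "evaluate"}

_FLOAT_FMT = "%.10g"  # fixed format => byte-identical tables across reruns


@dataclass
class RunConfig:
    """Everything needed to reproduce a run (see module docstring)."""

    form: str = "AAA"  # CAS | SAS | PAD | AAA | AAA-L
    n_pairs: int = 50
    methods: tuple[str, ...] = ("RF", "GB")
    measurements: tuple[str, ...] = MEASUREMENTS
    laterality: str = "bilateral"
    n_folds: int = 5
    feature_order: int = 5
    seed: int = 0
    network_config: str | None = None  # path; packaged default when None
    use_full_grids: bool = False
    method_params: dict = field(default_factory=lambda: {
        "RF": {"n_estimators": 100, "max_depth": 50},
        "GB": {"n_estimators": 100, "max_depth": 6},
        "MLP": {"neurons": 60, "layers": 2},
    })
    out_dir: str = "runs"

    def __post_init__(self) -> None:
        if self.form not in SEVERITY_BANDS:
            raise ValueError(f"unknown disease form {self.form!r}")
        self.methods = tuple(self.methods)
        self.measurements = tuple(self.measurements)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def _manifest_path(out: Path, stage: str) -> Path:
    return out / f"{stage}.manifest.json"


def _write_manifest(out: Path, stage: str, cfg: RunConfig, extra: dict) -> None:
    manifest = {
        "stage": stage,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "inputs": extra,
    }
    _manifest_path(out, stage).write_text(json.dumps(manifest, indent=1, sort_keys=True))


def _check_manifest(out: Path, stage: str, cfg: RunConfig) -> bool:
    path = _manifest_path(out, stage)
    if not path.exists():
        return False
    manifest = json.loads(path.read_text())
    if manifest.get("config_hash") != cfg.config_hash():
        raise RuntimeError(
            f"stage {stage!r}: existing artifacts were produced with a "
            "different config; remove the output directory to rerun")
    return True


def _patients_table(patients) -> pd.DataFrame:
    rows = []
    for p in patients:
        d = p.disease
        rows.append({
            "subject_id": p.subject_id,
            "label": p.label,
            "period_s": p.params.period,
            "kind": d.kind if d else "",
            "severity": d.severity if d else np.nan,
            "start": d.start if d else np.nan,
            "end": d.end if d else np.nan,
            "chain": d.chain if d else "",
            "side": d.side if d else "",
        })
    return pd.DataFrame(rows)


def run_stage(stage: str, cfg: RunConfig, _cache: dict | None = None) -> Path:
    """Run one stage (reusing cached upstream artifacts) and return its
    output directory.  ``_cache`` carries in-memory patients between stages
    within one process; on resume they are regenerated from the manifest
    seed, which yields identical results."""
    stage = STAGE_ALIASES.get(stage, stage)
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cache = _cache if _cache is not None else {}

    def patients():
        if "patients" not in cache:
            base = (load_network(cfg.network_config) if cfg.network_config
                    else default_network())
            rng = np.random.default_rng(cfg.seed)
            cache["patients"] = generate_twin_cohort(
                cfg.n_pairs, cfg.form, rng, base=base,
                variability=VariabilityConfig(),
                settings=cohort_solver_settings())
        return cache["patients"]

    if stage == "generate":
        if _check_manifest(out, stage, cfg):
            log.info("generate: cached")
            return out
        healthy, diseased = patients()
        _patients_table(healthy + diseased).to_csv(
            out / "patients.csv", index=False, float_format=_FLOAT_FMT)
        frames = []
        for p in healthy + diseased:
            df = p.waveforms.to_frame()
            df.insert(0, "label", p.label)
            df.insert(0, "subject_id", p.subject_id)
            frames.append(df)
        pd.concat(frames).to_csv(out / "waveforms.csv", index=False,
                                 float_format=_FLOAT_FMT)
        _write_manifest(out, stage, cfg, {"n_pairs": cfg.n_pairs})
        return out

    if stage == "featurize":
        run_stage("generate", cfg, cache)
        if _check_manifest(out, stage, cfg):
            return out
        healthy, diseased = patients()
        combo = MeasurementCombination(cfg.measurements, cfg.laterality)
        X, y, ids, cols = assemble_features(healthy + diseased, combo,
                                            cfg.feature_order)
        df = pd.DataFrame(X, columns=cols)
        df.insert(0, "label", y)
        df.insert(0, "subject_id", ids)
        df.to_csv(out / "features.csv", index=False, float_format=_FLOAT_FMT)
        _write_manifest(out, stage, cfg, {"width": len(cols)})
        return out

    if stage == "evaluate":
        run_stage("featurize", cfg, cache)
        if _check_manifest(out, stage, cfg):
            return out
        healthy, diseased = patients()
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
        records = combination_search(
            cfg.form, cfg.methods, healthy, diseased, rng,
            method_params=cfg.method_params,
            measurements=cfg.measurements, laterality=cfg.laterality,
            n_folds=cfg.n_folds, order=cfg.feature_order, seed=cfg.seed)
        records.to_csv(out / "evaluation.csv", index=False,
                       float_format=_FLOAT_FMT)
        _write_manifest(out, stage, cfg, {"n_records": len(records)})
        return out

    # report
    run_stage("evaluate", cfg, cache)
    if _check_manifest(out, stage, cfg):
        return out
    records = pd.read_csv(out / "evaluation.csv")
    summarise_by_count(records).to_csv(out / "summary_by_count.csv",
                                       index=False, float_format=_FLOAT_FMT)
    part = q1_partition(records)
    hist = pd.DataFrame({
        "bin_left": part["bins"][:-1],
        "bin_right": part["bins"][1:],
        "include_q1": part["include_hist"],
        "exclude_q1": part["exclude_hist"],
    })
    hist.to_csv(out / "q1_histograms.csv", index=False, float_format=_FLOAT_FMT)
    _write_manifest(out, stage, cfg, {})
    return out


def run_all(cfg: RunConfig) -> Path:
    cache: dict = {}
    for stage in STAGES:
        run_stage(stage, cfg, cache)
    return Path(cfg.out_dir)


def grids_for(cfg: RunConfig) -> dict:
    return FULL_GRIDS if cfg.use_full_grids else DESK_GRIDS
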