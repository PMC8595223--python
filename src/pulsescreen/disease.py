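"""Disease geometry: cosine area profiles and random lesion sampling.

A lesion is a smooth multiplicative perturbation of the reference area along
one vessel chain, parameterised by severity S, start b, end e (normalised
chain coordinates) and a reference location r used only during sampling to
enforce a minimum lesion length of 10% of the chain.  A stenosis of severity
S reduces the area to (1 - S) at the lesion midpoint; an aneurysm inflates it
to (1 + S).  The profile is continuous, equal to 1 at b and e, and symmetric
about the midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .network import NetworkTopology, VesselChain, chain_coordinate

__all__ = [
    "DiseaseSpec",
    "SEVERITY_BANDS",
    "DISEASE_FORMS",
    "area_multiplier",
    "sample_disease",
    "apply_disease",
    "refine_chain",
    "specs_to_table",
    "specs_from_table",
]

#: disease form -> (chain name, lesion kind, severity band)
SEVERITY_BANDS: dict[str, tuple[str, str, tuple[float, float]]] = {
    "CAS": ("CA", "stenosis", (0.5, 0.95)),
    "SAS": ("SA", "stenosis", (0.5, 0.95)),
    "PAD": ("PA", "stenosis", (0.5, 0.95)),
    "AAA": ("AA", "aneurysm", (7.13, 25.93)),
    "AAA-L": ("AA", "aneurysm", (3.0, 7.0)),
}

DISEASE_FORMS = tuple(SEVERITY_BANDS)

_STENOSIS_BAND = (0.5, 0.95)


@dataclass(frozen=True)
class DiseaseSpec:
    """One lesion on one chain: kind, severity and normalised extent."""

    kind: str  # "stenosis" | "aneurysm"
    severity: float
    start: float  # b, normalised chain coordinate
    end: float  # e
    reference: float  # r, sampling helper
    chain: str  # CA | SA | PA | AA
    side: str  # "left" | "right" | "none"

    def __post_init__(self) -> None:
        if self.kind not in ("stenosis", "aneurysm"):
            raise ValueError(f"unknown lesion kind {self.kind!r}")
        if not (0.1 <= self.start < self.end <= 0.9):
            raise ValueError(f"lesion extent [{self.start}, {self.end}] outside [0.1, 0.9]")
        if self.end - self.start < 0.1 - 1e-12:
            raise ValueError("lesion must span at least 10% of the chain")
        if self.kind == "stenosis" and not (_STENOSIS_BAND[0] <= self.severity <= _STENOSIS_BAND[1]):
            raise ValueError(f"stenosis severity {self.severity} outside {_STENOSIS_BAND}")
        if self.severity <= 0:
            raise ValueError("severity must be > 0")


def area_multiplier(x_n: np.ndarray | float, spec: DiseaseSpec) -> np.ndarray | float:
    """Normalised area A_n at chain coordinate x_n.

    Inside [b, e] the profile is ``(1 -/+ S/2) +/- (S/2) cos(2 pi (x_n - b)
    / (e - b))`` (upper signs: stenosis), i.e. 1 at both edges and 1 -/+ S at
    the midpoint; outside it is identically 1.
    """
    x = np.asarray(x_n, dtype=float)
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError("x_n must be in [0, 1]")
    theta = 2.0 * np.pi * (x - spec.start) / (spec.end - spec.start)
    half = 0.5 * spec.severity
    if spec.kind == "stenosis":
        prof = (1.0 - half) + half * np.cos(theta)
    else:
        prof = (1.0 + half) - half * np.cos(theta)
    out = np.where((x >= spec.start) & (x <= spec.end), prof, 1.0)
    if out.ndim == 0:
        return float(out)
    return out


def sample_disease(
    rng: np.random.Generator,
    form: str,
    severity_band: tuple[float, float] | None = None,
) -> DiseaseSpec:
    """Draw a random lesion for one disease form.

    Parameters are sampled sequentially from uniform distributions:
    r ~ U(0.2, 0.8), b ~ U(0.1, r - 0.05), e ~ U(r + 0.05, 0.9), then the
    severity from its band.  The +/-0.05 exclusion around r enforces lesion
    length >= 0.1.  For the bilateral chains (CA, SA, PA) the side is drawn
    with equal probability; the abdominal aorta is midline.
    """
    try:
        chain, kind, band = SEVERITY_BANDS[form]
    except KeyError:
        raise ValueError(f"unknown disease form {form!r}; expected one of {DISEASE_FORMS}") from None
    if severity_band is not None:
        band = severity_band
    lo, hi = band
    if not 0 < lo <= hi:
        raise ValueError(f"degenerate severity band {band}")
    r = rng.uniform(0.2, 0.8)
    b = rng.uniform(0.1, r - 0.05)
    e = rng.uniform(r + 0.05, 0.9)
    s = rng.uniform(lo, hi)
    side = "none" if chain == "AA" else ("right" if rng.random() < 0.5 else "left")
    return DiseaseSpec(kind=kind, severity=s, start=b, end=e, reference=r,
                       chain=chain, side=side)


def apply_disease(network: NetworkTopology, spec: DiseaseSpec) -> NetworkTopology:
    """Return a deep copy of ``network`` with the lesion imposed on its chain.

    The chain-coordinate profile is composed onto each member segment's area
    multiplier; segments outside the chain are untouched.
    """
    chain = network.chain(spec.chain, spec.side)  # raises KeyError if absent
    diseased = network.copy()
    total = chain.total_length
    # the solver grid must resolve the lesion: the minimum admissible lesion
    # spans 10% of the chain, so chain/80 guarantees >= 8 cells across any
    # lesion.  The cap is lesion-independent so that a healthy twin simulated
    # with refine_chain() shares the identical grid (no resolution artefact
    # separating the classes).
    lesion_dx = total / 80.0
    offset = 0.0
    for seg, length in zip(chain.segments, chain.lengths):
        vessel = diseased.vessels[seg]
        lo, ln, tot = offset, length, total

        def seg_multiplier(xi, _lo=lo, _ln=ln, _tot=tot, _spec=spec):
            x_n = (_lo + np.asarray(xi, dtype=float) * _ln) / _tot
            return area_multiplier(np.clip(x_n, 0.0, 1.0), _spec)

        prev = vessel.area_scale
        if prev is None:
            vessel.area_scale = seg_multiplier
        else:  # compose with any existing profile
            vessel.area_scale = lambda xi, _p=prev, _m=seg_multiplier: (
                np.asarray(_p(xi), dtype=float) * np.asarray(_m(xi), dtype=float))
        vessel.refine_dx = (lesion_dx if vessel.refine_dx is None
                            else min(vessel.refine_dx, lesion_dx))
        offset += length
    return diseased


def specs_to_table(specs) -> "pd.DataFrame":
    """Batch lesion specs as a delimited-table-ready frame (one row each)."""
    import pandas as pd

    return pd.DataFrame([{
        "kind": s.kind, "severity": s.severity, "start": s.start,
        "end": s.end, "reference": s.reference, "chain": s.chain,
        "side": s.side} for s in specs])


def specs_from_table(table) -> list[DiseaseSpec]:
    """Inverse of :func:`specs_to_table` (re-validates every row)."""
    return [DiseaseSpec(kind=r.kind, severity=float(r.severity),
                        start=float(r.start), end=float(r.end),
                        reference=float(r.reference), chain=r.chain,
                        side=r.side)
            for r in table.itertuples(index=False)]


def refine_chain(network: NetworkTopology, chain_name: str) -> None:
    """Refine all instances of a chain (both sides) to the lesion-ready grid.

    Applied in place.  Used on healthy subjects so that a diseased twin
    (whose chain :func:`apply_disease` refines identically) is compared on
    the same numerical grid — waveform differences between the twins are
    then purely haemodynamic.
    """
    for (name, _side), chain in network.chains.items():
        if name != chain_name:
            continue
        dx = chain.total_length / 80.0
        for seg in chain.segments:
            v = network.vessels[seg]
            v.refine_dx = dx if v.refine_dx is None else min(v.refine_dx, dx)
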