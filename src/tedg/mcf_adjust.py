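"""Mutation cell frequency (MCF) estimation from raw measurements.

MCF is the fraction of tumor cells carrying a lesion.  It unifies two
assay types: FISH fractions are divided by the FACS tumor-cell fraction,
and sequencing mutant-allele frequencies (MAF) are mapped through one of
three estimators:

* piecewise — ``2*MAF`` capped at 1 (heterozygous diploid);
* Hill — a smooth sigmoid ``K*MAF^n / (1 + K*MAF^n)`` whose parameters
  are calibrated by grid search so the curve tracks ``2*MAF`` on
  [0, 0.5]; the calibrated optimum is (K=16, n=2);
* deletion-adjusted Hill — for genes co-affected by a heterozygous
  deletion, where ``MCF_mut = MAF * (2 - MCF_del)``, the Hill target is
  ``(2 - MCF_del) * MAF`` instead.

Copy-neutral LOH and homozygous deletions are not modeled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from tedg.cohort_io import LesionMeasurement

logger = logging.getLogger(__name__)

#: Default gene -> co-measured deletion pairing (CLL drivers).
DEFAULT_DELETION_PAIRS = {"TP53": "del17p", "BIRC3": "delBIRC3"}

#: Midpoint-rule nodes for the calibration integral on [0, 0.5].
INTEGRATION_POINTS = 10_000

#: Grid-search domain: K over powers of two, n over small integers.
K_GRID = tuple(2.0 ** a for a in range(10))
N_GRID = tuple(range(1, 11))


@dataclass(frozen=True)
class HillParams:
    """Hill-function parameters: MCF = K*MAF^n / (1 + K*MAF^n)."""

    K: float
    n: float

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ValueError(f"K must be > 0, got {self.K}")
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")


@dataclass
class MCFProfile:
    """Per-sample lesion -> MCF map for one patient at one time."""

    patient_id: str
    sample_time: float
    mcf: dict[str, float] = field(default_factory=dict)
    method: str = "hill"

    def __post_init__(self) -> None:
        for lesion, v in self.mcf.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(
                    f"MCF out of [0, 1] for {lesion}: {v}")


def mcf_from_fish(fish_fraction: float, facs_fraction: float) -> float:
    """FISH abnormal-nuclei fraction corrected for tumor purity.

    Returns ``min(fish_fraction / facs_fraction, 1)``.
    """
    if not 0.0 <= fish_fraction <= 1.0:
        raise ValueError(f"fish_fraction out of [0, 1]: {fish_fraction}")
    if not 0.0 < facs_fraction <= 1.0:
        raise ValueError(f"facs_fraction out of (0, 1]: {facs_fraction}")
    return min(fish_fraction / facs_fraction, 1.0)


def mcf_piecewise(maf: float) -> float:
    """Piecewise diploid estimator: 2*MAF below 0.5, else 1."""
    if not 0.0 <= maf <= 1.0:
        raise ValueError(f"maf out of [0, 1]: {maf}")
    return 2.0 * maf if maf < 0.5 else 1.0


def mcf_hill(maf: float, params: HillParams) -> float:
    """Smooth Hill estimator K*maf^n / (1 + K*maf^n)."""
    if not 0.0 <= maf <= 1.0:
        raise ValueError(f"maf out of [0, 1]: {maf}")
    x = params.K * maf ** params.n
    return x / (1.0 + x)


def hill_objective(K: float, n: float, mcf_del: float = 0.0,
                   points: int = INTEGRATION_POINTS) -> float:
    """Squared-error integral of the Hill curve against its linear target.

    Integrates ``(K*m^n/(1+K*m^n) - (2 - mcf_del)*m)^2`` for m in
    [0, 0.5] by a fixed midpoint rule.  ``mcf_del = 0`` is the diploid
    case (target ``2*m``); a co-occurring heterozygous deletion with cell
    frequency ``mcf_del`` flattens the target to ``(2 - mcf_del)*m``.
    """
    if K <= 0 or n < 1:
        raise ValueError("require K > 0 and n >= 1")
    if not 0.0 <= mcf_del <= 1.0:
        raise ValueError(f"mcf_del out of [0, 1]: {mcf_del}")
    h = 0.5 / points
    m = (np.arange(points) + 0.5) * h
    hill = K * m ** n / (1.0 + K * m ** n)
    resid = hill - (2.0 - mcf_del) * m
    return float(np.sum(resid * resid) * h)


@lru_cache(maxsize=256)
def _fit_hill_cached(mcf_del_key: float) -> HillParams:
    best: tuple[float, float, float] | None = None
    for K in K_GRID:
        for n in N_GRID:
            f = hill_objective(K, n, mcf_del_key)
            # ties broken by smallest K, then smallest n (loop order)
            if best is None or f < best[0]:
                best = (f, K, n)
    assert best is not None
    return HillParams(K=best[1], n=float(best[2]))


def fit_hill(mcf_del: float = 0.0) -> HillParams:
    """Exhaustive grid search for the Hill parameters.

    K ranges over ``{2^0 .. 2^9}`` and n over ``{1 .. 10}``; returns the
    argmin of :func:`hill_objective`, with ties broken by smallest K
    then smallest n.  ``mcf_del = 0`` yields (K=16, n=2).
    """
    if not 0.0 <= mcf_del <= 1.0:
        raise ValueError(f"mcf_del out of [0, 1]: {mcf_del}")
    return _fit_hill_cached(round(float(mcf_del), 6))


def mcf_with_deletion(maf: float, mcf_del: float,
                      smoothed: bool = True) -> float:
    """MCF of a mutation in a gene carrying a heterozygous deletion.

    The exact relation is ``MCF_mut = MAF * (2 - MCF_del)``
    (``smoothed=False``).  The default applies the Hill curve fitted
    against that target, capped at 1.
    """
    if not 0.0 <= maf <= 1.0:
        raise ValueError(f"maf out of [0, 1]: {maf}")
    if not 0.0 <= mcf_del <= 1.0:
        raise ValueError(f"mcf_del out of [0, 1]: {mcf_del}")
    if not smoothed:
        return min(maf * (2.0 - mcf_del), 1.0)
    params = fit_hill(mcf_del)
    return min(mcf_hill(maf, params), 1.0)


def mcf_simple(maf: float, facs_fraction: float) -> float:
    """Textbook approximation 2*MAF / purity, capped at 1."""
    return min(2.0 * maf / facs_fraction, 1.0)


def adjust_sample(measurements: list[LesionMeasurement],
                  method: str = "hill",
                  deletion_pairs: dict[str, str] | None = None,
                  divide_purity: bool = True) -> MCFProfile:
    """Convert one sample's raw measurements into an MCF profile.

    All measurements must share (patient_id, sample_time).  FISH lesions
    are purity-corrected quotients.  NGS lesions go through the chosen
    estimator (``hill``, ``piecewise`` or ``simple``); genes paired with
    a co-measured deletion (e.g. TP53 <-> del17p) use the
    deletion-adjusted Hill curve with that deletion's MCF.  Unless
    ``divide_purity`` is False, NGS estimates are divided by the FACS
    fraction and capped at 1 (``simple`` already includes purity).

    A pairing that names a lesion absent from the sample falls back to
    the diploid Hill fit with a warning.
    """
    if not measurements:
        raise ValueError("empty sample")
    keys = {(m.patient_id, m.sample_time) for m in measurements}
    if len(keys) > 1:
        raise ValueError(f"measurements span multiple samples: {keys}")
    if method not in ("hill", "piecewise", "simple"):
        raise ValueError(f"unknown method {method!r}")
    patient_id, sample_time = next(iter(keys))
    if deletion_pairs is None:
        deletion_pairs = DEFAULT_DELETION_PAIRS

    fish_mcf: dict[str, float] = {}
    for m in measurements:
        if m.assay == "FISH":
            fish_mcf[m.lesion_id] = mcf_from_fish(m.raw_value,
                                                  m.facs_fraction)
    mcf: dict[str, float] = dict(fish_mcf)
    for m in measurements:
        if m.assay != "NGS":
            continue
        paired_del = deletion_pairs.get(m.lesion_id)
        if method == "simple":
            value = mcf_simple(m.raw_value, m.facs_fraction)
        elif method == "piecewise":
            value = mcf_piecewise(m.raw_value)
        elif paired_del is not None:
            if paired_del in fish_mcf:
                value = mcf_with_deletion(m.raw_value, fish_mcf[paired_del])
            else:
                logger.warning(
                    "sample (%s, %s): deletion pairing %s -> %s names an "
                    "absent lesion; using diploid Hill fit",
                    patient_id, sample_time, m.lesion_id, paired_del)
                value = mcf_hill(m.raw_value, fit_hill(0.0))
        else:
            value = mcf_hill(m.raw_value, fit_hill(0.0))
        if divide_purity and method != "simple":
            value = value / m.facs_fraction
        mcf[m.lesion_id] = min(value, 1.0)
    return MCFProfile(patient_id=patient_id, sample_time=sample_time,
                      mcf=mcf, method=method)


def adjust_cohort(cohort, method: str = "hill",
                  deletion_pairs: dict[str, str] | None = None,
                  divide_purity: bool = True) -> list[MCFProfile]:
    """Apply :func:`adjust_sample` to every (patient, time) sample."""
    profiles = []
    for pid in cohort.patients:
        for t in cohort.sample_times(pid):
            profiles.append(adjust_sample(
                cohort.patient_sample(pid, t), method=method,
                deletion_pairs=deletion_pairs,
                divide_purity=divide_purity))
    return profiles
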