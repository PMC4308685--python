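"""FEM — Fit the Evolutionary Model: clonal replacement detection.

Between two sequential samples, each lesion's frequency change is
standardized to a Z-score

    z = (f_curr - f_prev) / (sigma * sqrt(fbar * (1 - fbar))),

where fbar is the mean of the two frequencies and sigma an
assay-specific noise scale (one for sequencing, one for FISH) fitted
robustly from sample pairs not flanked by treatment.  For every sample
pair, one-sided p-values of the rising lesions are pooled with Fisher's
method into P_increase, and of the falling lesions into P_decrease.  A
pair significant on *both* axes shows a subclone expanding while another
contracts — clonal replacement, the signature of branching evolution;
patients with any such pair (after Benjamini-Hochberg control across
pairs) are classified branching, all others gradual-linear.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from tedg.cohort_io import CohortTable

logger = logging.getLogger(__name__)

#: Frequency-mean clamp, a coverage proxy (~1/(2*1000x depth)).
EPS_FBAR = 1.0 / 2000.0

SIGMA_FLOOR = 1e-6

#: Gaussian consistency factor: 1.4826 * MAD estimates the SD.
MAD_SCALE = 1.4826


@dataclass
class LesionZ:
    lesion_id: str
    assay: str
    f_prev: float
    f_curr: float
    z: float
    p_one_sided: float


@dataclass
class ReplacementCall:
    patient_id: str
    sample_pair: tuple[float, float]
    p_increase: float
    p_decrease: float
    replacement: bool = False
    lesion_z: list[LesionZ] = field(default_factory=list)


def zscore(f_prev: float, f_curr: float, sigma: float) -> float:
    """Standardized frequency change between two samples.

    z = (f_curr - f_prev) / (sigma * sqrt(fbar (1 - fbar))) with
    fbar = (f_prev + f_curr)/2 clamped away from {0, 1} so fully absent
    or fully clonal pairs stay finite.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    fbar = (f_prev + f_curr) / 2.0
    fbar = min(max(fbar, EPS_FBAR), 1.0 - EPS_FBAR)
    return (f_curr - f_prev) / (sigma * math.sqrt(fbar * (1.0 - fbar)))


def _pair_changes(cohort: CohortTable, exclude_treated: bool = True
                  ) -> dict[str, list[float]]:
    """Standardized (sigma-free) frequency changes per assay.

    Iterates consecutive sample pairs per patient and lesion; a pair is
    skipped when the later sample records an intervening treatment (and
    ``exclude_treated``).  Values are Delta f / sqrt(fbar (1 - fbar)).
    """
    changes: dict[str, list[float]] = {"NGS": [], "FISH": []}
    excluded = 0
    for pid in cohort.patients:
        times = cohort.sample_times(pid)
        for t_prev, t_curr in zip(times, times[1:]):
            prev = {(m.lesion_id, m.assay): m
                    for m in cohort.patient_sample(pid, t_prev)}
            curr = {(m.lesion_id, m.assay): m
                    for m in cohort.patient_sample(pid, t_curr)}
            treated = any(m.treatment_before_sample for m in curr.values())
            if exclude_treated and treated:
                excluded += 1
                continue
            for key in sorted(prev.keys() & curr.keys()):
                _lesion, assay = key
                f1, f2 = prev[key].raw_value, curr[key].raw_value
                fbar = (f1 + f2) / 2.0
                fbar = min(max(fbar, EPS_FBAR), 1.0 - EPS_FBAR)
                changes[assay].append(
                    (f2 - f1) / math.sqrt(fbar * (1.0 - fbar)))
    if excluded:
        logger.info("fit_sigma: excluded %d treatment-flanked sample "
                    "pairs", excluded)
    return changes


def fit_sigma(cohort: CohortTable, exclude_treated: bool = True,
              min_obs: int = 5) -> tuple[float, float]:
    """Robust per-assay noise scales (sigma_seq, sigma_fish).

    Standardized changes from sample pairs with no recorded intervening
    treatment are summarized by 1.4826 * MAD, so that background
    Z-scores are approximately standard normal even in the presence of
    genuine clonal expansions (which the median absolute deviation
    ignores).  Raises if fewer than ``min_obs`` usable changes exist
    for an assay present in the cohort.
    """
    changes = _pair_changes(cohort, exclude_treated)
    sigmas: dict[str, float] = {}
    for assay, vals in changes.items():
        if not vals:
            sigmas[assay] = float("nan")
            continue
        if len(vals) < min_obs:
            raise ValueError(
                f"only {len(vals)} usable {assay} changes (< {min_obs}); "
                "supply sigma manually")
        arr = np.asarray(vals)
        mad = np.median(np.abs(arr - np.median(arr)))
        sigma = MAD_SCALE * float(mad)
        if sigma < SIGMA_FLOOR:
            logger.warning("%s changes are degenerate; sigma floored at "
                           "%g", assay, SIGMA_FLOOR)
            sigma = SIGMA_FLOOR
        sigmas[assay] = sigma
    return sigmas["NGS"], sigmas["FISH"]


def fisher_combine(p_values: list[float]) -> float:
    """Fisher's combined probability test.

    X = -2 * sum(ln p) referred to chi-square with 2k degrees of
    freedom.  Zero p-values are clamped to the smallest positive float
    with a warning.
    """
    if not p_values:
        raise ValueError("need at least one p-value")
    ps = []
    for p in p_values:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value out of [0, 1]: {p}")
        if p == 0.0:
            logger.warning("p-value of 0 clamped to machine minimum")
            p = np.finfo(float).tiny
        ps.append(p)
    x = -2.0 * sum(math.log(p) for p in ps)
    return float(stats.chi2.sf(x, 2 * len(ps)))


def classify_sample_pair(lesion_zs: list[LesionZ], patient_id: str = "",
                         sample_pair: tuple[float, float] = (0.0, 0.0)
                         ) -> ReplacementCall:
    """Combine per-lesion evidence into P_increase and P_decrease.

    One-sided normal p-values of lesions with z > 0 are pooled with
    Fisher's method into P_increase; lesions with z < 0 likewise into
    P_decrease.  An empty side yields p = 1.
    """
    p_up = [lz.p_one_sided for lz in lesion_zs if lz.z > 0]
    p_down = [lz.p_one_sided for lz in lesion_zs if lz.z < 0]
    p_increase = fisher_combine(p_up) if p_up else 1.0
    p_decrease = fisher_combine(p_down) if p_down else 1.0
    return ReplacementCall(patient_id=patient_id, sample_pair=sample_pair,
                           p_increase=p_increase, p_decrease=p_decrease,
                           lesion_z=list(lesion_zs))


def lesion_zscores(prev: dict[str, tuple[str, float]],
                   curr: dict[str, tuple[str, float]],
                   sigma_seq: float, sigma_fish: float) -> list[LesionZ]:
    """Z-scores for lesions measured in both samples.

    ``prev`` and ``curr`` map lesion_id -> (assay, frequency).
    """
    out = []
    for lesion in sorted(prev.keys() & curr.keys()):
        assay, f1 = prev[lesion]
        _assay2, f2 = curr[lesion]
        sigma = sigma_fish if assay == "FISH" else sigma_seq
        z = zscore(f1, f2, sigma)
        p = float(stats.norm.sf(abs(z))) if z != 0 else 1.0
        out.append(LesionZ(lesion, assay, f1, f2, z, p))
    return out


def cohort_replacement_calls(cohort: CohortTable,
                             sigma_seq: float | None = None,
                             sigma_fish: float | None = None
                             ) -> list[ReplacementCall]:
    """Per-sample-pair P_increase / P_decrease for a whole cohort.

    Sigmas are fitted with :func:`fit_sigma` when not supplied.
    Raw frequencies are used exactly as recorded.
    """
    if sigma_seq is None or sigma_fish is None:
        fitted_seq, fitted_fish = fit_sigma(cohort)
        sigma_seq = sigma_seq if sigma_seq is not None else fitted_seq
        sigma_fish = sigma_fish if sigma_fish is not None else fitted_fish
    calls = []
    for pid in cohort.patients:
        times = cohort.sample_times(pid)
        for t1, t2 in zip(times, times[1:]):
            prev = {m.lesion_id: (m.assay, m.raw_value)
                    for m in cohort.patient_sample(pid, t1)}
            curr = {m.lesion_id: (m.assay, m.raw_value)
                    for m in cohort.patient_sample(pid, t2)}
            zs = lesion_zscores(prev, curr, sigma_seq, sigma_fish)
            calls.append(classify_sample_pair(zs, pid, (t1, t2)))
    return calls


def classify_patient(calls: list[ReplacementCall], fdr: float = 0.1
                     ) -> str:
    """Classify one patient as "linear" or "branching".

    Benjamini-Hochberg control at the given FDR is applied jointly to
    the pooled P_increase and P_decrease values across the patient's
    sample pairs; the patient is branching iff some pair is significant
    on both axes (a replacement event).  ``calls`` are mutated: their
    ``replacement`` flag is set.
    """
    if not calls:
        raise ValueError("need >= 1 sample pair")
    pooled = [c.p_increase for c in calls] + [c.p_decrease for c in calls]
    reject = _bh_reject(pooled, fdr)
    n = len(calls)
    branching = False
    for i, call in enumerate(calls):
        call.replacement = bool(reject[i] and reject[n + i])
        branching = branching or call.replacement
    return "branching" if branching else "linear"


def classify_cohort(cohort: CohortTable, fdr: float = 0.1,
                    sigma_seq: float | None = None,
                    sigma_fish: float | None = None
                    ) -> dict[str, str]:
    """Patient -> model label for a whole cohort.

    BH control is applied per cohort, both axes pooled across all
    patients' sample pairs.
    """
    calls = cohort_replacement_calls(cohort, sigma_seq, sigma_fish)
    pooled = [c.p_increase for c in calls] + [c.p_decrease for c in calls]
    reject = _bh_reject(pooled, fdr)
    n = len(calls)
    labels: dict[str, str] = {}
    for i, call in enumerate(calls):
        call.replacement = bool(reject[i] and reject[n + i])
        if call.replacement:
            labels[call.patient_id] = "branching"
        labels.setdefault(call.patient_id, "linear")
    return labels


def _bh_reject(p_values: list[float], fdr: float) -> list[bool]:
    """Benjamini-Hochberg step-up rejection mask."""
    m = len(p_values)
    order = np.argsort(p_values)
    reject = [False] * m
    cutoff = -1
    for rank, idx in enumerate(order, start=1):
        if p_values[idx] <= fdr * rank / m:
            cutoff = rank
    for rank, idx in enumerate(order, start=1):
        if rank <= cutoff:
            reject[idx] = True
    return reject
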