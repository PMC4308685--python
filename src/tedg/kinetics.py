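"""Clone-fitness kinetics: frequency slopes, growth rates and MMFS.

The standardized frequency change z between two samples (see
:mod:`tedg.fem`) divided by the elapsed time in years gives the
*mutation frequency slope* s (standard deviations per year).  The
*growth rate* of an observation is g = max(s, 0); a lesion's growth
rate is the mean g over all its observations.  A patient's *maximal
mutation frequency slope* (MMFS) is the maximum raw s over all lesions
and sample pairs — the expansion speed of the fittest clone.  Cohort
times are recorded in months and divided by 12 here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from tedg.cohort_io import CohortTable
from tedg.fem import fit_sigma, zscore

MONTHS_PER_YEAR = 12.0


@dataclass
class SlopeObservation:
    patient_id: str
    lesion_id: str
    assay: str
    t_prev: float  # months
    t_curr: float
    f_prev: float
    f_curr: float
    s: float  # per year

    @property
    def g(self) -> float:
        return max(self.s, 0.0)


@dataclass
class KineticsResult:
    observations: list[SlopeObservation] = field(default_factory=list)

    def for_patient(self, patient_id: str) -> list[SlopeObservation]:
        return [o for o in self.observations
                if o.patient_id == patient_id]

    def for_lesion(self, lesion_id: str) -> list[SlopeObservation]:
        return [o for o in self.observations if o.lesion_id == lesion_id]


def slopes(cohort: CohortTable, sigma_seq: float | None = None,
           sigma_fish: float | None = None) -> KineticsResult:
    """Per-observation mutation frequency slopes.

    For each patient, lesion and consecutive sample pair,
    s = z / Delta t, with z the standardized frequency change and
    Delta t in years.  Sigmas are fitted from the cohort when not
    supplied.
    """
    if sigma_seq is None or sigma_fish is None:
        fitted_seq, fitted_fish = fit_sigma(cohort)
        sigma_seq = sigma_seq if sigma_seq is not None else fitted_seq
        sigma_fish = sigma_fish if sigma_fish is not None else fitted_fish
    result = KineticsResult()
    for pid in cohort.patients:
        times = cohort.sample_times(pid)
        for t1, t2 in zip(times, times[1:]):
            if t2 == t1:
                raise ValueError(f"zero elapsed time for patient {pid}")
            dt_years = (t2 - t1) / MONTHS_PER_YEAR
            prev = {(m.lesion_id): m for m in cohort.patient_sample(pid, t1)}
            curr = {(m.lesion_id): m for m in cohort.patient_sample(pid, t2)}
            for lesion in sorted(prev.keys() & curr.keys()):
                m1, m2 = prev[lesion], curr[lesion]
                sigma = sigma_fish if m1.assay == "FISH" else sigma_seq
                z = zscore(m1.raw_value, m2.raw_value, sigma)
                result.observations.append(SlopeObservation(
                    patient_id=pid, lesion_id=lesion, assay=m1.assay,
                    t_prev=t1, t_curr=t2, f_prev=m1.raw_value,
                    f_curr=m2.raw_value, s=z / dt_years))
    return result


def growth_rates(result: KineticsResult,
                 subclonal_max: float | None = None) -> dict[str, float]:
    """Per-lesion mean growth rate (clipped slopes).

    g = max(s, 0) per observation, averaged over every observation of
    the lesion.  With ``subclonal_max`` set, observations whose earlier
    frequency exceeds it are dropped first — restricting the analysis
    to subclonal lesions (e.g. 0.20 removes clonal events).
    """
    by_lesion: dict[str, list[float]] = {}
    for o in result.observations:
        if subclonal_max is not None and o.f_prev > subclonal_max:
            continue
        by_lesion.setdefault(o.lesion_id, []).append(o.g)
    return {lesion: float(np.mean(gs))
            for lesion, gs in sorted(by_lesion.items())}


def mmfs(result: KineticsResult, patient_id: str) -> float:
    """Maximal mutation frequency slope of one patient.

    The maximum *unclipped* slope over all lesions and sample pairs; a
    patient whose clones all shrink gets a negative MMFS.  Raises on a
    patient with no slope observations.
    """
    obs = result.for_patient(patient_id)
    if not obs:
        raise ValueError(f"no slope observations for patient "
                         f"{patient_id!r}")
    return max(o.s for o in obs)


def compare_groups(values_a: list[float], values_b: list[float]
                   ) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum comparison of two value sets.

    Exact null distribution for small samples (both n <= 20, no ties),
    otherwise the normal approximation with tie correction.  Returns
    (U statistic of the first group, p-value); identical groups give
    p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.all(a == a[0]) and np.all(b == a[0]):
        return float(a.size * b.size / 2.0), 1.0
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (a.size <= 20 and b.size <= 20 and not has_ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
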