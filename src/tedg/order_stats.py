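"""Statistical tests for ordering networks and cross-sectional matrices.

Three tests:

* per-node binomial ordering test — under the null of no preferential
  timing, incoming and outgoing arrows of a lesion are equally likely,
  so the weighted in-degree is Binomial(d, 1/2); lesions with an excess
  of outgoing arrows are *early*, incoming *late*;
* global flow test — sum over nodes of (din - dout)^2 / dout referred
  to a chi-square with n - 1 degrees of freedom; a significant result
  means the network has directed flow rather than random accumulation;
* pairwise hypergeometric association — co-occurrence (upper tail) and
  mutual exclusivity (lower tail) of lesion pairs at diagnosis, with
  Bonferroni correction over tested pairs.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from tedg.cohort_io import CrossSectionalMatrix
from tedg.evograph import OrderGraph

logger = logging.getLogger(__name__)

#: Pseudocount applied to zero degrees (fold change) and to a zero
#: flow-test denominator; keeps sinks finite while letting them inflate
#: the statistic.
PSEUDOCOUNT = 0.5


@dataclass
class NodeOrderResult:
    lesion_id: str
    in_degree: int
    out_degree: int
    fold_change: float
    p_value: float
    label: str  # "early", "late" or "unlabeled"
    stars: str  # "", "*" (p<0.05) or "**" (p<0.01)


@dataclass
class AssociationResult:
    lesion_pair: tuple[str, str]
    p_co: float
    p_excl: float
    verdict: str  # "co-occur", "exclusive" or "none"
    corrected_alpha: float


def _binom_two_sided(k: int, d: int) -> float:
    """Two-sided binomial p at p=1/2 by doubling the smaller tail."""
    lower = stats.binom.cdf(k, d, 0.5)
    upper = stats.binom.sf(k - 1, d, 0.5)
    return float(min(1.0, 2.0 * min(lower, upper)))


def degree_order_test(isn: OrderGraph) -> list[NodeOrderResult]:
    """Binomial test of weighted in- vs out-degree per lesion.

    Degrees sum integer patient-count edge weights ("number of
    arrows").  Results are sorted by decreasing out/in fold change
    (pseudocount 0.5 on both sides when either degree is zero), so
    early lesions come first.  Isolated nodes are unlabeled with p = 1.
    """
    if isn.role not in ("ISN", "simplified"):
        raise ValueError(f"expected ISN or simplified graph, got "
                         f"{isn.role!r}")
    results = []
    for node in isn.nodes:
        din = int(round(isn.in_degree(node, weight="weight")))
        dout = int(round(isn.out_degree(node, weight="weight")))
        d = din + dout
        if d == 0:
            results.append(NodeOrderResult(node, 0, 0, 1.0, 1.0,
                                           "unlabeled", ""))
            continue
        p = _binom_two_sided(din, d)
        if din == 0 or dout == 0:
            fold = (dout + PSEUDOCOUNT) / (din + PSEUDOCOUNT)
        else:
            fold = dout / din
        label = "unlabeled"
        if p < 0.05:
            label = "early" if dout > din else "late"
        stars = "**" if p < 0.01 else ("*" if p < 0.05 else "")
        results.append(NodeOrderResult(node, din, dout, fold, p, label,
                                       stars))
    return sorted(results, key=lambda r: (-r.fold_change, r.lesion_id))


def flow_test(isn: OrderGraph) -> tuple[float, int, float]:
    """Global directed-flow test on the ISN.

    statistic = sum_i (din_i - dout_i)^2 / dout_i, with dout_i = 0
    replaced by the pseudocount 0.5 (pure sinks otherwise divide by
    zero); p-value from the upper tail of chi-square with n - 1 df.
    """
    n = isn.number_of_nodes()
    if n < 2:
        raise ValueError("flow test needs >= 2 nodes")
    stat = 0.0
    any_degree = False
    for node in isn.nodes:
        din = isn.in_degree(node, weight="weight")
        dout = isn.out_degree(node, weight="weight")
        if din or dout:
            any_degree = True
        denom = dout if dout > 0 else PSEUDOCOUNT
        stat += (din - dout) ** 2 / denom
    df = n - 1
    if not any_degree:
        logger.warning("flow test on an edgeless graph is undefined")
        return 0.0, df, 1.0
    return float(stat), df, float(stats.chi2.sf(stat, df))


def association_test(m: CrossSectionalMatrix, alpha: float = 0.05
                     ) -> list[AssociationResult]:
    """Pairwise hypergeometric co-occurrence / exclusivity test.

    For each lesion pair, patients missing either entry are dropped;
    with a of n patients carrying lesion A, b carrying B and k carrying
    both, the co-occurrence p is the hypergeometric upper tail
    P(X >= k) and the exclusivity p the lower tail P(X <= k).  p-values
    are Bonferroni-corrected by the number of pairs actually tested;
    verdicts are called at the corrected alpha.  Pairs where a lesion
    is present in none or all informative patients are reported with
    verdict "none" and are not counted in the correction.
    """
    lesions = m.lesion_ids
    if len(lesions) < 2:
        raise ValueError("association test needs >= 2 lesions")
    mat = m.matrix
    raw: list[tuple[tuple[str, str], float, float] | tuple] = []
    skipped: list[tuple[str, str]] = []
    for a, b in itertools.combinations(lesions, 2):
        sub = mat[[a, b]].dropna()
        n = len(sub)
        ca = int(sub[a].sum())
        cb = int(sub[b].sum())
        k = int(((sub[a] == 1) & (sub[b] == 1)).sum())
        if n == 0 or ca in (0, n) or cb in (0, n):
            logger.warning(
                "pair (%s, %s): degenerate marginals (n=%d, a=%d, b=%d); "
                "no test", a, b, n, ca, cb)
            skipped.append((a, b))
            continue
        p_co = float(stats.hypergeom.sf(k - 1, n, ca, cb))
        p_excl = float(stats.hypergeom.cdf(k, n, ca, cb))
        raw.append(((a, b), p_co, p_excl))
    n_tests = len(raw)
    corrected_alpha = alpha / n_tests if n_tests else alpha
    results = []
    for pair, p_co, p_excl in raw:
        if p_co <= corrected_alpha:
            verdict = "co-occur"
        elif p_excl <= corrected_alpha:
            verdict = "exclusive"
        else:
            verdict = "none"
        results.append(AssociationResult(pair, p_co, p_excl, verdict,
                                         corrected_alpha))
    for pair in skipped:
        results.append(AssociationResult(pair, float("nan"), float("nan"),
                                         "none", corrected_alpha))
    return results
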