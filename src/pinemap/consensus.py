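"""Consensus-map construction across two pedigrees.

Recombination-rate homogeneity between pedigrees is tested per marker
pair with a likelihood-ratio statistic: twice the gap between the sum
of the separately maximized log-likelihoods and the log-likelihood of a
single pooled recombination fraction fitted to all available meioses,
referred to the chi-square(1) upper tail.  Pairs passing (and, following
the study design, all pairs under the homogeneity assumption) are pooled
and the merged table is grouped and ordered with the linkage machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import minimize_scalar

from .formats import GenotypeMatrix, LinkageMapModel
from .linkage import (
    DEFAULT_GOF_JUMP,
    DEFAULT_LOD_THRESHOLD,
    LN10,
    InsufficientDataError,
    TwoPointResult,
    TwoPointTable,
    build_map,
    estimate_two_point,
)


class MergeError(ValueError):
    pass


@dataclass
class HeterogeneityResult:
    marker_a: str
    marker_b: str
    r1: float
    r2: float
    loglik1: float
    loglik2: float
    pooled_r: float
    statistic: float
    p_value: float
    significant: bool


def _pooled_fit(logliks) -> tuple[float, float]:
    """Maximize the summed log-likelihood over r in [0, 0.5]."""

    def neg(r):
        return -sum(fn(r) for fn in logliks)

    res = minimize_scalar(neg, bounds=(0.0, 0.5), method="bounded",
                          options={"xatol": 1e-7})
    return float(np.clip(res.x, 0.0, 0.5)), -float(res.fun)


def heterogeneity_test(
    res1: TwoPointResult, res2: TwoPointResult, alpha: float = 0.01
) -> HeterogeneityResult:
    """Likelihood-ratio homogeneity test for one marker pair.

    Both results must be informative (carry likelihood functions).
    """
    if res1.loglik is None or res2.loglik is None:
        raise InsufficientDataError(
            f"pair {res1.marker_a} x {res1.marker_b} not informative in both "
            "populations"
        )
    ll1 = res1.loglik(res1.r_hat)
    ll2 = res2.loglik(res2.r_hat)
    pooled_r, ll_pooled = _pooled_fit([res1.loglik, res2.loglik])
    stat = max(0.0, 2.0 * (ll1 + ll2 - ll_pooled))
    p = float(stats.chi2.sf(stat, df=1))
    return HeterogeneityResult(
        marker_a=res1.marker_a,
        marker_b=res1.marker_b,
        r1=res1.r_hat,
        r2=res2.r_hat,
        loglik1=ll1,
        loglik2=ll2,
        pooled_r=pooled_r,
        statistic=stat,
        p_value=p,
        significant=bool(p < alpha),
    )


def heterogeneity_test_matrices(
    m1: GenotypeMatrix,
    m2: GenotypeMatrix,
    marker_a: str,
    marker_b: str,
    alpha: float = 0.01,
) -> HeterogeneityResult:
    res1 = estimate_two_point(m1, marker_a, marker_b)
    res2 = estimate_two_point(m2, marker_a, marker_b)
    return heterogeneity_test(res1, res2, alpha)


@dataclass
class ConsensusReport:
    model: LinkageMapModel
    table: TwoPointTable
    n_markers: int
    n_shared: int
    heterogeneity: list[HeterogeneityResult]


def pooled_two_point_table(
    m1: GenotypeMatrix, m2: GenotypeMatrix, markers=None
) -> tuple[TwoPointTable, list[str]]:
    """Pairwise pooled r/LOD over the union of both pedigrees' markers.

    For a pair informative in both populations the pooled r̂ maximizes
    the joint likelihood over all meioses; pairs informative in one
    population keep that population's estimate.  Returns the table and
    the list of shared (both-population) markers.
    """
    ids1, ids2 = set(m1.marker_ids), set(m2.marker_ids)
    if markers is None:
        markers = sorted(ids1 | ids2)
    shared = sorted(ids1 & ids2 & set(markers))
    nm = len(markers)
    r = np.full((nm, nm), 0.5)
    lod = np.zeros((nm, nm))
    for i in range(nm):
        for j in range(i + 1, nm):
            a, b = markers[i], markers[j]
            fns = []
            single = None
            for m in (m1, m2):
                if a in set(m.marker_ids) and b in set(m.marker_ids):
                    try:
                        res = estimate_two_point(m, a, b)
                    except InsufficientDataError:
                        continue
                    if res.loglik is not None:
                        fns.append(res.loglik)
                        single = res
            if not fns:
                continue
            if len(fns) == 1:
                r[i, j] = r[j, i] = single.r_hat
                lod[i, j] = lod[j, i] = single.lod
            else:
                pooled_r, ll = _pooled_fit(fns)
                ll_null = sum(fn(0.5) for fn in fns)
                r[i, j] = r[j, i] = pooled_r
                lod[i, j] = lod[j, i] = max(0.0, (ll - ll_null) / LN10)
    np.fill_diagonal(r, 0.0)
    return TwoPointTable(list(markers), r, lod), shared


def build_consensus(
    m1: GenotypeMatrix,
    m2: GenotypeMatrix,
    lod_threshold: float = DEFAULT_LOD_THRESHOLD,
    gof_jump_threshold: float = DEFAULT_GOF_JUMP,
    alpha: float = 0.01,
    heterogeneity_pairs: int | None = None,
) -> ConsensusReport:
    """Merge two pedigrees into a consensus map.

    Homogeneity is tested on every shared-marker pair informative in
    both populations (capped at ``heterogeneity_pairs`` if given); the
    merged pooled table is then grouped and ordered.  Groups lacking a
    shared anchor simply pass through from the population that carries
    them — with sparse anchors the consensus can therefore hold more
    groups than chromosomes.
    """
    if not set(m1.marker_ids) & set(m2.marker_ids):
        raise MergeError("no shared markers between the two pedigrees")
    table, shared = pooled_two_point_table(m1, m2)
    het: list[HeterogeneityResult] = []
    pairs = [(a, b) for k, a in enumerate(shared) for b in shared[k + 1 :]]
    if heterogeneity_pairs is not None:
        pairs = pairs[:heterogeneity_pairs]
    for a, b in pairs:
        try:
            het.append(heterogeneity_test_matrices(m1, m2, a, b, alpha))
        except InsufficientDataError:
            continue
    model = build_map(table, lod_threshold, gof_jump_threshold, label_prefix="CG")
    return ConsensusReport(
        model=model,
        table=table,
        n_markers=model.n_markers,
        n_shared=len(shared),
        heterogeneity=het,
    )
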