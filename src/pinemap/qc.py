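"""Genotyping-assay QC: SNP classification, association tests, segregation
distortion and the within-contig genotyping-error estimator.

The error estimator exploits physically linked SNPs: markers on the same
amplicon/contig are a few hundred bp apart, so the probability of a true
crossover between them in one meiosis is essentially zero.  Any apparent
recombinant between adjacent within-contig markers is therefore a
genotyping error; the error rate is (implied recombination events) /
(scorable offspring x adjacent within-contig pairs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .formats import FormatError, GenotypeMatrix, MarkerMeta, legal_calls

DEFAULT_CALL_RATE_FLOOR = 0.8


@dataclass
class QcSummary:
    """Per-assay bookkeeping of success and conversion."""

    n_total: int
    n_failed: int
    n_monomorphic: int
    n_polymorphic: int
    per_sample_success: dict[str, float]
    per_snp_status: dict[str, str]
    counts_by_source: dict[str, dict[str, int]]

    @property
    def success_rate(self) -> float:
        return (self.n_total - self.n_failed) / self.n_total if self.n_total else 0.0

    @property
    def conversion_rate(self) -> float:
        return self.n_polymorphic / self.n_total if self.n_total else 0.0


def classify_snps(
    matrix: GenotypeMatrix, call_rate_floor: float = DEFAULT_CALL_RATE_FLOOR
) -> dict[str, str]:
    """Status per SNP: failed (call rate below floor), monomorphic
    (one genotype class) or polymorphic (>=2 classes)."""
    status = {}
    miss = matrix.missing_symbol
    for mid, row in zip(matrix.marker_ids, matrix.calls):
        called = [c for c in row if c != miss]
        if len(called) < call_rate_floor * len(row):
            status[mid] = "failed"
        elif len(set(called)) <= 1:
            status[mid] = "monomorphic"
        else:
            status[mid] = "polymorphic"
    return status


def qc_summary(
    matrix: GenotypeMatrix,
    meta: list[MarkerMeta] | None = None,
    call_rate_floor: float = DEFAULT_CALL_RATE_FLOOR,
    n_assay_total: int | None = None,
) -> QcSummary:
    """Assemble the QC table.

    ``n_assay_total`` lets the conversion rate be reported against the
    full assay content when the matrix only holds the attempted SNPs.
    """
    status = classify_snps(matrix, call_rate_floor)
    miss = matrix.missing_symbol
    n_total = n_assay_total or matrix.n_markers
    counts = {"failed": 0, "monomorphic": 0, "polymorphic": 0}
    for s in status.values():
        counts[s] += 1
    counts["failed"] += n_total - matrix.n_markers  # absent = failed upstream

    per_sample = {}
    for j, ind in enumerate(matrix.offspring_ids):
        called = sum(1 for row in matrix.calls if row[j] != miss)
        per_sample[ind] = called / matrix.n_markers if matrix.n_markers else 0.0

    by_source: dict[str, dict[str, int]] = {}
    if meta is not None:
        tag_of = {m.marker_id: m.source_tag for m in meta}
        for mid, s in status.items():
            tag = tag_of.get(mid, "unknown")
            by_source.setdefault(tag, {"failed": 0, "monomorphic": 0, "polymorphic": 0})
            by_source[tag][s] += 1

    return QcSummary(
        n_total=n_total,
        n_failed=counts["failed"],
        n_monomorphic=counts["monomorphic"],
        n_polymorphic=counts["polymorphic"],
        per_sample_success=per_sample,
        per_snp_status=status,
        counts_by_source=by_source,
    )


def chi2_2x2_yates(table) -> tuple[float, float]:
    """Continuity-corrected (Yates) chi-square test on a 2x2 table.

    Returns (statistic, p) with p from the chi-square(1) upper tail.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0):
        raise ValueError("negative counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero margin: test undefined")
    stat, p, _, _ = stats.chi2_contingency(t, correction=True)
    return float(stat), float(p)


EXPECTED_RATIOS = {
    "1:1": np.array([1.0, 1.0]),
    "1:2:1": np.array([1.0, 2.0, 1.0]),
}


def segregation_distortion(
    counts, expected_ratio: str, alpha: float = 0.01
) -> tuple[float, float, bool]:
    """Pearson chi-square of observed class counts against a Mendelian
    ratio; returns (statistic, p, distorted-at-alpha)."""
    if expected_ratio not in EXPECTED_RATIOS:
        raise ValueError(f"unknown ratio {expected_ratio!r}")
    obs = np.asarray(counts, dtype=float)
    ratio = EXPECTED_RATIOS[expected_ratio]
    if obs.shape != ratio.shape:
        raise ValueError(
            f"ratio {expected_ratio} expects {len(ratio)} classes, got {len(obs)}"
        )
    n = obs.sum()
    if n <= 0:
        raise ValueError("no observations")
    exp = ratio / ratio.sum() * n
    stat, p = stats.chisquare(obs, exp)
    return float(stat), float(p), bool(p < alpha)


def marker_class_counts(matrix: GenotypeMatrix, marker_id: str):
    """Observed genotype-class counts of a marker, in legal-call order,
    with its Mendelian ratio label."""
    code = matrix.seg_code(marker_id)
    legal = legal_calls(matrix.pedigree_type, code)
    row = matrix.row(marker_id)
    counts = [row.count(c) for c in legal]
    ratio = "1:1" if len(legal) == 2 else "1:2:1"
    return counts, ratio


# ---------------------------------------------------------------------------
# within-contig genotyping-error estimator
# ---------------------------------------------------------------------------

def _phase_allele(call: str, code: str, pedigree_type: str):
    """Project one call onto a single 0/1 phase-trackable allele.

    Testcross calls reflect one meiosis directly; homozygous intercross
    and F2 calls carry the same allele on both gametes, so they project
    to that allele.  Double heterozygotes (``hk``, ``h``) are not
    phase-resolvable and return None.
    """
    if pedigree_type == "F2":
        return {"a": 0, "h": None, "b": 1}[call]
    if code == "lmxll":
        return {"ll": 0, "lm": 1}[call]
    if code == "nnxnp":
        return {"nn": 0, "np": 1}[call]
    if code == "hkxhk":
        return {"hh": 0, "hk": None, "kk": 1}[call]
    raise FormatError(f"unknown segregation code {code!r}")


def _informative_parent(code: str) -> str:
    return {"lmxll": "female", "nnxnp": "male", "hkxhk": "both", "codom": "both"}[code]


@dataclass
class ErrorRateResult:
    events: int
    data_points: int

    @property
    def rate(self) -> float:
        if self.data_points == 0:
            return float("nan")
        return self.events / self.data_points

    @property
    def rate_percent_1dp(self) -> float:
        """Rate in percent, rounded to one decimal (reporting convention)."""
        return round(100.0 * self.rate, 1)


def error_rate_from_counts(events: int, data_points: int) -> ErrorRateResult:
    if data_points < 0 or events < 0 or events > data_points:
        raise ValueError("need 0 <= events <= data_points")
    return ErrorRateResult(events=events, data_points=data_points)


def estimate_error_rate(
    matrix: GenotypeMatrix, meta: list[MarkerMeta]
) -> ErrorRateResult:
    """Estimate the genotyping-error rate from within-contig marker pairs.

    For every contig carrying >=2 polymorphic markers, adjacent marker
    pairs are scored across offspring.  A data point is one offspring x
    pair where both calls are non-missing and phase-resolvable (double
    heterozygotes are not); since true within-contig recombination is
    null, the pair's linkage phase is taken as the one minimising implied
    recombinants, and each implied recombinant gamete counts as one
    event.  CP pairs informative in different parents contribute no data
    points.
    """
    contig_of = {m.marker_id: m.contig_id for m in meta}
    status = classify_snps(matrix, call_rate_floor=0.0)
    by_contig: dict[str, list[str]] = {}
    for mid in matrix.marker_ids:
        if status.get(mid) != "polymorphic":
            continue
        c = contig_of.get(mid)
        if c is not None:
            by_contig.setdefault(c, []).append(mid)

    multi = {c: ms for c, ms in by_contig.items() if len(ms) >= 2}
    if not multi:
        import warnings

        warnings.warn("no contig with >=2 polymorphic markers; rate undefined")
        return ErrorRateResult(events=0, data_points=0)

    miss = matrix.missing_symbol
    events = 0
    points = 0
    for _, mids in sorted(multi.items()):
        for a, b in zip(mids, mids[1:]):
            code_a, code_b = matrix.seg_code(a), matrix.seg_code(b)
            pa, pb = _informative_parent(code_a), _informative_parent(code_b)
            if pa != "both" and pb != "both" and pa != pb:
                continue  # no shared informative meiosis
            diffs = []
            for ca, cb in zip(matrix.row(a), matrix.row(b)):
                if ca == miss or cb == miss:
                    continue
                xa = _phase_allele(ca, code_a, matrix.pedigree_type)
                xb = _phase_allele(cb, code_b, matrix.pedigree_type)
                if xa is None or xb is None:
                    continue
                diffs.append(xa != xb)
            if not diffs:
                continue
            n_diff = sum(diffs)
            points += len(diffs)
            # phase = the orientation implying fewer recombinants
            events += min(n_diff, len(diffs) - n_diff)
    return ErrorRateResult(events=events, data_points=points)
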