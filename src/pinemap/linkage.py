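"""Two-point linkage estimation, LOD grouping, Kosambi distances and
regression-style marker ordering for outbred (CP) and selfed (F2) pedigrees.

Estimation follows the two-way pseudo-testcross logic: markers
heterozygous in a single parent (lmxll via the seed parent, nnxnp via
the pollen parent) segregate 1:1 and give a closed-form recombination
fraction from recombinant counts in that parent's meioses; markers
heterozygous in both parents (hkxhk) and F2 codominant markers segregate
1:2:1 and are handled by an EM algorithm over the 9-class joint table,
whose double-heterozygote cell mixes parental and recombinant gamete
pairs.  Linkage phase is not known in advance in a CP cross: every phase
configuration is evaluated and the maximum-likelihood one kept (ties
broken toward coupling).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .formats import GenotypeMatrix

LN10 = math.log(10.0)
EM_TOL = 1e-8
EM_MAX_ITER = 200
DEFAULT_LOD_THRESHOLD = 3.0
DEFAULT_GOF_JUMP = 5.0
_TINY = 1e-300


class InsufficientDataError(ValueError):
    pass


# ---------------------------------------------------------------------------
# mapping functions
# ---------------------------------------------------------------------------

def kosambi(r: float) -> float:
    """Kosambi map distance in cM: d = 25 ln((1+2r)/(1-2r)); r in [0, 0.5)."""
    r = float(r)
    if not 0.0 <= r < 0.5:
        raise ValueError(f"recombination fraction {r} outside [0, 0.5)")
    return 25.0 * math.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))


def kosambi_inverse(d_cM: float) -> float:
    """Inverse Kosambi: r = tanh(d/50)/2."""
    if d_cM < 0:
        raise ValueError(f"negative distance {d_cM}")
    return 0.5 * math.tanh(d_cM / 50.0)


def haldane(r: float) -> float:
    """Haldane map distance in cM (no interference): d = -50 ln(1-2r)."""
    if not 0.0 <= r < 0.5:
        raise ValueError(f"recombination fraction {r} outside [0, 0.5)")
    return -50.0 * math.log(1.0 - 2.0 * r)


# ---------------------------------------------------------------------------
# two-point estimation
# ---------------------------------------------------------------------------

@dataclass
class TwoPointResult:
    marker_a: str
    marker_b: str
    r_hat: float
    lod: float
    phase: str  # "coupling", "repulsion", phase-pair like "cr", or "uninformative"
    informative_meioses: int
    loglik: object = None  # callable r -> log-likelihood at the ML phase


def _call_combos(call: str, code: str):
    """CP call -> possible (female allele, male allele); None = parent
    homozygous at this marker (uninformative meiosis)."""
    if code == "lmxll":
        return {"ll": [(0, None)], "lm": [(1, None)]}[call]
    if code == "nnxnp":
        return {"nn": [(None, 0)], "np": [(None, 1)]}[call]
    if code == "hkxhk":
        return {"hh": [(0, 0)], "kk": [(1, 1)], "hk": [(0, 1), (1, 0)]}[call]
    raise ValueError(f"unknown segregation code {code!r}")


def _f2_combos(call: str):
    """F2 call -> possible (gamete1 allele, gamete2 allele)."""
    return {"a": [(0, 0)], "b": [(1, 1)], "h": [(0, 1), (1, 0)]}[call]


def _class_structures_cp(code_a: str, code_b: str, phases: tuple[int, ...]):
    """Per joint-call class, the (const, n_recombinant) expansion.

    ``phases`` holds one bit per doubly-informative parent (0 coupling,
    1 repulsion) in (female, male) order.  Returns (classes, K) where
    classes maps (call_a, call_b) -> list of (const, b); class
    probability is sum const * ((1-r)/2)^(K-b) * (r/2)^b.
    """
    inf_f = [code_a in ("lmxll", "hkxhk"), code_b in ("lmxll", "hkxhk")]
    inf_m = [code_a in ("nnxnp", "hkxhk"), code_b in ("nnxnp", "hkxhk")]
    both_f = all(inf_f)
    both_m = all(inf_m)
    K = int(both_f) + int(both_m)
    phase_iter = iter(phases)
    phase_f = next(phase_iter) if both_f else 0
    phase_m = next(phase_iter) if both_m else 0

    calls_a = {"lmxll": ("ll", "lm"), "nnxnp": ("nn", "np"), "hkxhk": ("hh", "hk", "kk")}
    classes: dict[tuple[str, str], list[tuple[float, int]]] = {}
    for ca in calls_a[code_a]:
        for cb in calls_a[code_b]:
            expansion = []
            for fa, ma in _call_combos(ca, code_a):
                for fb, mb in _call_combos(cb, code_b):
                    const = 1.0
                    b = 0
                    # female meiosis
                    if both_f:
                        rec = (fa != fb) ^ bool(phase_f)
                        b += int(rec)
                    elif inf_f[0] or inf_f[1]:
                        const *= 0.5
                    # male meiosis
                    if both_m:
                        rec = (ma != mb) ^ bool(phase_m)
                        b += int(rec)
                    elif inf_m[0] or inf_m[1]:
                        const *= 0.5
                    expansion.append((const, b))
            classes[(ca, cb)] = expansion
    return classes, K


def _class_structures_f2(phase: int):
    """F2 9-class expansion under a single F1 phase; K = 2 meioses."""
    classes: dict[tuple[str, str], list[tuple[float, int]]] = {}
    for ca in "ahb":
        for cb in "ahb":
            expansion = []
            for g1a, g2a in _f2_combos(ca):
                for g1b, g2b in _f2_combos(cb):
                    b = int((g1a != g1b) ^ bool(phase)) + int((g2a != g2b) ^ bool(phase))
                    expansion.append((1.0, b))
            classes[(ca, cb)] = expansion
    return classes, 2


def _em_fit(class_counts: dict, classes: dict, K: int):
    """EM for r over a (const, b)-expanded class table.

    Returns (r_hat, loglik_at_r_hat, loglik_fn).
    """
    items = [(n, classes[c]) for c, n in class_counts.items() if n > 0]
    n_obs = sum(n for n, _ in items)

    def loglik(r: float) -> float:
        r = min(max(r, 0.0), 0.5)
        total = 0.0
        for n, expansion in items:
            p = sum(
                const * ((1 - r) / 2.0) ** (K - b) * (r / 2.0) ** b
                for const, b in expansion
            )
            total += n * math.log(max(p, _TINY))
        return total

    if K == 0 or n_obs == 0:
        return 0.5, 0.0, loglik

    r = 0.25
    ll_prev = loglik(r)
    for _ in range(EM_MAX_ITER):
        num = 0.0
        for n, expansion in items:
            ws = [
                const * ((1 - r) / 2.0) ** (K - b) * (r / 2.0) ** b
                for const, b in expansion
            ]
            tot = sum(ws)
            if tot <= 0:
                continue
            e_rec = sum(w * b for w, (_, b) in zip(ws, expansion)) / tot
            num += n * e_rec
        r = min(max(num / (n_obs * K), 0.0), 0.5)
        ll = loglik(r)
        if abs(ll - ll_prev) <= EM_TOL * (abs(ll_prev) + 1.0):
            ll_prev = ll
            break
        ll_prev = ll
    return r, ll_prev, loglik


def _informative_parents(code_a: str, code_b: str) -> int:
    f = code_a in ("lmxll", "hkxhk") and code_b in ("lmxll", "hkxhk")
    m = code_a in ("nnxnp", "hkxhk") and code_b in ("nnxnp", "hkxhk")
    return int(f) + int(m)


def estimate_two_point(
    matrix: GenotypeMatrix, marker_a: str, marker_b: str
) -> TwoPointResult:
    """Maximum-likelihood two-point recombination fraction and LOD.

    Fully informative same-parent testcross pairs use the closed-form
    recombinant-count ratio; pairs involving 1:2:1 markers and F2 pairs
    use EM over the joint class table; all phase configurations are
    evaluated and the best kept.  Pairs informative in different parents
    only (lmxll vs nnxnp) are uninformative: r = 0.5, LOD = 0.
    """
    miss = matrix.missing_symbol
    row_a, row_b = matrix.row(marker_a), matrix.row(marker_b)
    pairs = [(a, b) for a, b in zip(row_a, row_b) if a != miss and b != miss]
    if not pairs:
        raise InsufficientDataError(
            f"no shared non-missing offspring for {marker_a} x {marker_b}"
        )
    if matrix.pedigree_type == "F2":
        counts: dict[tuple[str, str], int] = {}
        for p in pairs:
            counts[p] = counts.get(p, 0) + 1
        best = None
        for phase in (0, 1):
            classes, K = _class_structures_f2(phase)
            r, ll, fn = _em_fit(counts, classes, K)
            if best is None or ll > best[1] + 1e-12:
                best = (r, ll, fn, "coupling" if phase == 0 else "repulsion")
        r, ll, fn, phase_label = best
        lod = max(0.0, (ll - fn(0.5)) / LN10)
        return TwoPointResult(
            marker_a, marker_b, r, lod, phase_label, 2 * len(pairs), loglik=fn
        )

    code_a, code_b = matrix.seg_code(marker_a), matrix.seg_code(marker_b)
    K = _informative_parents(code_a, code_b)
    if K == 0:
        return TwoPointResult(
            marker_a, marker_b, 0.5, 0.0, "uninformative", 0, loglik=None
        )
    counts = {}
    for p in pairs:
        counts[p] = counts.get(p, 0) + 1
    labels = {0: "coupling", 1: "repulsion"}
    best = None
    for phases in itertools.product((0, 1), repeat=K):
        classes, K2 = _class_structures_cp(code_a, code_b, phases)
        r, ll, fn = _em_fit(counts, classes, K2)
        if best is None or ll > best[1] + 1e-12:
            label = "/".join(labels[p] for p in phases)
            best = (r, ll, fn, label)
    r, ll, fn, phase_label = best
    lod = max(0.0, (ll - fn(0.5)) / LN10)
    return TwoPointResult(
        marker_a, marker_b, r, lod, phase_label, K * len(pairs), loglik=fn
    )


# ---------------------------------------------------------------------------
# all-pairs tables (vectorized fast paths)
# ---------------------------------------------------------------------------

@dataclass
class TwoPointTable:
    """Symmetric pairwise r/LOD matrices over a marker set.

    ``n`` holds the informative-meiosis count per pair (used as the
    sample size behind each estimate when weighting map regressions).
    """

    marker_ids: list[str]
    r: np.ndarray
    lod: np.ndarray
    n: np.ndarray | None = None
    index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.index:
            self.index = {m: i for i, m in enumerate(self.marker_ids)}
        if self.n is None:
            self.n = np.full_like(self.lod, 100.0)

    def pair(self, a: str, b: str) -> tuple[float, float]:
        i, j = self.index[a], self.index[b]
        return float(self.r[i, j]), float(self.lod[i, j])


def _testcross_matrices(enc: np.ndarray, mask: np.ndarray):
    """Closed-form r/LOD for all pairs of 0/1-encoded single-meiosis
    markers.  ``enc`` is markers x offspring in {0,1}; ``mask`` marks
    non-missing calls."""
    E = np.where(mask, enc, 0).astype(float)
    M = mask.astype(float)
    shared = M @ M.T
    agree = E @ E.T + (M - E) @ (M - E).T
    mism = shared - agree
    R = np.minimum(mism, shared - mism)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(shared > 0, R / np.maximum(shared, 1), 0.5)
        term_r = np.where(R > 0, R * np.log10(np.maximum(r, _TINY)), 0.0)
        term_p = np.where(
            shared - R > 0,
            (shared - R) * np.log10(np.maximum(1 - r, _TINY)),
            0.0,
        )
        lod = shared * np.log10(2.0) + term_r + term_p
    lod = np.where(shared > 0, np.maximum(lod, 0.0), 0.0)
    return r, lod, shared


_F2_ENC = {"a": 0, "h": 1, "b": 2, "-": -1}


def _f2_pair_counts(enc: np.ndarray):
    """9-class counts for all marker pairs: returns C[u,v] matrices."""
    ind = [(enc == u).astype(float) for u in range(3)]
    return [[ind[u] @ ind[v].T for v in range(3)] for u in range(3)]


def _f2_em_vectorized(C, n_iter=EM_MAX_ITER):
    """Vectorized EM over all pairs for the F2 coupling table.

    C is the 3x3 list of pairwise count matrices.  Returns (r, loglik).
    """
    n = sum(C[u][v] for u in range(3) for v in range(3))
    # expected recombinant gametes per class (class 1,1 is r-dependent)
    e_fixed = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
    r = np.full(n.shape, 0.25)
    for _ in range(n_iter):
        p, q = 1.0 - r, r
        e11 = 2.0 * q**2 / np.maximum(p**2 + q**2, _TINY)
        num = sum(
            C[u][v] * (e11 if (u == 1 and v == 1) else e_fixed[u, v])
            for u in range(3)
            for v in range(3)
        )
        r_new = np.clip(num / np.maximum(2.0 * n, 1.0), 0.0, 0.5)
        if np.max(np.abs(r_new - r)) < 1e-10:
            r = r_new
            break
        r = r_new

    def loglik_at(rr):
        p, q = 1.0 - rr, rr
        probs = {
            (0, 0): p**2 / 4,
            (0, 1): p * q / 2,
            (0, 2): q**2 / 4,
            (1, 0): p * q / 2,
            (1, 1): (p**2 + q**2) / 2,
            (1, 2): p * q / 2,
            (2, 0): q**2 / 4,
            (2, 1): p * q / 2,
            (2, 2): p**2 / 4,
        }
        return sum(
            C[u][v] * np.log(np.maximum(probs[(u, v)], _TINY))
            for u in range(3)
            for v in range(3)
        )

    ll = loglik_at(r)
    ll_null = loglik_at(np.full_like(r, 0.5))
    return r, ll, ll_null, n


def two_point_table(matrix: GenotypeMatrix, markers=None) -> TwoPointTable:
    """All-pairs two-point table.

    F2 matrices and CP testcross pairs take vectorized paths; CP pairs
    involving hkxhk markers fall back to the per-pair EM engine.
    """
    if markers is None:
        markers = list(matrix.marker_ids)
    sub = matrix.subset(markers)
    nm = len(markers)
    r = np.full((nm, nm), 0.5)
    lod = np.zeros((nm, nm))

    if matrix.pedigree_type == "F2":
        enc = np.array(
            [[_F2_ENC[c] for c in row] for row in sub.calls], dtype=np.int8
        )
        C_coup = _f2_pair_counts(enc)
        # repulsion = relabel second marker (swap a<->b): permute columns
        flip = {0: 2, 1: 1, 2: 0}
        C_rep = [[C_coup[u][flip[v]] for v in range(3)] for u in range(3)]
        r_c, ll_c, ll0, n_shared = _f2_em_vectorized(C_coup)
        r_r, ll_r, ll0_r, _ = _f2_em_vectorized(C_rep)
        take_rep = ll_r > ll_c + 1e-12
        r = np.where(take_rep, r_r, r_c)
        ll = np.where(take_rep, ll_r, ll_c)
        lod = np.maximum((ll - ll0) / LN10, 0.0)
        np.fill_diagonal(r, 0.0)
        np.fill_diagonal(lod, 0.0)
        return TwoPointTable(markers, r, lod, n=2.0 * n_shared)

    # CP: vectorized closed form per testcross class
    codes = sub.seg_codes
    n_inf = np.zeros((nm, nm))
    enc_rows = np.zeros((nm, sub.n_offspring), dtype=np.int8)
    mask = np.zeros((nm, sub.n_offspring), dtype=bool)
    one_call = {"lmxll": "lm", "nnxnp": "np"}
    for i, (code, row) in enumerate(zip(codes, sub.calls)):
        if code in one_call:
            for j, c in enumerate(row):
                if c != "--":
                    mask[i, j] = True
                    enc_rows[i, j] = 1 if c == one_call[code] else 0
    for code in ("lmxll", "nnxnp"):
        idx = [i for i, c in enumerate(codes) if c == code]
        if len(idx) < 2:
            continue
        rr, ll, shared = _testcross_matrices(enc_rows[idx], mask[idx])
        ii = np.array(idx)
        r[np.ix_(ii, ii)] = rr
        lod[np.ix_(ii, ii)] = ll
        n_inf[np.ix_(ii, ii)] = shared

    hk_idx = [i for i, c in enumerate(codes) if c == "hkxhk"]
    for i in hk_idx:
        for j in range(nm):
            if j == i or (j in hk_idx and j < i):
                continue
            try:
                res = estimate_two_point(sub, markers[i], markers[j])
            except InsufficientDataError:
                continue
            r[i, j] = r[j, i] = res.r_hat
            lod[i, j] = lod[j, i] = res.lod
            n_inf[i, j] = n_inf[j, i] = res.informative_meioses
    np.fill_diagonal(r, 0.0)
    np.fill_diagonal(lod, 0.0)
    return TwoPointTable(markers, r, lod, n=n_inf)


# ---------------------------------------------------------------------------
# grouping
# ---------------------------------------------------------------------------

def group_markers(
    table: TwoPointTable, lod_threshold: float = DEFAULT_LOD_THRESHOLD
) -> list[list[str]]:
    """Single-linkage partition: markers joined whenever pairwise
    LOD >= threshold; transitive closure via graph components."""
    g = nx.Graph()
    g.add_nodes_from(table.marker_ids)
    nm = len(table.marker_ids)
    ii, jj = np.nonzero(np.triu(table.lod >= lod_threshold, k=1))
    for i, j in zip(ii, jj):
        g.add_edge(table.marker_ids[i], table.marker_ids[j])
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return comps


def split_pseudo_testcross(matrix: GenotypeMatrix):
    """CP marker sets per parental map: (female, male, shared hkxhk)."""
    if matrix.pedigree_type != "CP":
        raise ValueError("split_pseudo_testcross needs a CP matrix")
    female, male, shared = [], [], []
    for mid, code in zip(matrix.marker_ids, matrix.seg_codes):
        if code == "lmxll":
            female.append(mid)
        elif code == "nnxnp":
            male.append(mid)
        elif code == "hkxhk":
            female.append(mid)
            male.append(mid)
            shared.append(mid)
        else:
            raise ValueError(f"marker {mid}: unknown CP code {code!r}")
    return female, male, shared


# ---------------------------------------------------------------------------
# ordering (regression-style, framework/accessory)
# ---------------------------------------------------------------------------

@dataclass
class OrderingResult:
    order: list[str]
    positions: list[float]  # cumulative Kosambi cM, first = 0
    gof_trace: list[float]  # normalized goodness-of-fit after each insertion
    accessory: list[tuple[str, str, float, float]]  # (marker, anchor, rf, lod)


def _ls_positions(order_idx, D, W):
    """LOD^2-weighted least-squares positions for a marker order.

    Minimizes sum w_ij (x_j - x_i - d_ij)^2 with x_0 = 0; returns
    (positions, normalized gof = weighted mean squared residual, cM^2).
    """
    order = np.asarray(order_idx)
    k = len(order)
    aa, bb = np.triu_indices(k, k=1)
    w = W[order[aa], order[bb]]
    keep = w > 0
    if not np.any(keep):
        return np.zeros(k), 0.0
    aa, bb, w = aa[keep], bb[keep], w[keep]
    y = D[order[aa], order[bb]]
    P = len(w)
    A = np.zeros((P, k - 1))
    rows = np.arange(P)
    A[rows, bb - 1] = 1.0
    inner = aa > 0
    A[rows[inner], aa[inner] - 1] = -1.0
    sw = np.sqrt(w)
    x, *_ = np.linalg.lstsq(A * sw[:, None], y * sw, rcond=None)
    pos = np.concatenate([[0.0], x])
    resid = A @ x - y
    # mean chi-square per pair: ~1 when residuals match their variances
    gof = float(np.sum(w * resid**2) / len(w))
    return pos, gof


def order_group(
    group: list[str],
    table: TwoPointTable,
    gof_jump_threshold: float = DEFAULT_GOF_JUMP,
    ripple_window: int = 3,
    min_link_lod: float = DEFAULT_LOD_THRESHOLD,
) -> OrderingResult:
    """Order one linkage group by sequential insertion.

    Seeds with the highest-LOD pair, then repeatedly inserts the
    unplaced marker with strongest linkage to the current map at the
    slot minimizing the weighted least-squares discrepancy between map
    positions and pairwise Kosambi distances (each pair weighted by the
    inverse variance of its distance estimate, so residuals are scored
    in standard-deviation units), rippling a window of
    ``ripple_window`` around the insertion point.  A marker whose best
    insertion raises the normalized goodness-of-fit by more than
    ``gof_jump_threshold``, or whose strongest linkage to the placed map
    falls below ``min_link_lod``, is deferred, retried once after the
    first pass, then demoted to accessory status anchored at its
    max-LOD framework marker.
    """
    if len(group) < 2:
        raise ValueError("order_group needs >= 2 markers")
    idx = [table.index[m] for m in group]
    sub_r = table.r[np.ix_(idx, idx)]
    sub_lod = table.lod[np.ix_(idx, idx)]
    sub_n = table.n[np.ix_(idx, idx)]
    k = len(group)
    D = np.vectorize(lambda rr: kosambi(min(rr, 0.4999)))(sub_r)
    # inverse variance of the Kosambi distance: var(d) = (dd/dr)^2 var(r),
    # dd/dr = 100/(1-4r^2), var(r) ~ r(1-r)/n_meioses
    rc = np.clip(sub_r, 0.01, 0.49)
    W = sub_n * (1.0 - 4.0 * rc**2) ** 2 / (1.0e4 * rc * (1.0 - rc))
    W[sub_lod <= 0] = 0.0

    tri = np.triu(sub_lod, k=1)
    a, b = np.unravel_index(np.argmax(tri), tri.shape)
    order = [a, b]
    gof_trace: list[float] = [0.0]
    gof_cur = 0.0
    remaining = [i for i in range(k) if i not in order]
    deferred: list[int] = []

    def best_insertion(m, order, gof_cur):
        best = None
        for slot in range(len(order) + 1):
            cand = order[:slot] + [m] + order[slot:]
            pos, gof = _ls_positions(cand, D, W)
            if best is None or gof < best[1]:
                best = (cand, gof)
        return best

    def ripple(order, gof_cur, around):
        # ripple only windows overlapping the newly placed locus
        improved = True
        while improved:
            improved = False
            pos_in = order.index(around)
            lo = max(0, pos_in - ripple_window + 1)
            hi = min(len(order) - ripple_window, pos_in)
            for start in range(lo, hi + 1):
                window = order[start : start + ripple_window]
                for perm in itertools.permutations(window):
                    if list(perm) == window:
                        continue
                    cand = order[:start] + list(perm) + order[start + ripple_window :]
                    _, gof = _ls_positions(cand, D, W)
                    if gof < gof_cur - 1e-12:
                        order, gof_cur = cand, gof
                        improved = True
        return order, gof_cur

    def place_round(pool, order, gof_cur, defer_to):
        pool = list(pool)
        while pool:
            linked = max(pool, key=lambda m: sub_lod[m, order].max())
            pool.remove(linked)
            if sub_lod[linked, order].max() < min_link_lod:
                defer_to.append(linked)
                continue
            cand, gof = best_insertion(linked, order, gof_cur)
            if gof - gof_cur > gof_jump_threshold:
                defer_to.append(linked)
                continue
            order, gof_cur = cand, gof
            if len(order) >= ripple_window:
                order, gof_cur = ripple(order, gof_cur, linked)
            gof_trace.append(gof_cur)
        return order, gof_cur

    order, gof_cur = place_round(remaining, order, gof_cur, deferred)
    retry, deferred = deferred, []
    order, gof_cur = place_round(retry, order, gof_cur, deferred)

    pos, _ = _ls_positions(order, D, W)
    if pos[-1] < pos[0]:  # canonical orientation: increasing positions
        order = order[::-1]
        pos, _ = _ls_positions(order, D, W)
    # monotone cumulative positions from the LS fit
    pos = pos - pos.min()
    pos = np.maximum.accumulate(pos)
    pos = pos - pos[0]

    accessory = []
    for m in deferred:
        anchor = int(np.argmax(sub_lod[m, order]))
        anchor_idx = order[anchor]
        accessory.append(
            (
                group[m],
                group[anchor_idx],
                float(sub_r[m, anchor_idx]),
                float(sub_lod[m, anchor_idx]),
            )
        )
    return OrderingResult(
        order=[group[i] for i in order],
        positions=[float(p) for p in pos],
        gof_trace=gof_trace,
        accessory=accessory,
    )


def build_map(
    table: TwoPointTable,
    lod_threshold: float = DEFAULT_LOD_THRESHOLD,
    gof_jump_threshold: float = DEFAULT_GOF_JUMP,
    label_prefix: str = "LG",
):
    """Group then order all markers of a two-point table into a map."""
    from .formats import LinkageGroup, LinkageMapModel

    groups = group_markers(table, lod_threshold)
    lgs = []
    n = 0
    for comp in groups:
        n += 1
        label = f"{label_prefix}{n}"
        if len(comp) < 2:
            lgs.append(LinkageGroup(label, [(comp[0], 0.0)]))
            continue
        res = order_group(
            comp, table, gof_jump_threshold, min_link_lod=lod_threshold
        )
        lgs.append(
            LinkageGroup(
                label,
                list(zip(res.order, res.positions)),
                res.accessory,
            )
        )
    return LinkageMapModel(groups=lgs)
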