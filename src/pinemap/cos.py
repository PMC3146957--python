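"""Comparative orthologous sequence (COS) detection and linkage-group
alignment between two conifer genera (pine and spruce).

A COS marker is a single-copy gene with exactly one unigene per genus
inside one clustered family.  The chain is: filter tabular similarity
hits (coverage >= 60% of the shorter sequence, identity strictly above
80%), Markov-cluster each genus's hit graph to find within-genus gene
families, call size-one clusters singletons, join the two genera's
singletons and re-cluster the cross-genus hits, then flag families with
exactly one member per genus as COS and bin them into confidence
categories A-E from database-hit evidence.  Markov clustering is
implemented here directly (expansion/inflation of a column-stochastic
matrix), as the pipeline consumes hit tables rather than driving the
external TribeMCL binary.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .formats import FormatError, SimilarityHit

DEFAULT_MIN_COV = 0.60
DEFAULT_MIN_IDENTITY = 80.0
DEFAULT_INFLATION = 2.0
DEFAULT_MIN_ANCHORS = 3
DEFAULT_ORTHOLOG_MIN_COV = 0.75


class ValidationError(ValueError):
    pass


def filter_cos_hits(
    hits: list[SimilarityHit],
    min_cov: float = DEFAULT_MIN_COV,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> list[SimilarityHit]:
    """Keep hits covering >= *min_cov* of the shorter sequence with
    identity strictly above *min_identity*; self-hits are dropped.
    Idempotent."""
    kept = []
    for h in hits:
        if h.is_self_hit:
            continue
        if h.query_length <= 0 or h.subject_length <= 0:
            raise FormatError(
                f"hit {h.query_id}/{h.subject_id}: missing sequence lengths"
            )
        shorter = min(h.query_length, h.subject_length)
        if h.alignment_length / shorter < min_cov:
            continue
        if not h.percent_identity > min_identity:
            continue
        kept.append(h)
    return kept


def hits_to_graph(hits: list[SimilarityHit], all_ids=None) -> nx.Graph:
    """Undirected similarity graph; reciprocal hits keep the max weight
    (weight = percent identity).  ``all_ids`` adds isolated unigenes."""
    g = nx.Graph()
    if all_ids is not None:
        g.add_nodes_from(all_ids)
    for h in hits:
        if h.is_self_hit:
            continue
        w = float(h.percent_identity)
        if g.has_edge(h.query_id, h.subject_id):
            g[h.query_id][h.subject_id]["weight"] = max(
                g[h.query_id][h.subject_id]["weight"], w
            )
        else:
            g.add_edge(h.query_id, h.subject_id, weight=w)
    return g


def mcl_cluster(
    graph: nx.Graph,
    inflation: float = DEFAULT_INFLATION,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> list[set]:
    """Markov clustering of a weighted similarity graph.

    Self-loops (weight = the node's maximum incident weight, or 1 for
    isolated nodes) are added, columns normalized, then expansion
    (matrix squaring) and inflation (elementwise power + renormalize)
    alternate until the matrix is stable.  Clusters are read from
    attractor rows and returned as a partition of all nodes; nodes in
    different connected components can never share a cluster.
    """
    nodes = list(graph.nodes)
    n = len(nodes)
    if n == 0:
        return []
    idx = {v: i for i, v in enumerate(nodes)}
    M = np.zeros((n, n))
    for u, v, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        if not np.isfinite(w) or w < 0:
            raise ValueError(f"edge {u}-{v}: non-finite or negative weight {w}")
        M[idx[u], idx[v]] = M[idx[v], idx[u]] = w
    loop = M.max(axis=0)
    loop[loop <= 0] = 1.0
    M[np.diag_indices(n)] = loop

    def normalize(A):
        col = A.sum(axis=0)
        col[col == 0] = 1.0
        return A / col

    M = normalize(M)
    for _ in range(max_iter):
        prev = M
        M = normalize(np.power(M @ M, inflation))
        M[M < 1e-12] = 0.0
        if np.max(np.abs(M - prev)) < tol:
            break

    thresh = 1e-6
    attractors = [i for i in range(n) if M[i, i] > thresh]
    membership = [set(np.flatnonzero(M[i] > thresh)) | {i} for i in attractors]
    # merge overlapping attractor systems into one cluster each
    clusters: list[set] = []
    for mem in membership:
        merged = None
        for c in clusters:
            if c & mem:
                merged = c
                break
        if merged is None:
            clusters.append(set(mem))
        else:
            merged |= mem
    assigned = set().union(*clusters) if clusters else set()
    for i in range(n):
        if i not in assigned:
            clusters.append({i})
    # a node attracted by two systems would break the partition: merge
    changed = True
    while changed:
        changed = False
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                if clusters[i] & clusters[j]:
                    clusters[i] |= clusters.pop(j)
                    changed = True
                    break
            if changed:
                break
    out = [set(nodes[i] for i in c) for c in clusters]
    out.sort(key=lambda c: (-len(c), min(str(x) for x in c)))
    return out


def identify_singletons(unigene_ids, clusters: list[set]) -> set:
    """Unigenes that do not form a family with any other sequence:
    members of size-one clusters plus ids absent from all clusters."""
    ids = set(unigene_ids)
    singles = set()
    clustered = set()
    for c in clusters:
        clustered |= c
        if len(c) == 1:
            singles |= c & ids
    singles |= ids - clustered
    return singles


@dataclass
class CosFamily:
    family_id: str
    pine_members: list[str]
    spruce_members: list[str]
    is_cos: bool
    category: str | None = None  # assigned only to COS families

    @property
    def members(self) -> list[str]:
        return self.pine_members + self.spruce_members


def identify_cos(
    pine_singletons: set, spruce_singletons: set, clusters: list[set]
) -> list[CosFamily]:
    """Flag clustered families holding exactly one pine and one spruce
    singleton as COS; other families are retained with is_cos=False."""
    fams = []
    for k, c in enumerate(clusters):
        pine = sorted(c & set(pine_singletons))
        spruce = sorted(c & set(spruce_singletons))
        fams.append(
            CosFamily(
                family_id=f"fam{k:04d}",
                pine_members=pine,
                spruce_members=spruce,
                is_cos=(len(pine) == 1 and len(spruce) == 1),
            )
        )
    return fams


@dataclass
class CosFlags:
    """Database-evidence flags for one COS family."""

    has_plaza_hit: bool = False
    has_nr_hit: bool = False
    has_maritime_hit: bool = False
    in_tgi_only: bool = False
    duplication_flag: bool = False


def categorize_one(flags: CosFlags) -> str:
    """Map evidence flags to the A-E confidence category.

    Precedence: E (duplication/alternative-splice signature) over A
    (protein hit in PLAZA) over B (NCBI-nr hit only) over C (maritime
    pine unigene set only) over D (conifer TGI unigenes only).  A family
    with no evidence at all is contradictory — every COS came from the
    TGI unigene sets, so some flag must hold.
    """
    if flags.duplication_flag:
        return "E"
    if flags.has_plaza_hit:
        return "A"
    if flags.has_nr_hit:
        return "B"
    if flags.has_maritime_hit:
        return "C"
    if flags.in_tgi_only:
        return "D"
    raise ValidationError("contradictory flags: no database evidence set")


def categorize_cos(
    families: list[CosFamily], flags: dict[str, CosFlags]
) -> list[CosFamily]:
    """Assign categories to COS families in place (non-COS untouched)."""
    for fam in families:
        if fam.is_cos:
            fam.category = categorize_one(flags[fam.family_id])
    return families


@dataclass
class LgAlignment:
    counts: dict  # (group_a, group_b) -> shared ortholog count
    homologous_pairs: list[tuple]  # declared pairs, count >= min_anchors
    conflicts: list[str]  # ortholog ids contradicting a declared homology
    excluded_low_cov: list[str]


def align_linkage_groups(
    orthologs: list[tuple],
    min_anchors: int = DEFAULT_MIN_ANCHORS,
    ortholog_min_cov: float = DEFAULT_ORTHOLOG_MIN_COV,
) -> LgAlignment:
    """Declare homologous linkage-group pairs between two species maps.

    ``orthologs`` holds (ortholog_id, group_in_A, group_in_B, coverage)
    tuples; rows under the coverage screen are excluded.  A group pair
    is declared homologous when it shares >= *min_anchors* orthologs;
    an ortholog whose group pair is undeclared while either group
    belongs to a declared pair is reported as a conflict (putative
    paralogy).
    """
    counts: dict[tuple, int] = {}
    used = []
    excluded = []
    for row in orthologs:
        if len(row) == 4:
            oid, ga, gb, cov = row
        else:
            oid, ga, gb = row
            cov = 1.0
        if ga is None or gb is None:
            raise ValidationError(f"ortholog {oid}: missing group label")
        if cov < ortholog_min_cov:
            excluded.append(oid)
            continue
        used.append((oid, ga, gb))
        counts[(ga, gb)] = counts.get((ga, gb), 0) + 1
    declared = sorted(p for p, c in counts.items() if c >= min_anchors)
    declared_a = {a for a, _ in declared}
    declared_b = {b for _, b in declared}
    conflicts = [
        oid
        for oid, ga, gb in used
        if (ga, gb) not in declared and (ga in declared_a or gb in declared_b)
    ]
    return LgAlignment(
        counts=counts,
        homologous_pairs=declared,
        conflicts=conflicts,
        excluded_low_cov=excluded,
    )
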