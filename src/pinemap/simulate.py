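"""Synthetic genomes, pedigrees and genotype matrices.

The generator emulates the data structure of a conifer SNP-mapping study:
a 12-linkage-group genome totalling ~2,500 cM, an outbred full-sib (CP)
cross in which SNPs segregate 1:1 (``lmxll`` via the seed parent,
``nnxnp`` via the pollen parent) or 1:2:1 (``hkxhk``, both parents
heterozygous), and a selfed F2 progeny with codominant a/h/b calls.
Several markers may share a contig (separated by <0.01 cM), genotyping
errors are injected as uniform mis-calls among the legal alternatives,
and missing data as uniform no-calls.

Meioses use a no-interference crossover model: recombination between
adjacent markers at distance d cM occurs with the Haldane probability
r = (1 - exp(-2d/100))/2, equivalent to a Poisson crossover process.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .formats import (
    CP_CODES,
    F2_CALLS,
    F2_CODE,
    AlignedFragment,
    GenotypeMatrix,
    MarkerMeta,
    SimilarityHit,
    legal_calls,
)

DEFAULT_N_GROUPS = 12
DEFAULT_GENOME_CM = 2500.0
# markers of one contig are a few hundred bp apart: genetically co-located
CONTIG_OFFSET_CM = 0.0


class ConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Knobs of the pedigree simulator.

    Defaults mirror the study conditions this package targets: ~90
    offspring per pedigree, a 0.4% genotyping-error rate, a small
    missing-data rate, and a 40/40/20 mixture of lmxll/nnxnp/hkxhk
    segregation types for the CP cross.
    """

    seed: int = 0
    n_offspring: int = 90
    error_rate: float = 0.004
    missing_rate: float = 0.02
    crossover_model: str = "poisson"
    cp_mixture: tuple[float, float, float] = (0.4, 0.4, 0.2)

    def __post_init__(self) -> None:
        for name in ("error_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0,1]")
        if self.n_offspring < 1:
            raise ConfigError("n_offspring must be >= 1")
        if self.crossover_model != "poisson":
            raise ConfigError(f"unknown crossover model {self.crossover_model!r}")
        if abs(sum(self.cp_mixture) - 1.0) > 1e-9:
            raise ConfigError("cp_mixture must sum to 1")


@dataclass
class TrueGenome:
    """Ground truth for a simulated cross: marker positions and phases."""

    n_groups: int
    group_lengths_cM: np.ndarray
    marker_ids: list[str]
    group_of: np.ndarray  # int, per marker
    pos_cM: np.ndarray  # float, per marker, within its group
    seg_type: list[str]  # CP segregation code per marker
    phase_female: np.ndarray  # haplotype (0/1) carrying the minor allele
    phase_male: np.ndarray
    contig_of: list[str]

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def markers_in_group(self, g: int) -> np.ndarray:
        idx = np.flatnonzero(self.group_of == g)
        return idx[np.argsort(self.pos_cM[idx], kind="stable")]

    def marker_meta(self, scores: np.ndarray | None = None) -> list[MarkerMeta]:
        return [
            MarkerMeta(
                marker_id=m,
                contig_id=c,
                designability_score=1.0 if scores is None else float(scores[i]),
            )
            for i, (m, c) in enumerate(zip(self.marker_ids, self.contig_of))
        ]


def simulate_genome(
    config: SimulationConfig,
    n_groups: int = DEFAULT_N_GROUPS,
    group_lengths_cM=None,
    n_markers: int = 360,
    contig_multiplicity: int = 1,
    positions=None,
) -> TrueGenome:
    """Place markers on a multi-group genome and assign phases/seg types.

    Markers are placed uniformly at random (group chosen proportionally to
    its length) unless explicit ``positions`` — a list of (group, cM)
    pairs — are supplied.  With ``contig_multiplicity`` k > 1, markers are
    planted in contigs of k co-located variants (<0.01 cM apart).
    """
    rng = np.random.default_rng([config.seed, 101])
    if group_lengths_cM is None:
        group_lengths_cM = np.full(n_groups, DEFAULT_GENOME_CM / n_groups)
    group_lengths_cM = np.asarray(group_lengths_cM, dtype=float)
    if len(group_lengths_cM) != n_groups:
        raise ConfigError("group_lengths_cM length != n_groups")
    if np.any(group_lengths_cM < 0):
        raise ConfigError("group lengths must be non-negative")
    if n_markers < 2:
        raise ConfigError("need at least 2 markers")
    if contig_multiplicity < 1:
        raise ConfigError("contig_multiplicity must be >= 1")

    if positions is not None:
        group_of = np.array([g for g, _ in positions], dtype=int)
        pos = np.array([p for _, p in positions], dtype=float)
        if len(pos) != n_markers:
            raise ConfigError("positions length != n_markers")
        contigs = [f"ctg{i:05d}" for i in range(n_markers)]
    else:
        n_contigs, rem = divmod(n_markers, contig_multiplicity)
        if rem:
            raise ConfigError(
                "n_markers must be a multiple of contig_multiplicity"
            )
        if np.any((group_lengths_cM == 0) & (n_contigs > n_groups)):
            raise ConfigError("zero-length group cannot hold multiple markers")
        probs = group_lengths_cM / group_lengths_cM.sum()
        cgroups = rng.choice(n_groups, size=n_contigs, p=probs)
        cpos = rng.uniform(0.0, group_lengths_cM[cgroups])
        group_of = np.repeat(cgroups, contig_multiplicity)
        pos = (
            np.repeat(cpos, contig_multiplicity)
            + np.tile(np.arange(contig_multiplicity) * CONTIG_OFFSET_CM, n_contigs)
        )
        pos = np.minimum(pos, np.repeat(group_lengths_cM[cgroups], contig_multiplicity))
        contigs = [
            f"ctg{c:05d}" for c in np.repeat(np.arange(n_contigs), contig_multiplicity)
        ]
    if np.any(pos < 0) or np.any(pos > group_lengths_cM[group_of]):
        raise ConfigError("marker position outside its group")

    codes = list(CP_CODES)
    seg_idx = rng.choice(3, size=n_markers, p=list(config.cp_mixture))
    seg_type = [codes[i] for i in seg_idx]
    return TrueGenome(
        n_groups=n_groups,
        group_lengths_cM=group_lengths_cM,
        marker_ids=[f"M{i:04d}" for i in range(n_markers)],
        group_of=group_of,
        pos_cM=pos,
        seg_type=seg_type,
        phase_female=rng.integers(0, 2, size=n_markers),
        phase_male=rng.integers(0, 2, size=n_markers),
        contig_of=contigs,
    )


def _gamete_haplotypes(rng, genome: TrueGenome, n_meioses: int) -> np.ndarray:
    """Inherited haplotype (0/1) per meiosis x marker, genome order."""
    hap = np.empty((n_meioses, genome.n_markers), dtype=np.int8)
    for g in range(genome.n_groups):
        idx = genome.markers_in_group(g)
        if idx.size == 0:
            continue
        d = np.diff(genome.pos_cM[idx])
        p_switch = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
        draws = np.empty((n_meioses, idx.size), dtype=np.int8)
        draws[:, 0] = rng.integers(0, 2, size=n_meioses)
        if idx.size > 1:
            draws[:, 1:] = rng.random((n_meioses, idx.size - 1)) < p_switch
        hap[:, idx] = np.cumsum(draws, axis=1) % 2
    return hap


def simulate_cross(
    genome: TrueGenome, config: SimulationConfig, pedigree_type: str
) -> GenotypeMatrix:
    """Simulate a CP or F2 progeny and return the genotype matrix.

    CP offspring combine one maternal and one paternal gamete; each
    marker is emitted under its assigned segregation code.  F2 offspring
    combine two independent gametes of the selfed F1 (every marker
    codominant).  Errors and missingness are injected at the configured
    rates after the clean calls are generated.
    """
    if pedigree_type not in ("CP", "F2"):
        raise ConfigError(f"unknown pedigree type {pedigree_type!r}")
    stream = 0 if pedigree_type == "CP" else 1
    rng = np.random.default_rng([config.seed, 7, stream])
    n = config.n_offspring
    nm = genome.n_markers

    if pedigree_type == "CP":
        hap_f = _gamete_haplotypes(rng, genome, n)
        hap_m = _gamete_haplotypes(rng, genome, n)
        # allele 1 = the informative parent's "second" allele (m, p or k)
        allele_f = (hap_f == genome.phase_female[None, :]).astype(np.int8)
        allele_m = (hap_m == genome.phase_male[None, :]).astype(np.int8)
        calls: list[list[str]] = []
        for i in range(nm):
            code = genome.seg_type[i]
            if code == "lmxll":
                row = np.where(allele_f[:, i] == 1, "lm", "ll")
            elif code == "nnxnp":
                row = np.where(allele_m[:, i] == 1, "np", "nn")
            else:  # hkxhk
                dose = allele_f[:, i] + allele_m[:, i]
                row = np.array(["hh", "hk", "kk"])[dose]
            calls.append(list(row))
        seg_codes = list(genome.seg_type)
    else:
        hap1 = _gamete_haplotypes(rng, genome, n)
        hap2 = _gamete_haplotypes(rng, genome, n)
        a1 = (hap1 == genome.phase_female[None, :]).astype(np.int8)
        a2 = (hap2 == genome.phase_female[None, :]).astype(np.int8)
        dose = a1 + a2
        lut = np.array(F2_CALLS)
        calls = [list(lut[dose[:, i]]) for i in range(nm)]
        seg_codes = [F2_CODE] * nm

    matrix = GenotypeMatrix(
        pedigree_type=pedigree_type,
        marker_ids=list(genome.marker_ids),
        seg_codes=seg_codes,
        calls=calls,
        offspring_ids=[f"off{j:03d}" for j in range(n)],
        name=f"sim_{pedigree_type}",
    )
    if config.error_rate > 0:
        matrix = _inject_errors_rng(matrix, config.error_rate, rng)
    if config.missing_rate > 0:
        matrix = inject_missing_rng(matrix, config.missing_rate, rng)
    return matrix


def _inject_errors_rng(matrix: GenotypeMatrix, rate: float, rng) -> GenotypeMatrix:
    miss = matrix.missing_symbol
    new_calls = []
    for code, row in zip(matrix.seg_codes, matrix.calls):
        legal = legal_calls(matrix.pedigree_type, code)
        out = list(row)
        flip = rng.random(len(row)) < rate
        for j in np.flatnonzero(flip):
            if out[j] == miss:
                continue
            alts = [c for c in legal if c != out[j]]
            out[j] = alts[rng.integers(len(alts))]
        new_calls.append(out)
    return replace(matrix, calls=new_calls)


def inject_errors(matrix: GenotypeMatrix, rate: float, seed: int) -> GenotypeMatrix:
    """Replace each non-missing call, independently with probability
    *rate*, by a uniformly chosen different legal call."""
    if not 0.0 <= rate <= 1.0:
        raise ConfigError(f"rate={rate} outside [0,1]")
    return _inject_errors_rng(matrix, rate, np.random.default_rng([seed, 13]))


def inject_missing_rng(matrix: GenotypeMatrix, rate: float, rng) -> GenotypeMatrix:
    miss = matrix.missing_symbol
    new_calls = []
    for row in matrix.calls:
        out = list(row)
        drop = rng.random(len(row)) < rate
        for j in np.flatnonzero(drop):
            out[j] = miss
        new_calls.append(out)
    return replace(matrix, calls=new_calls)


def inject_missing(matrix: GenotypeMatrix, rate: float, seed: int) -> GenotypeMatrix:
    if not 0.0 <= rate <= 1.0:
        raise ConfigError(f"rate={rate} outside [0,1]")
    return inject_missing_rng(matrix, rate, np.random.default_rng([seed, 17]))


# ---------------------------------------------------------------------------
# aligned-fragment simulation (feeds the discovery stage)
# ---------------------------------------------------------------------------

def simulate_fragments(
    seed: int,
    n_fragments: int = 20,
    depth: int = 12,
    length: int = 400,
    n_snps_per_fragment: int = 3,
    low_quality_rate: float = 0.01,
    source_tag: str = "in_vitro",
):
    """Generate haploid aligned fragments with planted bi-allelic SNPs.

    Returns ``(fragments, truth)`` where truth maps fragment_id to the
    list of planted variant columns.  Planted SNPs always satisfy the
    discovery filters (minor count >= 2); low-quality cells (Phred 10)
    are sprinkled at ``low_quality_rate`` to exercise masking.
    """
    rng = np.random.default_rng([seed, 23])
    bases = np.array(list("ACGT"))
    fragments = []
    truth: dict[str, list[int]] = {}
    for f in range(n_fragments):
        fid = f"frag{f:03d}"
        ref = rng.choice(4, size=length)
        seqs = np.tile(ref, (depth, 1))
        cols = rng.choice(length, size=n_snps_per_fragment, replace=False)
        for col in np.sort(cols):
            alt = (ref[col] + rng.integers(1, 4)) % 4
            minor = rng.integers(2, depth // 2 + 1)
            carriers = rng.choice(depth, size=minor, replace=False)
            seqs[carriers, col] = alt
        qual = np.full((depth, length), 40, dtype=int)
        low = rng.random((depth, length)) < low_quality_rate
        qual[low] = 10
        seq_strs = ["".join(bases[row]) for row in seqs]
        fragments.append(
            AlignedFragment(fid, seq_strs, qual.tolist(), source_tag=source_tag)
        )
        truth[fid] = sorted(int(c) for c in cols)
    return fragments, truth


# ---------------------------------------------------------------------------
# ortholog-universe simulation (feeds the COS stage)
# ---------------------------------------------------------------------------

def simulate_cos_universe(
    seed: int,
    n_orthologs: int = 10,
    n_paralog_families: int = 3,
    n_lone: int = 5,
):
    """Build a pine/spruce unigene universe with planted one-to-one
    orthologs and within-genus paralog families, plus the within- and
    cross-genus similarity hits their sequences would produce.

    Returns ``(pine_ids, spruce_ids, within_hits, cross_hits, truth)``;
    truth lists the planted (pine_id, spruce_id) ortholog pairs.
    """
    rng = np.random.default_rng([seed, 29])
    pine, spruce = [], []
    within: list[SimilarityHit] = []
    cross: list[SimilarityHit] = []
    truth = []

    def hit(q, s, ident=95.0, alen=450, qlen=500, slen=500):
        return SimilarityHit(q, s, ident, alen, qlen, slen, e_value=1e-50, bit_score=800.0)

    for i in range(n_orthologs):
        p, s = f"pine_ort{i:02d}", f"spruce_ort{i:02d}"
        pine.append(p)
        spruce.append(s)
        ident = float(rng.uniform(85, 99))
        cross.append(hit(p, s, ident=ident))
        cross.append(hit(s, p, ident=ident))
        truth.append((p, s))
    for fam in range(n_paralog_families):
        members = [f"pine_par{fam}{k}" for k in range(3)]
        pine.extend(members)
        for a in members:
            for b in members:
                if a != b:
                    within.append(hit(a, b, ident=float(rng.uniform(90, 99))))
    for i in range(n_lone):
        pine.append(f"pine_lone{i:02d}")
        spruce.append(f"spruce_lone{i:02d}")
    return pine, spruce, within, cross, truth
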