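"""SNP/indel discovery in aligned gene fragments and array-panel selection.

Mirrors the snp2illumina-style screening used when designing a
GoldenGate SNP array from resequenced amplicons and EST assemblies:
Phred masking (scores < 30 become N), bi-allelic SNPs and 1-6 bp
indels with detection depth >= 4 and minor allele count >= 2
(singletons discarded), then panel selection under a designability
floor (score > 0.4), a 60-nt spacing constraint, a within-fragment
linkage-disequilibrium screen, and a per-gene cap favouring breadth
of gene coverage over depth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .formats import AlignedFragment, FormatError, MarkerMeta

DEFAULT_PHRED_THRESHOLD = 30
DEFAULT_MIN_DEPTH = 4
DEFAULT_MIN_SCORE = 0.4
DEFAULT_MIN_SPACING_NT = 60
DEFAULT_LD_THRESHOLD = 0.9
DEFAULT_PER_GENE_CAP = 2
MAX_INDEL_LEN = 6

BASES = set("ACGT")


@dataclass
class PolymorphismRecord:
    """A detected bi-allelic SNP or short indel."""

    fragment_id: str
    column: int  # 0-based alignment column (indels: run start)
    type: str  # "SNP" | "indel"
    alleles: tuple[str, str]
    detection_depth: int
    minor_count: int
    indel_length: int = 0

    @property
    def maf(self) -> float:
        return self.minor_count / self.detection_depth

    @property
    def marker_id(self) -> str:
        return f"{self.fragment_id}_{self.column}"


def mask_low_quality(
    fragment: AlignedFragment, threshold: int = DEFAULT_PHRED_THRESHOLD
) -> AlignedFragment:
    """Replace every base whose Phred score is below *threshold* with N.

    Gap cells (score sentinel -1) are untouched; a base scored exactly at
    the threshold is retained.
    """
    if fragment.qualities is None:
        raise FormatError(f"fragment {fragment.fragment_id}: no quality scores")
    masked = []
    for seq, quals in zip(fragment.sequences, fragment.qualities):
        chars = list(seq)
        for i, (c, q) in enumerate(zip(chars, quals)):
            if c != "-" and 0 <= q < threshold:
                chars[i] = "N"
        masked.append("".join(chars))
    return replace(fragment, sequences=masked)


def _gap_runs(seq: str):
    """Maximal gap runs of one sequence as (start, length) pairs."""
    runs = []
    start = None
    for i, c in enumerate(seq + "$"):
        if c == "-":
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i - start))
            start = None
    return runs


def detect_polymorphisms(
    fragment: AlignedFragment,
    min_depth: int = DEFAULT_MIN_DEPTH,
    drop_singletons: bool = True,
) -> list[PolymorphismRecord]:
    """Scan a masked alignment for bi-allelic SNPs and 1-6 bp indels.

    A SNP column qualifies iff exactly two bases occur among its non-N,
    non-gap characters, at least *min_depth* sequences carry a base, and
    (with *drop_singletons*) the minor allele is seen at least twice.
    An indel qualifies iff a gap run of identical extent (1-6 columns)
    is present in some sequences and absent (all bases, no N) in others,
    with the same depth/minor-count rules; presence/absence are the two
    alleles, anchored at the run's start column.
    """
    records: list[PolymorphismRecord] = []
    seqs = fragment.sequences
    L = fragment.length
    min_minor = 2 if drop_singletons else 1

    for col in range(L):
        chars = [s[col] for s in seqs]
        bases = [c for c in chars if c in BASES]
        counts = {b: bases.count(b) for b in set(bases)}
        if len(counts) != 2:
            continue
        depth = len(bases)
        if depth < min_depth:
            continue
        (major, _), (minor, minor_n) = sorted(
            counts.items(), key=lambda kv: (-kv[1], kv[0])
        )
        if minor_n < min_minor:
            continue
        records.append(
            PolymorphismRecord(
                fragment_id=fragment.fragment_id,
                column=col,
                type="SNP",
                alleles=(major, minor),
                detection_depth=depth,
                minor_count=minor_n,
            )
        )

    # indels: group identical (start, length) gap runs across sequences
    run_carriers: dict[tuple[int, int], list[int]] = {}
    for i, s in enumerate(seqs):
        for run in _gap_runs(s):
            run_carriers.setdefault(run, []).append(i)
    for (start, length), carriers in sorted(run_carriers.items()):
        if length > MAX_INDEL_LEN:
            continue
        absent = []
        conflicted = False
        for i, s in enumerate(seqs):
            if i in carriers:
                continue
            window = s[start : start + length]
            if "-" in window:  # partially overlapping different run
                conflicted = True
                break
            if "N" in window:
                continue  # masked: not counted in depth
            absent.append(i)
        if conflicted:
            continue
        depth = len(carriers) + len(absent)
        minor_n = min(len(carriers), len(absent))
        if depth < min_depth or minor_n < min_minor or minor_n == 0:
            continue
        records.append(
            PolymorphismRecord(
                fragment_id=fragment.fragment_id,
                column=start,
                type="indel",
                alleles=("ins", "del") if len(absent) >= len(carriers) else ("del", "ins"),
                detection_depth=depth,
                minor_count=minor_n,
                indel_length=length,
            )
        )
    records.sort(key=lambda r: (r.column, r.type))
    return records


def ungapped_positions(fragment: AlignedFragment) -> list[int]:
    """Map alignment columns to ungapped fragment coordinates.

    A column counts toward the coordinate if at least half the sequences
    carry a base there (majority-consensus convention).
    """
    depth = fragment.depth
    pos = []
    u = 0
    for col in range(fragment.length):
        pos.append(u)
        n_base = sum(1 for s in fragment.sequences if s[col] != "-")
        if n_base * 2 >= depth:
            u += 1
    return pos


def haplotype_r2(fragment: AlignedFragment, col_a: int, col_b: int) -> float:
    """Pairwise LD (r²) between two variant columns, computed directly on
    the discovery haplotypes (haploid sequences).

    Sequences with a missing (N or gap) character at either column are
    dropped.  Monomorphic columns (after dropping) give r² = 0.
    """
    pairs = [
        (s[col_a], s[col_b])
        for s in fragment.sequences
        if s[col_a] in BASES and s[col_b] in BASES
    ]
    if not pairs:
        return 0.0
    n = len(pairs)
    a_alleles = sorted({a for a, _ in pairs})
    b_alleles = sorted({b for _, b in pairs})
    if len(a_alleles) < 2 or len(b_alleles) < 2:
        return 0.0
    pa = sum(1 for a, _ in pairs if a == a_alleles[0]) / n
    pb = sum(1 for _, b in pairs if b == b_alleles[0]) / n
    pab = sum(1 for a, b in pairs if a == a_alleles[0] and b == b_alleles[0]) / n
    denom = pa * (1 - pa) * pb * (1 - pb)
    if denom <= 0:
        return 0.0
    d = pab - pa * pb
    return d * d / denom


@dataclass
class Rejection:
    record: PolymorphismRecord
    rule: str  # "score" | "spacing" | "LD" | "cap"


def select_for_array(
    records: list[PolymorphismRecord],
    meta: dict[str, MarkerMeta],
    fragments: dict[str, AlignedFragment] | None = None,
    min_score: float = DEFAULT_MIN_SCORE,
    min_spacing_nt: int = DEFAULT_MIN_SPACING_NT,
    ld_threshold: float = DEFAULT_LD_THRESHOLD,
    per_gene_cap: int = DEFAULT_PER_GENE_CAP,
) -> tuple[list[PolymorphismRecord], list[Rejection]]:
    """Select an array panel from detected polymorphisms.

    Four filters fire in order, each rejection logged with its rule:
    (1) designability score below *min_score*; (2) within-fragment
    spacing: among candidates closer than *min_spacing_nt* (ungapped
    coordinates), the higher-MAF one wins (ties: higher score, then
    leftmost); (3) within-fragment LD: a candidate whose haplotype r²
    with an already-kept record exceeds *ld_threshold* is dropped
    (requires *fragments*; skipped when None); (4) a per-fragment cap
    preferring breadth of gene coverage.
    """
    for r in records:
        if r.marker_id not in meta:
            raise KeyError(f"no metadata for record {r.marker_id}")

    selected: list[PolymorphismRecord] = []
    rejections: list[Rejection] = []

    by_frag: dict[str, list[PolymorphismRecord]] = {}
    for r in records:
        m = meta[r.marker_id]
        if m.designability_score < min_score:
            rejections.append(Rejection(r, "score"))
            continue
        by_frag.setdefault(r.fragment_id, []).append(r)

    for fid in sorted(by_frag):
        cands = by_frag[fid]
        frag = fragments.get(fid) if fragments else None
        upos = ungapped_positions(frag) if frag is not None else None

        def coord(rec: PolymorphismRecord) -> int:
            return upos[rec.column] if upos is not None else rec.column

        priority = sorted(
            cands,
            key=lambda r: (-r.maf, -meta[r.marker_id].designability_score, coord(r)),
        )
        kept: list[PolymorphismRecord] = []
        for r in priority:
            if any(abs(coord(r) - coord(k)) < min_spacing_nt for k in kept):
                rejections.append(Rejection(r, "spacing"))
                continue
            if frag is not None and any(
                haplotype_r2(frag, r.column, k.column) > ld_threshold for k in kept
            ):
                rejections.append(Rejection(r, "LD"))
                continue
            kept.append(r)
        kept.sort(key=lambda r: (-r.maf, -meta[r.marker_id].designability_score, coord(r)))
        for r in kept[per_gene_cap:]:
            rejections.append(Rejection(r, "cap"))
        selected.extend(sorted(kept[:per_gene_cap], key=coord))

    return selected, rejections


def surrogate_design_score(fragment: AlignedFragment, column: int, window: int = 30) -> float:
    """Synthetic designability score for fixtures (GC/complexity heuristic).

    This is NOT the vendor SNPScore: real designability comes from the
    array manufacturer's assay-design tool and is consumed as metadata.
    The surrogate scores flanking-sequence GC balance and base diversity
    so that fixture pipelines have a plausible [0,1] score to filter on.
    """
    seq = fragment.sequences[0]
    lo, hi = max(0, column - window), min(len(seq), column + window + 1)
    flank = [c for c in seq[lo:hi] if c in BASES]
    if not flank:
        return 0.0
    gc = sum(1 for c in flank if c in "GC") / len(flank)
    diversity = len(set(flank)) / 4.0
    gc_balance = 1.0 - 2.0 * abs(gc - 0.5)
    return round(0.3 + 0.4 * gc_balance + 0.3 * diversity, 3)
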