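"""Domain types and file formats for the linkage-mapping pipeline.

The on-disk genotype dialect follows the JoinMap ``.loc`` convention:
a header declaring population name, population type (``CP`` or ``F2``),
locus and individual counts, followed by one block per locus.  CP loci
carry a segregation code (``<lmxll>``, ``<nnxnp>`` or ``<hkxhk>``) and
calls from the code's legal set; F2 loci are codominant with calls
``a``/``h``/``b``.  Missing data is ``--`` (CP) or ``-`` (F2); readers
also accept ``.`` as an alias.  All readers reject malformed input with
an error naming the offending marker/line rather than coercing.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

# legal genotype calls per segregation code (missing handled separately)
CP_CODES = {
    "lmxll": ("ll", "lm"),
    "nnxnp": ("nn", "np"),
    "hkxhk": ("hh", "hk", "kk"),
}
F2_CODE = "codom"
F2_CALLS = ("a", "h", "b")
MISSING = {"CP": "--", "F2": "-"}

DNA_ALPHABET = set("ACGTN-")


class FormatError(ValueError):
    """Raised when an input file violates the declared dialect."""


def legal_calls(pedigree_type: str, seg_code: str) -> tuple[str, ...]:
    if pedigree_type == "CP":
        try:
            return CP_CODES[seg_code]
        except KeyError:
            raise FormatError(f"unknown CP segregation code {seg_code!r}")
    if pedigree_type == "F2":
        return F2_CALLS
    raise FormatError(f"unknown pedigree type {pedigree_type!r}")


@dataclass
class AlignedFragment:
    """A multiple alignment of haploid gene-fragment sequences.

    ``qualities`` (optional) holds one Phred score per alignment cell;
    gap cells carry the sentinel -1 and are never masked.
    """

    fragment_id: str
    sequences: list[str]
    qualities: list[list[int]] | None = None
    source_tag: str = "in_vitro"

    def __post_init__(self) -> None:
        if not self.sequences:
            raise FormatError(f"fragment {self.fragment_id}: no sequences")
        L = len(self.sequences[0])
        for i, s in enumerate(self.sequences):
            if len(s) != L:
                raise FormatError(
                    f"fragment {self.fragment_id}: sequence {i} has length "
                    f"{len(s)} != {L}"
                )
            bad = set(s) - DNA_ALPHABET
            if bad:
                raise FormatError(
                    f"fragment {self.fragment_id}: illegal characters {bad}"
                )
        if self.qualities is not None:
            if len(self.qualities) != len(self.sequences) or any(
                len(q) != L for q in self.qualities
            ):
                raise FormatError(
                    f"fragment {self.fragment_id}: quality matrix shape does "
                    "not match sequences"
                )
        if self.source_tag not in ("in_vitro", "in_silico"):
            raise FormatError(
                f"fragment {self.fragment_id}: bad source_tag {self.source_tag!r}"
            )

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def depth(self) -> int:
        return len(self.sequences)


@dataclass
class GenotypeMatrix:
    """Segregation-coded genotypes, markers x offspring, for one pedigree."""

    pedigree_type: str  # "CP" or "F2"
    marker_ids: list[str]
    seg_codes: list[str]  # per marker; F2 markers all carry ``codom``
    calls: list[list[str]]  # markers x offspring
    offspring_ids: list[str]
    name: str = "pop"

    def __post_init__(self) -> None:
        if self.pedigree_type not in ("CP", "F2"):
            raise FormatError(f"unknown pedigree type {self.pedigree_type!r}")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            dup = sorted(
                m for m in set(self.marker_ids) if self.marker_ids.count(m) > 1
            )
            raise FormatError(f"duplicate marker id(s): {', '.join(dup)}")
        if len(self.seg_codes) != len(self.marker_ids):
            raise FormatError("seg_codes length != marker_ids length")
        if len(self.calls) != len(self.marker_ids):
            raise FormatError("calls rows != marker count")
        miss = MISSING[self.pedigree_type]
        for mid, code, row in zip(self.marker_ids, self.seg_codes, self.calls):
            if len(row) != len(self.offspring_ids):
                raise FormatError(f"marker {mid}: call count != offspring count")
            legal = set(legal_calls(self.pedigree_type, code)) | {miss}
            for j, call in enumerate(row):
                if call not in legal:
                    raise FormatError(
                        f"marker {mid}, offspring column {j}: illegal call "
                        f"{call!r} for segregation code {code}"
                    )

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def n_offspring(self) -> int:
        return len(self.offspring_ids)

    @property
    def missing_symbol(self) -> str:
        return MISSING[self.pedigree_type]

    def marker_index(self, marker_id: str) -> int:
        return self.marker_ids.index(marker_id)

    def row(self, marker_id: str) -> list[str]:
        return self.calls[self.marker_index(marker_id)]

    def seg_code(self, marker_id: str) -> str:
        return self.seg_codes[self.marker_index(marker_id)]

    def subset(self, marker_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.marker_index(m) for m in marker_ids]
        return GenotypeMatrix(
            pedigree_type=self.pedigree_type,
            marker_ids=[self.marker_ids[i] for i in idx],
            seg_codes=[self.seg_codes[i] for i in idx],
            calls=[list(self.calls[i]) for i in idx],
            offspring_ids=list(self.offspring_ids),
            name=self.name,
        )


@dataclass
class MarkerMeta:
    """Per-marker metadata: origin fragment/contig and array-design score."""

    marker_id: str
    contig_id: str
    source_tag: str = "in_vitro"
    designability_score: float = 1.0
    position_in_fragment: int = 0

    def __post_init__(self) -> None:
        if not self.contig_id:
            raise FormatError(f"marker {self.marker_id}: empty contig_id")
        if not 0.0 <= self.designability_score <= 1.0:
            raise FormatError(
                f"marker {self.marker_id}: designability score "
                f"{self.designability_score} outside [0,1]"
            )
        if self.source_tag not in ("in_vitro", "in_silico"):
            raise FormatError(
                f"marker {self.marker_id}: bad source_tag {self.source_tag!r}"
            )


@dataclass
class SimilarityHit:
    """One row of a 12-column tabular (outfmt-6 style) similarity search."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    query_length: int
    subject_length: int
    e_value: float = 0.0
    bit_score: float = 0.0
    query_cov: float = field(default=0.0)
    subject_cov: float = field(default=0.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise FormatError(
                f"hit {self.query_id}/{self.subject_id}: identity "
                f"{self.percent_identity} outside [0,100]"
            )
        if self.query_cov == 0.0 and self.query_length > 0:
            self.query_cov = min(1.0, self.alignment_length / self.query_length)
        if self.subject_cov == 0.0 and self.subject_length > 0:
            self.subject_cov = min(1.0, self.alignment_length / self.subject_length)
        for name, cov in (("query_cov", self.query_cov), ("subject_cov", self.subject_cov)):
            if not 0.0 <= cov <= 1.0:
                raise FormatError(
                    f"hit {self.query_id}/{self.subject_id}: {name} {cov} outside [0,1]"
                )

    @property
    def is_self_hit(self) -> bool:
        return self.query_id == self.subject_id


@dataclass
class LinkageGroup:
    label: str
    framework: list[tuple[str, float]]  # (marker_id, position_cM), ordered
    accessory: list[tuple[str, str, float, float]] = field(default_factory=list)
    # accessory rows: (marker_id, anchor_marker_id, two_point_rf, two_point_lod)

    def __post_init__(self) -> None:
        pos = [p for _, p in self.framework]
        if pos:
            if pos[0] != 0.0:
                raise FormatError(f"group {self.label}: first position must be 0")
            if any(b < a for a, b in zip(pos, pos[1:])):
                raise FormatError(f"group {self.label}: positions not non-decreasing")
        fw = {m for m, _ in self.framework}
        for m, anchor, rf, lod in self.accessory:
            if anchor not in fw:
                raise FormatError(
                    f"group {self.label}: accessory {m} anchored at {anchor}, "
                    "not a framework marker of this group"
                )

    @property
    def length_cM(self) -> float:
        return self.framework[-1][1] if self.framework else 0.0

    @property
    def marker_ids(self) -> list[str]:
        return [m for m, _ in self.framework] + [a[0] for a in self.accessory]


@dataclass
class LinkageMapModel:
    """Grouped, ordered markers with cM positions and framework status."""

    groups: list[LinkageGroup]

    @property
    def n_markers(self) -> int:
        return sum(len(g.framework) + len(g.accessory) for g in self.groups)

    @property
    def total_length_cM(self) -> float:
        return sum(g.length_cM for g in self.groups)


# ---------------------------------------------------------------------------
# genotype files
# ---------------------------------------------------------------------------

def read_genotypes(path, pedigree_type: str | None = None) -> GenotypeMatrix:
    """Read a JoinMap-style ``.loc`` genotype file.

    The header must declare ``popt`` (CP or F2), ``nloc`` and ``nind``.
    If *pedigree_type* is given it must match the header.
    """
    with open(path) as fh:
        text = fh.read()
    return loads_genotypes(text, pedigree_type)


def loads_genotypes(text: str, pedigree_type: str | None = None) -> GenotypeMatrix:
    header: dict[str, str] = {}
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line or line.startswith(";"):
            continue
        if "=" in line:
            key, _, val = line.partition("=")
            header[key.strip().lower()] = val.strip()
        else:
            i -= 1
            break
    for key in ("popt", "nloc", "nind"):
        if key not in header:
            raise FormatError(f"missing header field {key!r}")
    popt = header["popt"].upper()
    if popt not in ("CP", "F2"):
        raise FormatError(f"unsupported population type {header['popt']!r}")
    if pedigree_type is not None and popt != pedigree_type:
        raise FormatError(
            f"file declares population type {popt}, expected {pedigree_type}"
        )
    try:
        nloc, nind = int(header["nloc"]), int(header["nind"])
    except ValueError as exc:
        raise FormatError(f"non-integer nloc/nind: {exc}") from exc

    miss = MISSING[popt]
    marker_ids: list[str] = []
    seg_codes: list[str] = []
    calls: list[list[str]] = []
    offspring_ids: list[str] = []
    in_individuals = False
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line or line.startswith(";"):
            continue
        if line.lower().startswith("individual names"):
            in_individuals = True
            continue
        if in_individuals:
            offspring_ids.append(line)
            continue
        toks = line.split()
        name = toks[0]
        code = F2_CODE
        rest = toks[1:]
        if rest and rest[0].startswith("<") and rest[0].endswith(">"):
            code = rest[0][1:-1]
            rest = rest[1:]
        if popt == "CP" and code == F2_CODE:
            raise FormatError(f"marker {name}: CP locus lacks segregation code")
        row = list(rest)
        while len(row) < nind and i < len(lines):
            nxt = lines[i].strip()
            if not nxt or nxt.startswith(";"):
                i += 1
                continue
            row.extend(nxt.split())
            i += 1
        if len(row) != nind:
            raise FormatError(
                f"marker {name}: {len(row)} calls, header declares nind={nind}"
            )
        row = [miss if c == "." else c for c in row]
        marker_ids.append(name)
        seg_codes.append(code)
        calls.append(row)
    if len(marker_ids) != nloc:
        raise FormatError(
            f"{len(marker_ids)} loci found, header declares nloc={nloc}"
        )
    if not offspring_ids:
        offspring_ids = [f"ind{j + 1}" for j in range(nind)]
    if len(offspring_ids) != nind:
        raise FormatError(
            f"{len(offspring_ids)} individual names, header declares nind={nind}"
        )
    return GenotypeMatrix(
        pedigree_type=popt,
        marker_ids=marker_ids,
        seg_codes=seg_codes,
        calls=calls,
        offspring_ids=offspring_ids,
        name=header.get("name", "pop"),
    )


def dumps_genotypes(matrix: GenotypeMatrix) -> str:
    out = io.StringIO()
    out.write(f"name = {matrix.name}\n")
    out.write(f"popt = {matrix.pedigree_type}\n")
    out.write(f"nloc = {matrix.n_markers}\n")
    out.write(f"nind = {matrix.n_offspring}\n\n")
    for mid, code, row in zip(matrix.marker_ids, matrix.seg_codes, matrix.calls):
        tag = "" if matrix.pedigree_type == "F2" else f" <{code}>"
        out.write(f"{mid}{tag} " + " ".join(row) + "\n")
    out.write("\nindividual names:\n")
    for ind in matrix.offspring_ids:
        out.write(ind + "\n")
    return out.getvalue()


def write_genotypes(matrix: GenotypeMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(dumps_genotypes(matrix))


# ---------------------------------------------------------------------------
# aligned fragments (FASTA + quality sidecar)
# ---------------------------------------------------------------------------

def read_fragments(fasta_path, qual_path=None) -> list[AlignedFragment]:
    """Read aligned fragments from FASTA.

    Record ids follow ``<fragment_id>|<sequence_id>``; consecutive records
    sharing a fragment_id form one alignment.  The optional quality sidecar
    mirrors the FASTA: ``>`` header lines followed by whitespace-separated
    Phred scores (one per alignment cell, -1 for gap cells).
    """
    quals: dict[str, list[int]] = {}
    if qual_path is not None:
        current = None
        with open(qual_path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line:
                    continue
                if line.startswith(">"):
                    current = line[1:].split()[0]
                    quals[current] = []
                else:
                    if current is None:
                        raise FormatError(
                            f"{qual_path}:{lineno}: scores before any header"
                        )
                    try:
                        quals[current].extend(int(tok) for tok in line.split())
                    except ValueError as exc:
                        raise FormatError(
                            f"{qual_path}:{lineno}: non-integer score ({exc})"
                        ) from exc

    frag_order: list[str] = []
    frag_seqs: dict[str, list[tuple[str, str]]] = {}
    frag_tags: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if "|" in rec.id:
            fid, sid = rec.id.split("|", 1)
        else:
            fid, sid = rec.id, rec.id
        if fid not in frag_seqs:
            frag_order.append(fid)
            frag_seqs[fid] = []
            tag = "in_vitro"
            for tok in rec.description.split():
                if tok.startswith("source="):
                    tag = tok.split("=", 1)[1]
            frag_tags[fid] = tag
        frag_seqs[fid].append((rec.id, str(rec.seq).upper()))

    fragments = []
    for fid in frag_order:
        seqs = [s for _, s in frag_seqs[fid]]
        qmat = None
        if quals:
            qmat = []
            for rid, s in frag_seqs[fid]:
                if rid not in quals:
                    raise FormatError(f"no quality scores for sequence {rid}")
                q = quals[rid]
                if len(q) != len(s):
                    raise FormatError(
                        f"sequence {rid}: {len(q)} scores for {len(s)} columns"
                    )
                qmat.append(q)
        fragments.append(
            AlignedFragment(fid, seqs, qmat, source_tag=frag_tags[fid])
        )
    return fragments


def write_fragments(fragments: Iterable[AlignedFragment], fasta_path, qual_path=None):
    frags = list(fragments)
    records = []
    for frag in frags:
        for i, s in enumerate(frag.sequences):
            records.append(
                SeqRecord(
                    Seq(s),
                    id=f"{frag.fragment_id}|s{i}",
                    description=f"source={frag.source_tag}",
                )
            )
    SeqIO.write(records, str(fasta_path), "fasta")
    if qual_path is not None:
        with open(qual_path, "w") as fh:
            for frag in frags:
                if frag.qualities is None:
                    continue
                for i, q in enumerate(frag.qualities):
                    fh.write(f">{frag.fragment_id}|s{i}\n")
                    fh.write(" ".join(str(x) for x in q) + "\n")


# ---------------------------------------------------------------------------
# similarity hits (tabular BLAST, outfmt-6 column order)
# ---------------------------------------------------------------------------

def read_similarity_hits(path, lengths: dict[str, int] | None = None) -> list[SimilarityHit]:
    """Read a 12-column tabular similarity file (BLAST outfmt 6).

    Columns: query, subject, %identity, alignment length, mismatches,
    gap opens, qstart, qend, sstart, send, evalue, bitscore.  Optional
    columns 13-14 are query and subject lengths; otherwise *lengths*
    supplies them (ids absent from *lengths* get length 0, coverage 0).
    Self-hits are retained (callers filter them).
    """
    hits: list[SimilarityHit] = []
    lengths = lengths or {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < 12:
                raise FormatError(f"{path}:{lineno}: expected >=12 columns, got {len(cols)}")
            try:
                ident = float(cols[2])
                alen = int(cols[3])
                evalue = float(cols[10])
                bits = float(cols[11])
                qlen = int(cols[12]) if len(cols) > 12 else lengths.get(cols[0], 0)
                slen = int(cols[13]) if len(cols) > 13 else lengths.get(cols[1], 0)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric field ({exc})") from exc
            hits.append(
                SimilarityHit(
                    query_id=cols[0],
                    subject_id=cols[1],
                    percent_identity=ident,
                    alignment_length=alen,
                    query_length=qlen,
                    subject_length=slen,
                    e_value=evalue,
                    bit_score=bits,
                )
            )
    return hits


# ---------------------------------------------------------------------------
# linkage-map files
# ---------------------------------------------------------------------------

def write_map(model: LinkageMapModel, path) -> None:
    """Write a map as TSV: group, marker, cM, status[, anchor, rf, lod]."""
    with open(path, "w") as fh:
        fh.write("group\tmarker\tposition_cM\tstatus\tanchor\trf\tlod\n")
        for g in model.groups:
            for m, pos in g.framework:
                fh.write(f"{g.label}\t{m}\t{pos:.4f}\tframework\t.\t.\t.\n")
            for m, anchor, rf, lod in g.accessory:
                fh.write(
                    f"{g.label}\t{m}\t.\taccessory\t{anchor}\t{rf:.4f}\t{lod:.2f}\n"
                )


def read_map(path) -> LinkageMapModel:
    groups: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("group\t"):
            raise FormatError(f"{path}: missing map header line")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != 7:
                raise FormatError(f"{path}:{lineno}: expected 7 columns")
            label, marker, pos, status = cols[0], cols[1], cols[2], cols[3]
            if label not in groups:
                groups[label] = {"framework": [], "accessory": []}
                order.append(label)
            if status == "framework":
                try:
                    groups[label]["framework"].append((marker, float(pos)))
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: bad position ({exc})") from exc
            elif status == "accessory":
                try:
                    groups[label]["accessory"].append(
                        (marker, cols[4], float(cols[5]), float(cols[6]))
                    )
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: bad accessory row ({exc})") from exc
            else:
                raise FormatError(f"{path}:{lineno}: unknown status {status!r}")
    return LinkageMapModel(
        groups=[
            LinkageGroup(label, groups[label]["framework"], groups[label]["accessory"])
            for label in order
        ]
    )
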