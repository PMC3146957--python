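"""End-to-end pipeline wiring: simulate -> discover -> design-array ->
qc -> two-point -> maps -> consensus -> genome stats -> COS.

Every stage writes plain-text artifacts into an output directory and
the run ends with a manifest listing each file with its SHA-256, so a
rerun under the same configuration is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import consensus as consensus_mod
from . import cos as cos_mod
from . import discovery, genome, linkage, qc, simulate
from .formats import write_fragments, write_genotypes, write_map

log = logging.getLogger("pinemap")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "pinemap_out"
    # simulation (study-shaped defaults)
    n_groups: int = 12
    genome_cM: float = 2500.0
    n_markers: int = 120
    contig_multiplicity: int = 2
    n_offspring: int = 90
    error_rate: float = 0.004
    missing_rate: float = 0.02
    # discovery / array design
    phred_threshold: int = 30
    min_depth: int = 4
    min_score: float = 0.4
    min_spacing_nt: int = 60
    ld_threshold: float = 0.9
    per_gene_cap: int = 2
    # linkage
    lod_threshold: float = 3.0
    gof_jump_threshold: float = 5.0
    # cos
    mcl_inflation: float = 2.0
    min_cov: float = 0.60
    min_identity: float = 80.0
    log_level: str = "INFO"

    def validate(self) -> None:
        checks = [
            ("lod_threshold", self.lod_threshold >= 0),
            ("gof_jump_threshold", self.gof_jump_threshold >= 0),
            ("error_rate", 0 <= self.error_rate <= 1),
            ("missing_rate", 0 <= self.missing_rate <= 1),
            ("min_score", 0 <= self.min_score <= 1),
            ("ld_threshold", 0 <= self.ld_threshold <= 1),
            ("min_cov", 0 <= self.min_cov <= 1),
            ("min_identity", 0 <= self.min_identity <= 100),
            ("mcl_inflation", self.mcl_inflation > 1),
            ("n_markers", self.n_markers >= 2),
            ("n_offspring", self.n_offspring >= 1),
        ]
        bad = [name for name, ok in checks if not ok]
        if bad:
            raise PipelineError("config", f"invalid value(s) for: {', '.join(bad)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise PipelineError("config", f"unknown key(s): {', '.join(sorted(unknown))}")
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in dependency order; returns the manifest."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []

    def emit(path: Path):
        artifacts.append(path)
        log.info("wrote %s", path)

    sim_cfg = simulate.SimulationConfig(
        seed=config.seed,
        n_offspring=config.n_offspring,
        error_rate=config.error_rate,
        missing_rate=config.missing_rate,
    )

    stage = "simulate"
    try:
        genome_truth = simulate.simulate_genome(
            sim_cfg,
            n_groups=config.n_groups,
            group_lengths_cM=[config.genome_cM / config.n_groups] * config.n_groups,
            n_markers=config.n_markers,
            contig_multiplicity=config.contig_multiplicity,
        )
        cp = simulate.simulate_cross(genome_truth, sim_cfg, "CP")
        f2 = simulate.simulate_cross(genome_truth, sim_cfg, "F2")
        write_genotypes(cp, out / "cp.loc")
        write_genotypes(f2, out / "f2.loc")
        emit(out / "cp.loc")
        emit(out / "f2.loc")
        with open(out / "truth.tsv", "w") as fh:
            fh.write("marker\tgroup\tpos_cM\tseg_type\tcontig\n")
            for i, m in enumerate(genome_truth.marker_ids):
                fh.write(
                    f"{m}\t{genome_truth.group_of[i]}\t"
                    f"{genome_truth.pos_cM[i]:.4f}\t{genome_truth.seg_type[i]}\t"
                    f"{genome_truth.contig_of[i]}\n"
                )
        emit(out / "truth.tsv")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    stage = "discover-snps"
    try:
        fragments, _ = simulate.simulate_fragments(config.seed)
        write_fragments(fragments, out / "fragments.fasta", out / "fragments.qual")
        emit(out / "fragments.fasta")
        emit(out / "fragments.qual")
        records = []
        frag_by_id = {}
        for frag in fragments:
            masked = discovery.mask_low_quality(frag, config.phred_threshold)
            frag_by_id[frag.fragment_id] = masked
            records.extend(
                discovery.detect_polymorphisms(masked, min_depth=config.min_depth)
            )
        with open(out / "candidates.tsv", "w") as fh:
            fh.write("marker\tfragment\tcolumn\ttype\tdepth\tminor\tmaf\n")
            for rec in records:
                fh.write(
                    f"{rec.marker_id}\t{rec.fragment_id}\t{rec.column}\t{rec.type}"
                    f"\t{rec.detection_depth}\t{rec.minor_count}\t{rec.maf:.4f}\n"
                )
        emit(out / "candidates.tsv")
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    stage = "design-array"
    try:
        from .formats import MarkerMeta

        meta = {
            rec.marker_id: MarkerMeta(
                marker_id=rec.marker_id,
                contig_id=rec.fragment_id,
                designability_score=discovery.surrogate_design_score(
                    frag_by_id[rec.fragment_id], rec.column
                ),
                position_in_fragment=rec.column,
            )
            for rec in records
        }
        selected, rejections = discovery.select_for_array(
            records,
            meta,
            fragments=frag_by_id,
            min_score=config.min_score,
            min_spacing_nt=config.min_spacing_nt,
            ld_threshold=config.ld_threshold,
            per_gene_cap=config.per_gene_cap,
        )
        with open(out / "selection.tsv", "w") as fh:
            fh.write("marker\tstatus\trule\n")
            for rec in selected:
                fh.write(f"{rec.marker_id}\tselected\t.\n")
            for rej in rejections:
                fh.write(f"{rej.record.marker_id}\trejected\t{rej.rule}\n")
        emit(out / "selection.tsv")
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    stage = "qc"
    try:
        marker_meta = genome_truth.marker_meta()
        summary = qc.qc_summary(cp, marker_meta)
        err = qc.estimate_error_rate(cp, marker_meta)
        with open(out / "qc.tsv", "w") as fh:
            fh.write("metric\tvalue\n")
            fh.write(f"n_total\t{summary.n_total}\n")
            fh.write(f"n_failed\t{summary.n_failed}\n")
            fh.write(f"n_monomorphic\t{summary.n_monomorphic}\n")
            fh.write(f"n_polymorphic\t{summary.n_polymorphic}\n")
            fh.write(f"success_rate\t{summary.success_rate:.4f}\n")
            fh.write(f"conversion_rate\t{summary.conversion_rate:.4f}\n")
            fh.write(f"error_events\t{err.events}\n")
            fh.write(f"error_data_points\t{err.data_points}\n")
            fh.write(f"error_rate_percent\t{err.rate_percent_1dp}\n")
        emit(out / "qc.tsv")
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    stage = "map-two-point"
    try:
        female, male, _ = linkage.split_pseudo_testcross(cp)
        table_f = linkage.two_point_table(cp, female)
        table_m = linkage.two_point_table(cp, male)
        table_f2 = linkage.two_point_table(f2)
        with open(out / "two_point_f2.tsv", "w") as fh:
            fh.write("marker_a\tmarker_b\tr\tlod\n")
            ids = table_f2.marker_ids
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    fh.write(
                        f"{ids[i]}\t{ids[j]}\t{table_f2.r[i, j]:.4f}"
                        f"\t{table_f2.lod[i, j]:.2f}\n"
                    )
        emit(out / "two_point_f2.tsv")
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    stage = "build-map"
    try:
        for name, tbl in (("female", table_f), ("male", table_m), ("f2", table_f2)):
            model = linkage.build_map(
                tbl, config.lod_threshold, config.gof_jump_threshold
            )
            write_map(model, out / f"map_{name}.tsv")
            emit(out / f"map_{name}.tsv")
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    stage = "consensus"
    try:
        # shared markers: those informative in both pedigrees (hkxhk in CP)
        report = consensus_mod.build_consensus(
            cp,
            f2,
            lod_threshold=config.lod_threshold,
            gof_jump_threshold=config.gof_jump_threshold,
            heterogeneity_pairs=200,
        )
        write_map(report.model, out / "map_consensus.tsv")
        emit(out / "map_consensus.tsv")
        with open(out / "heterogeneity.tsv", "w") as fh:
            fh.write("marker_a\tmarker_b\tr1\tr2\tpooled_r\tstatistic\tp\tsignificant\n")
            for h in report.heterogeneity:
                fh.write(
                    f"{h.marker_a}\t{h.marker_b}\t{h.r1:.4f}\t{h.r2:.4f}"
                    f"\t{h.pooled_r:.4f}\t{h.statistic:.3f}\t{h.p_value:.4g}"
                    f"\t{h.significant}\n"
                )
        emit(out / "heterogeneity.tsv")
    except consensus_mod.MergeError:
        log.warning("consensus skipped: no shared markers")
        report = None
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    stage = "genome-stats"
    try:
        stats_rows = []
        for z in (3.0, 4.0, 5.0):
            try:
                est = genome.genome_length_method3(table_f2, table_f2.marker_ids, z)
                stats_rows.append((z, est))
            except genome.EstimateUndefinedError:
                continue
        cov = genome.coverage_proportion(4.0, config.n_markers, config.genome_cM)
        with open(out / "genome_stats.tsv", "w") as fh:
            fh.write("stat\tz\tvalue\n")
            for z, est in stats_rows:
                fh.write(f"G_cM\t{z}\t{est.G:.1f}\n")
            fh.write(f"coverage_d4\t.\t{cov:.4f}\n")
            fh.write(
                f"markers_for_95pct_c10\t.\t"
                f"{genome.markers_needed(0.95, 10, config.genome_cM)}\n"
            )
        emit(out / "genome_stats.tsv")
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    stage = "cos"
    try:
        pine, spruce, within, cross, _ = simulate.simulate_cos_universe(config.seed)
        within_f = cos_mod.filter_cos_hits(within, config.min_cov, config.min_identity)
        graph = cos_mod.hits_to_graph(within_f, all_ids=pine + spruce)
        clusters = cos_mod.mcl_cluster(graph, inflation=config.mcl_inflation)
        pine_single = cos_mod.identify_singletons(pine, clusters)
        spruce_single = cos_mod.identify_singletons(spruce, clusters)
        cross_f = cos_mod.filter_cos_hits(cross, config.min_cov, config.min_identity)
        joined = sorted(pine_single | spruce_single)
        cross_graph = cos_mod.hits_to_graph(
            [h for h in cross_f if h.query_id in set(joined) and h.subject_id in set(joined)],
            all_ids=joined,
        )
        cross_clusters = cos_mod.mcl_cluster(cross_graph, inflation=config.mcl_inflation)
        families = cos_mod.identify_cos(pine_single, spruce_single, cross_clusters)
        with open(out / "cos_families.tsv", "w") as fh:
            fh.write("family\tis_cos\tpine_members\tspruce_members\n")
            for fam in families:
                fh.write(
                    f"{fam.family_id}\t{fam.is_cos}\t"
                    f"{','.join(fam.pine_members) or '.'}\t"
                    f"{','.join(fam.spruce_members) or '.'}\n"
                )
        emit(out / "cos_families.tsv")
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    manifest = {
        "seed": config.seed,
        "config": asdict(config),
        "artifacts": {p.name: _sha256(p) for p in artifacts},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
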