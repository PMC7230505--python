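"""End-to-end orchestration: annotations -> counts -> shift -> DE -> integration.

Every stage reads and writes plain tab-separated artifacts so any stage can
be rerun standalone from the previous stage's on-disk output. A manifest
(JSON) records the package version, a hash of the configuration, and a
checksum per emitted file; a rerun with an identical configuration and seed
is byte-identical for the deterministic stages. A failed stage leaves its
partial outputs in place next to a FAILED marker file.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotation import (
    build_exon_annotation,
    build_intergenic_annotation,
    build_intron_annotation,
    parse_gene_gtf,
    parse_repeat_annotation,
    read_chrom_sizes,
    read_gtf_annotation,
    write_gtf,
)
from .de import aggregate_repeat_classes, filter_low_expression, nb_test
from .integrate import (
    context_table,
    full_length_line1_de,
    gene_set_overlap,
    intersect_de_repeats_with_de_introns,
    locate_repeats,
    read_gene_set,
)
from .quantify import CompartmentSummary, build_count_matrix, load_fragments, summarize_compartments
from .report import compartment_report, write_report
from .shift import PairedDesign, summarize_design, shift_table

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full run."""

    genes: str
    repeats: str
    chrom_sizes: str
    design: str
    fragments: dict  # sample_id -> path (BED or SAM/BAM)
    out_dir: str
    gene_sets: dict = field(default_factory=dict)  # set name -> id-list path
    l1_annotation: str | None = None
    min_fpkm: float = 5.0
    min_fraction: float = 0.8
    lfc: float = 1.0
    q: float = 0.05
    sidedness: str = "one-sided"
    strand_aware: bool = False
    min_mapq: int = 30

    def __post_init__(self) -> None:
        for name, v in (("min_fpkm", self.min_fpkm), ("lfc", self.lfc), ("q", self.q),
                        ("min_fraction", self.min_fraction)):
            if v <= 0:
                raise ValueError(f"threshold {name} must be positive, got {v}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def build_annotations(config: PipelineConfig, out: Path) -> dict[str, Path]:
    genes = parse_gene_gtf(config.genes)
    sizes = read_chrom_sizes(config.chrom_sizes)
    anns = {
        "exons": build_exon_annotation(genes),
        "introns": build_intron_annotation(genes, strand_aware=config.strand_aware),
        "intergenic": build_intergenic_annotation(genes, sizes),
        "repeats": parse_repeat_annotation(config.repeats),
    }
    paths = {}
    for name, ann in anns.items():
        p = out / f"{name}.gtf"
        write_gtf(ann, p)
        paths[name] = p
    return paths


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the run directory.

    Stage order: build-annotations -> count -> summarize/shift -> de (exon,
    intron, repeats, full-length L1) -> integrate -> report.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config_hash": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True).encode()
        ).hexdigest(),
        "stages": {},
    }
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    try:
        _run_stages(config, out, manifest)
    except Exception as exc:
        failed_marker.write_text(f"{type(exc).__name__}: {exc}\n")
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        raise
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out


def _record(manifest: dict, stage: str, paths) -> None:
    manifest["stages"][stage] = {
        str(Path(p).name): _sha256(Path(p)) for p in paths
    }


def _run_stages(config: PipelineConfig, out: Path, manifest: dict) -> None:
    # annotations
    ann_paths = build_annotations(config, out)
    _record(manifest, "build-annotations", ann_paths.values())
    exon_ann = read_gtf_annotation(ann_paths["exons"], "exon")
    intron_ann = read_gtf_annotation(ann_paths["introns"], "intron")
    repeat_ann = parse_repeat_annotation(ann_paths["repeats"], dialect="gtf")
    genes = parse_gene_gtf(config.genes)

    # fragments + counts
    design = PairedDesign.from_tsv(config.design)
    fragment_sets = []
    for cond in ("T0", "T1"):
        for sid in design.sample_ids(cond):
            if sid not in config.fragments:
                raise KeyError(f"no fragment file configured for design sample {sid!r}")
            fs = load_fragments(
                config.fragments[sid], sample_id=sid, condition=cond, min_mapq=config.min_mapq
            )
            fs.subject_id = next(s for s, m in design.samples.items() if m[cond] == sid)
            fragment_sets.append(fs)
    count_paths = []
    matrices = {}
    for name, ann, key in (
        ("exon", exon_ann, "gene_id"),
        ("intron", intron_ann, "gene_id"),
        ("repeat", repeat_ann, "feature_id"),
    ):
        cm = build_count_matrix(fragment_sets, ann, group_by=key)
        p = out / f"counts_{name}.tsv"
        cm.to_tsv(p)
        matrices[name] = cm
        count_paths.append(p)
    _record(manifest, "count", count_paths)

    # summary + shift
    rows = [summarize_compartments(fs, exon_ann, intron_ann, repeat_ann) for fs in fragment_sets]
    summary = CompartmentSummary.from_rows(rows)
    summary.to_tsv(out / "compartment_summary.tsv")
    results = summarize_design(summary, design, sidedness=config.sidedness)
    shift_table(results).to_csv(out / "shift.tsv", sep="\t", index=False)
    write_report(compartment_report(summary, design, results), out / "table2_report.tsv")
    _record(manifest, "shift",
            [out / "compartment_summary.tsv", out / "shift.tsv", out / "table2_report.tsv"])

    # differential expression per compartment
    de_tables = {}
    de_paths = []
    for name, cm in matrices.items():
        filtered = filter_low_expression(cm, config.min_fpkm, config.min_fraction)
        logger.info("%s DE: %d of %d features pass the expression filter",
                    name, len(filtered.counts), len(cm.counts))
        if len(filtered.counts) == 0:
            de = pd.DataFrame(columns=["feature_id", "base_mean", "log2FC",
                                       "p_value", "q_value", "call"])
        else:
            de = nb_test(filtered, design, lfc_threshold=config.lfc, alpha=config.q)
        de_tables[name] = de
        p = out / f"de_{name}.tsv"
        de.to_csv(p, sep="\t", index=False)
        de_paths.append(p)
    rep_classes = {
        iv.feature_id: iv.attributes.get("repeat_class", "Unknown")
        for iv in repeat_ann.features
    }
    class_summary = aggregate_repeat_classes(de_tables["repeat"], rep_classes)
    class_summary.table.to_csv(out / "repeat_class_summary.tsv", sep="\t", index=False)
    de_paths.append(out / "repeat_class_summary.tsv")
    _record(manifest, "de", de_paths)

    # integration
    rep_by_id = {iv.feature_id: iv for iv in repeat_ann.features}
    mod_reps = [
        rep_by_id[f] for f in de_tables["repeat"].loc[
            de_tables["repeat"]["call"].isin(("UP", "DOWN")), "feature_id"
        ] if f in rep_by_id
    ]
    mod_gene_ids = set(
        de_tables["exon"].loc[de_tables["exon"]["call"].isin(("UP", "DOWN")), "feature_id"]
    )
    contexts = locate_repeats(mod_reps, genes, intron_ann, mod_gene_ids, exon_ann)
    context_table(contexts).to_csv(out / "repeat_context.tsv", sep="\t", index=False)

    intron_by_key = {}
    for iv in intron_ann.features:
        intron_by_key.setdefault(iv.attributes.get("gene_id", iv.feature_id), []).append(iv)
    mod_intron_keys = set(
        de_tables["intron"].loc[de_tables["intron"]["call"].isin(("UP", "DOWN")), "feature_id"]
    )
    mod_introns = [iv for k in mod_intron_keys for iv in intron_by_key.get(k, [])]
    matches, match_hosts = intersect_de_repeats_with_de_introns(mod_reps, mod_introns)
    matches.to_csv(out / "repeat_intron_matches.tsv", sep="\t", index=False)
    (out / "matched_intron_host_genes.txt").write_text("".join(g + "\n" for g in match_hosts))

    integrate_paths = [out / "repeat_context.tsv", out / "repeat_intron_matches.tsv",
                       out / "matched_intron_host_genes.txt"]
    if config.gene_sets:
        overlap_rows = []
        deg_exon = mod_gene_ids
        deg_intron = {g for k in mod_intron_keys for g in str(k).split(",")}
        for name, path in sorted(config.gene_sets.items()):
            ov = gene_set_overlap(deg_exon, deg_intron, read_gene_set(path), set_name=name)
            overlap_rows.append(asdict(ov))
        pd.DataFrame(overlap_rows).to_csv(out / "gene_set_overlap.tsv", sep="\t", index=False)
        integrate_paths.append(out / "gene_set_overlap.tsv")
    if config.l1_annotation:
        l1_ann = read_gtf_annotation(config.l1_annotation, "repeat")
        l1_de = full_length_line1_de(
            matrices["repeat"], design, l1_ann,
            config.min_fpkm, config.min_fraction, config.lfc, config.q,
        )
        l1_de.to_csv(out / "de_l1_full.tsv", sep="\t", index=False)
        integrate_paths.append(out / "de_l1_full.tsv")
    _record(manifest, "integrate", integrate_paths)
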