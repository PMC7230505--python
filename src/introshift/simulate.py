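"""Synthetic genomes, annotations, fragments and counts with known truth.

The generator emulates the structure of the study this pipeline targets:
five subjects sampled at rest (T0) and immediately post-race (T1), fragments
distributed over exon / intron / repeat / intergenic space with
condition-specific mixing proportions (defaults: exon 56.3% -> 53.4%, intron
23.2% -> 27.6%, repeat 14.3% -> 15.8%), repeats nested inside introns and in
intergenic space with LINE/SINE/LTR/DNA class labels, a configured fraction
of overlapping gene pairs, a handful of full-length (>= 6 kb) LINE-1 loci,
and negative-binomial feature counts with a designated differentially
expressed subset at |log2FC| >= 1.

Fragments are generated directly as genomic intervals (BED), not reads:
alignment is outside this package's scope, so simulating sequencers would
exercise nothing the pipeline implements. A single integer seed drives a
hierarchical generator (numpy SeedSequence spawns per stage), so each stage
is reproducible independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .annotation import (
    CompartmentAnnotation,
    GeneModel,
    GenomicInterval,
    build_exon_annotation,
    build_intergenic_annotation,
    build_intron_annotation,
    merge_intervals,
    subtract_intervals,
    write_chrom_sizes,
    write_gtf,
)
from .quantify import CountMatrix, FragmentSet
from .shift import PairedDesign

REPEAT_CLASSES = ("LINE", "SINE", "LTR", "DNA")

# per-class (family, placement weight, length range); weights roughly follow
# the modulated-class mix reported for mammalian PBMC transcriptomes
# (LINE ~47%, SINE ~24%, DNA ~12%, LTR ~9%)
_CLASS_SPECS = {
    "LINE": {"family": "L1", "weight": 0.47, "length": (400, 2000)},
    "SINE": {"family": "ERE1", "weight": 0.24, "length": (150, 350)},
    "DNA": {"family": "hAT-Charlie", "weight": 0.12, "length": (200, 600)},
    "LTR": {"family": "ERVL", "weight": 0.09, "length": (300, 900)},
}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults mirror the study shape."""

    seed: int = 0
    n_subjects: int = 5
    sequence_lengths: dict = field(
        default_factory=lambda: {"chr1": 100_000, "chr2": 100_000, "chr3": 100_000}
    )
    n_genes: int = 36
    overlapping_gene_fraction: float = 0.1
    exons_per_gene: tuple = (3, 7)
    gene_length: tuple = (2_000, 5_000)
    gene_gap: tuple = (1_000, 3_500)
    repeats_per_kb: float = 0.5  # placement rate in eligible intronic/intergenic space
    intronic_repeat_share: float = 0.6  # of placed repeats, fraction going into introns
    full_length_l1_count: int = 3
    full_length_l1_length: tuple = (6_000, 7_000)
    fragments_per_sample: int = 50_000
    fragment_length: int = 150
    # observed-assignment targets per condition (fraction of fragments
    # overlapping each compartment's annotation)
    t0_proportions: dict = field(
        default_factory=lambda: {"exon": 0.563, "intron": 0.232, "repeat": 0.143}
    )
    t1_proportions: dict = field(
        default_factory=lambda: {"exon": 0.534, "intron": 0.276, "repeat": 0.158}
    )
    repeat_draw_intronic_fraction: float = 0.6  # of repeat-compartment draws
    subject_jitter_sd: float = 0.010  # shared T0/T1 per-subject offset, proportion scale
    sample_noise_sd: float = 0.005  # independent per-sample noise, proportion scale
    de_fraction: float = 0.10
    de_log2fc_choices: tuple = (1.0, 1.5, 2.0, 2.5)
    nb_dispersion: float = 0.1
    baseline_log_mean: float = float(np.log(100.0))
    baseline_log_sd: float = 1.0
    size_factor_log_sd: float = 0.1

    def validate(self) -> None:
        for name, props in (("t0", self.t0_proportions), ("t1", self.t1_proportions)):
            for comp, p in props.items():
                if not 0 <= p <= 1:
                    raise ValueError(f"{name} proportion for {comp} outside [0,1]: {p}")
            if props["intron"] < self.repeat_draw_intronic_fraction * props["repeat"]:
                raise ValueError(
                    f"{name}: intron proportion smaller than the intronic share of "
                    "repeat draws; lower repeat_draw_intronic_fraction"
                )
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        for k, v in data.items():
            if isinstance(v, tuple):
                data[k] = [float(x) if isinstance(x, float) else int(x) for x in v]
            elif isinstance(v, np.floating):
                data[k] = float(v)
            elif isinstance(v, np.integer):
                data[k] = int(v)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class GroundTruth:
    """What the generator actually did, for oracle-style assertions."""

    feature_truth: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: feature_id, compartment, repeat_class, true_log2fc
    fragment_counts: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: sample_id, category, n_fragments

    def to_tsv(self, path: str | Path) -> None:
        self.feature_truth.to_csv(path, sep="\t", index=False)


@dataclass
class SimulatedAnnotation:
    genes: list
    repeat_annotation: CompartmentAnnotation
    l1_annotation: CompartmentAnnotation
    sequence_lengths: dict
    truth: GroundTruth


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(stage + 1)[stage])


# ---------------------------------------------------------------------------
# Annotation generation
# ---------------------------------------------------------------------------

def _place_genes(cfg: SimulationConfig, rng: np.random.Generator) -> list[GeneModel]:
    genes: list[GeneModel] = []
    chroms = sorted(cfg.sequence_lengths)
    per_chrom = int(np.ceil(cfg.n_genes / len(chroms)))
    gid = 0
    for chrom in chroms:
        length = cfg.sequence_lengths[chrom]
        cursor = int(rng.integers(500, 2000))
        placed = 0
        prev_span = None
        while placed < per_chrom and gid < cfg.n_genes:
            glen = int(rng.integers(*cfg.gene_length))
            overlap = (
                prev_span is not None
                and rng.random() < cfg.overlapping_gene_fraction
                and prev_span[1] - prev_span[0] > glen // 2 + 200
            )
            if overlap:
                start = int(rng.integers(prev_span[0] + 100, prev_span[1] - glen // 2))
            else:
                start = cursor
            end = start + glen
            if end > length - 500:
                break
            gene_id = f"GENE{gid:04d}"
            strand = "+" if rng.random() < 0.5 else "-"
            n_ex = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
            # 2*n_ex - 1 alternating exon/intron blocks, exons at both ends
            cuts = np.sort(rng.choice(np.arange(start + 50, end - 50), 2 * n_ex - 2, replace=False))
            bounds = np.concatenate([[start], cuts, [end]])
            exons = []
            for i in range(0, len(bounds) - 1, 2):
                s, e = int(bounds[i]), int(bounds[i + 1])
                if e > s:
                    exons.append(
                        GenomicInterval(chrom, s, e, strand, f"{gene_id}:ex{i // 2}",
                                        {"gene_id": gene_id})
                    )
            if not exons:
                continue
            span = GenomicInterval(chrom, start, end, strand, gene_id)
            genes.append(GeneModel(gene_id, span, exons, strand))
            gid += 1
            placed += 1
            prev_span = (start, end)
            cursor = max(cursor, end) + int(rng.integers(*cfg.gene_gap))
    if len(genes) < cfg.n_genes:
        raise ValueError(
            f"infeasible placement: fitted {len(genes)} of {cfg.n_genes} genes; "
            "genome too small for the requested gene number/lengths"
        )
    return genes


def _sample_positions_in(space: list[GenomicInterval], lengths: np.ndarray,
                         rng: np.random.Generator) -> list[tuple[str, int, int]]:
    """Place intervals of the given lengths uniformly in the space, nested
    entirely inside single space intervals; drops lengths that fit nowhere."""
    out = []
    for L in lengths:
        fits = [iv for iv in space if len(iv) >= L]
        if not fits:
            continue
        weights = np.array([len(iv) - L + 1 for iv in fits], dtype=float)
        iv = fits[rng.choice(len(fits), p=weights / weights.sum())]
        s = int(rng.integers(iv.start, iv.end - L + 1))
        out.append((iv.seq_id, s, s + int(L)))
    return out


def generate_annotation(config: SimulationConfig) -> SimulatedAnnotation:
    """Genes, repeats (intronic + intergenic), full-length L1s, and truth.

    Deterministic given config.seed. Repeats are nested entirely inside
    single intron or intergenic intervals. Raises when the genome cannot hold
    the requested gene count.
    """
    config.validate()
    rng = _stage_rng(config.seed, 0)
    genes = _place_genes(config, rng)
    intron_ann = build_intron_annotation(genes)
    intergenic_ann = build_intergenic_annotation(genes, config.sequence_lengths)

    classes = list(_CLASS_SPECS)
    weights = np.array([_CLASS_SPECS[c]["weight"] for c in classes])
    weights = weights / weights.sum()
    feats: list[GenomicInterval] = []
    truth_rows = []

    # full-length L1 loci go into intergenic space first so the large gaps
    # are still intact (the small repeats would fragment them)
    l1_feats = []
    l1_lengths = rng.integers(*config.full_length_l1_length, size=config.full_length_l1_count)
    placed = _sample_positions_in(list(intergenic_ann.features), np.asarray(l1_lengths), rng)
    if len(placed) < config.full_length_l1_count:
        raise ValueError(
            "infeasible placement: not enough intergenic space for "
            f"{config.full_length_l1_count} full-length L1 loci"
        )
    for seq, s, e in placed:
        fid = f"L1-full|{seq}:{s}-{e}"
        iv = GenomicInterval(
            seq, s, e, "+" if rng.random() < 0.5 else "-", fid,
            {"repeat_name": "L1-full", "repeat_class": "LINE", "repeat_family": "L1"},
        )
        feats.append(iv)
        l1_feats.append(iv)
        truth_rows.append(
            {"feature_id": fid, "compartment": "repeat", "repeat_class": "LINE",
             "location": "intergenic", "true_log2fc": 0.0}
        )
    free_intergenic = subtract_intervals(intergenic_ann.features, l1_feats)

    for location, space_ann, share in (
        ("intronic", intron_ann.features, config.intronic_repeat_share),
        ("intergenic", free_intergenic, 1 - config.intronic_repeat_share),
    ):
        kb = sum(len(iv) for iv in space_ann) / 1000.0
        n = rng.poisson(config.repeats_per_kb * kb * share)
        drawn_classes = rng.choice(classes, size=n, p=weights)
        lengths = np.array(
            [int(rng.integers(*_CLASS_SPECS[c]["length"])) for c in drawn_classes], dtype=int
        )
        placed = _sample_positions_in(list(space_ann), lengths, rng)
        for (seq, s, e), rclass in zip(placed, drawn_classes):
            spec = _CLASS_SPECS[rclass]
            name = f"{spec['family']}-{rclass}"
            fid = f"{name}|{seq}:{s}-{e}"
            feats.append(
                GenomicInterval(
                    seq, s, e, "+" if rng.random() < 0.5 else "-", fid,
                    {"repeat_name": name, "repeat_class": rclass,
                     "repeat_family": spec["family"]},
                )
            )
            truth_rows.append(
                {"feature_id": fid, "compartment": "repeat", "repeat_class": rclass,
                 "location": location, "true_log2fc": 0.0}
            )

    feats.sort(key=lambda iv: (iv.seq_id, iv.start, iv.end, iv.feature_id))
    repeat_ann = CompartmentAnnotation("repeat", feats, provenance="simulated")
    l1_ann = CompartmentAnnotation("repeat", l1_feats, provenance="simulated full-length L1")
    truth = GroundTruth(feature_truth=pd.DataFrame(truth_rows))
    return SimulatedAnnotation(genes, repeat_ann, l1_ann, dict(config.sequence_lengths), truth)


# ---------------------------------------------------------------------------
# Fragment simulation
# ---------------------------------------------------------------------------

def _sampling_spaces(ann: SimulatedAnnotation):
    """Disjoint draw spaces so observed compartment percentages hit targets:
    exon, pure intron (introns minus repeats), intronic repeats, intergenic
    repeats, pure intergenic."""
    exon_space = merge_intervals(build_exon_annotation(ann.genes).features)
    intron = build_intron_annotation(ann.genes).features
    intergenic = build_intergenic_annotation(ann.genes, ann.sequence_lengths).features
    reps = ann.repeat_annotation.features
    rep_merged = merge_intervals(reps)
    intron_merged = merge_intervals(intron)
    rep_intronic = [iv for iv in rep_merged if _contained_any(iv, intron_merged)]
    rep_intergenic = [iv for iv in rep_merged if not _contained_any(iv, intron_merged)]
    return {
        "exon": exon_space,
        "intron_pure": subtract_intervals(intron, reps),
        "repeat_intronic": rep_intronic,
        "repeat_intergenic": rep_intergenic,
        "intergenic_pure": subtract_intervals(intergenic, reps),
    }


def _contained_any(iv: GenomicInterval, merged: list[GenomicInterval]) -> bool:
    return any(
        m.seq_id == iv.seq_id and m.start <= iv.start and iv.end <= m.end for m in merged
    )


def _draw_fragments(space: list[GenomicInterval], n: int, frag_len: int,
                    rng: np.random.Generator) -> list[GenomicInterval]:
    if n == 0:
        return []
    if not space:
        raise ValueError("cannot draw fragments from an empty compartment space")
    lens = np.array([len(iv) for iv in space], dtype=np.int64)
    picks = rng.choice(len(space), size=n, p=lens / lens.sum())
    iv_start = np.array([iv.start for iv in space], dtype=np.int64)[picks]
    iv_len = lens[picks]
    L = np.minimum(frag_len, iv_len)
    offsets = np.floor(rng.random(n) * (iv_len - L + 1)).astype(np.int64)
    starts = iv_start + offsets
    seqs = [space[k].seq_id for k in picks]
    return [
        GenomicInterval(seq, int(s), int(s + l))
        for seq, s, l in zip(seqs, starts, L)
    ]


def simulate_fragments(
    config: SimulationConfig, annotation: SimulatedAnnotation
) -> tuple[dict[str, FragmentSet], PairedDesign, GroundTruth]:
    """Per-sample fragment sets with the condition's mixing proportions.

    Each sample's fragments are a multinomial draw over five disjoint spaces
    (exon, pure intron, intronic repeat, intergenic repeat, pure intergenic);
    the repeat-compartment target is split between intronic and intergenic
    repeat space by repeat_draw_intronic_fraction, so intron targets already
    include the intronic-repeat signal. A per-subject baseline offset (shared
    between T0 and T1) plus independent per-sample noise jitters the
    proportions.
    """
    config.validate()
    rng = _stage_rng(config.seed, 1)
    spaces = _sampling_spaces(annotation)
    space_order = ["exon", "intron_pure", "repeat_intronic", "repeat_intergenic", "intergenic_pure"]
    rho = config.repeat_draw_intronic_fraction
    samples: dict[str, FragmentSet] = {}
    design_map: dict[str, dict[str, str]] = {}
    count_rows = []
    for i in range(config.n_subjects):
        subject = f"S{i + 1}"
        subj_offset = rng.normal(0.0, config.subject_jitter_sd, size=3)
        design_map[subject] = {}
        for cond in ("T0", "T1"):
            props = config.t0_proportions if cond == "T0" else config.t1_proportions
            noise = rng.normal(0.0, config.sample_noise_sd, size=3)
            p_e = props["exon"] + subj_offset[0] + noise[0]
            p_i = props["intron"] + subj_offset[1] + noise[1]
            p_r = props["repeat"] + subj_offset[2] + noise[2]
            p_e, p_i, p_r = (float(np.clip(v, 0.0, 1.0)) for v in (p_e, p_i, p_r))
            probs = np.array(
                [p_e, p_i - rho * p_r, rho * p_r, (1 - rho) * p_r,
                 1.0 - p_e - p_i - (1 - rho) * p_r]
            )
            probs = np.clip(probs, 0.0, None)
            if probs.sum() <= 0:
                raise ValueError("mixing proportions leave no mass to draw from")
            probs = probs / probs.sum()
            counts = rng.multinomial(config.fragments_per_sample, probs)
            sample_id = f"{subject}_{cond}"
            frags: list[GenomicInterval] = []
            for cat, n in zip(space_order, counts):
                frags.extend(_draw_fragments(spaces[cat], int(n), config.fragment_length, rng))
                count_rows.append({"sample_id": sample_id, "category": cat, "n_fragments": int(n)})
            perm = rng.permutation(len(frags))
            frags = [frags[j] for j in perm]
            for j, f in enumerate(frags):
                f.feature_id = f"{sample_id}:frag{j:07d}"
            samples[sample_id] = FragmentSet(sample_id, frags, cond, subject)
            design_map[subject][cond] = sample_id
    truth = GroundTruth(
        feature_truth=annotation.truth.feature_truth,
        fragment_counts=pd.DataFrame(count_rows),
    )
    return samples, PairedDesign(design_map), truth


# ---------------------------------------------------------------------------
# Count simulation
# ---------------------------------------------------------------------------

def simulate_counts(
    config: SimulationConfig,
    feature_ids: Sequence[str],
    feature_lengths: Mapping[str, int] | None = None,
    true_log2fc: Mapping[str, float] | None = None,
    n_per_group: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[CountMatrix, pd.DataFrame, PairedDesign]:
    """NB count matrix with known per-feature log2 fold changes.

    mean[f, s] = baseline_f * size_s * 2^(log2FC_f * [s in T1]); counts are
    negative-binomial with the configured dispersion (Poisson in the
    dispersion -> 0 limit). When `true_log2fc` is None a de_fraction subset
    gets effects drawn from de_log2fc_choices with random sign. Returns the
    matrix, a truth table and the matching paired design.
    """
    rng = rng if rng is not None else _stage_rng(config.seed, 2)
    ids = list(feature_ids)
    n = n_per_group or config.n_subjects
    if true_log2fc is None:
        lfc = np.zeros(len(ids))
        n_de = int(round(config.de_fraction * len(ids)))
        de_idx = rng.choice(len(ids), size=n_de, replace=False)
        mags = rng.choice(config.de_log2fc_choices, size=n_de)
        signs = rng.choice([-1.0, 1.0], size=n_de)
        lfc[de_idx] = mags * signs
    else:
        lfc = np.array([float(true_log2fc.get(f, 0.0)) for f in ids])
    baseline = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, size=len(ids))
    sizes = rng.lognormal(0.0, config.size_factor_log_sd, size=2 * n)
    design_map = {f"S{j + 1}": {"T0": f"S{j + 1}_T0", "T1": f"S{j + 1}_T1"} for j in range(n)}
    sample_ids = [f"S{j + 1}_{c}" for c in ("T0", "T1") for j in range(n)]
    is_t1 = np.array([sid.endswith("T1") for sid in sample_ids])
    mu = baseline[:, None] * sizes[None, :] * np.power(2.0, lfc[:, None] * is_t1[None, :])
    disp = config.nb_dispersion
    if disp < 1e-8:
        counts = rng.poisson(mu)
    else:
        shape = 1.0 / disp
        counts = rng.poisson(rng.gamma(shape, mu / shape))
    counts_df = pd.DataFrame(counts.astype(np.int64), index=ids, columns=sample_ids)
    if feature_lengths is None:
        lengths = pd.Series(rng.integers(500, 5000, size=len(ids)), index=ids)
    else:
        lengths = pd.Series({f: int(feature_lengths[f]) for f in ids})
    lib = counts_df.sum(axis=0)
    cm = CountMatrix(counts_df, lengths, lib)
    truth = pd.DataFrame({"feature_id": ids, "true_log2fc": lfc, "baseline_mean": baseline})
    return cm, truth, PairedDesign(design_map)


# ---------------------------------------------------------------------------
# On-disk bundle
# ---------------------------------------------------------------------------

def write_simulation(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate the full synthetic study and write every artifact to disk.

    Emits genes.gtf, rmsk.tsv (simplified 7-column, 0-based), chrom.sizes,
    l1_full.gtf, one BED per sample, design.tsv, truth.tsv and sim.yaml.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ann = generate_annotation(config)
    samples, design, truth = simulate_fragments(config, ann)

    paths: dict[str, Path] = {}
    genes_gtf = out / "genes.gtf"
    with open(genes_gtf, "w") as fh:
        for g in ann.genes:
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(
                f"{g.span.seq_id}\tintroshift_sim\tgene\t{g.span.start + 1}\t{g.span.end}"
                f"\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for ex in g.exons:
                fh.write(
                    f"{ex.seq_id}\tintroshift_sim\texon\t{ex.start + 1}\t{ex.end}"
                    f"\t.\t{g.strand}\t.\t{attrs}\n"
                )
    paths["genes"] = genes_gtf

    rmsk = out / "rmsk.tsv"
    with open(rmsk, "w") as fh:
        fh.write("#genoName\tgenoStart\tgenoEnd\tstrand\trepName\trepClass\trepFamily\n")
        for iv in ann.repeat_annotation.features:
            fh.write(
                f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{iv.strand}\t"
                f"{iv.attributes['repeat_name']}\t{iv.attributes['repeat_class']}\t"
                f"{iv.attributes['repeat_family']}\n"
            )
    paths["repeats"] = rmsk

    sizes = out / "chrom.sizes"
    write_chrom_sizes(ann.sequence_lengths, sizes)
    paths["chrom_sizes"] = sizes

    l1 = out / "l1_full.gtf"
    write_gtf(ann.l1_annotation, l1)
    paths["l1"] = l1

    for sid, fs in samples.items():
        bed = out / f"{sid}.bed"
        with open(bed, "w") as fh:
            for iv in fs.fragments:
                fh.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{iv.feature_id}\n")
        paths[f"fragments:{sid}"] = bed

    design_tsv = out / "design.tsv"
    design.to_tsv(design_tsv)
    paths["design"] = design_tsv

    truth_tsv = out / "truth.tsv"
    truth.feature_truth.to_csv(truth_tsv, sep="\t", index=False)
    truth.fragment_counts.to_csv(out / "fragment_truth.tsv", sep="\t", index=False)
    paths["truth"] = truth_tsv

    config.to_yaml(out / "sim.yaml")
    paths["config"] = out / "sim.yaml"
    return paths
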