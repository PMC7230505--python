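"""Placing modulated repeats in their genomic context.

Classifies differentially expressed repeat loci relative to gene structure
(exonic / intronic / genic-other / intergenic, with an exonic > intronic >
genic-other precedence for loci touching several compartments), intersects
modulated repeats with modulated introns, overlaps DEG lists with curated
gene sets, and runs the DE stage on full-length LINE-1 loci only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import CompartmentAnnotation, GeneModel, GenomicInterval, build_exon_annotation
from .de import filter_low_expression, nb_test, size_factors
from .quantify import CountMatrix


def _interval_table(features: Sequence[GenomicInterval]) -> dict[str, tuple[np.ndarray, np.ndarray, list[str]]]:
    by_seq: dict[str, list[tuple[int, int, str]]] = {}
    for iv in features:
        by_seq.setdefault(iv.seq_id, []).append((iv.start, iv.end, iv.feature_id))
    out = {}
    for seq, triples in by_seq.items():
        triples.sort()
        starts = np.array([t[0] for t in triples], dtype=np.int64)
        ends = np.array([t[1] for t in triples], dtype=np.int64)
        out[seq] = (starts, ends, [t[2] for t in triples], np.maximum.accumulate(ends))
    return out


def _overlapping_ids(iv: GenomicInterval, table) -> list[str]:
    if iv.seq_id not in table:
        return []
    starts, ends, ids, cummax_ends = table[iv.seq_id]
    # features are start-sorted; the running max of ends bounds the left scan
    lo = int(np.searchsorted(cummax_ends, iv.start, side="right"))
    hi = int(np.searchsorted(starts, iv.end, side="left"))
    return [ids[j] for j in range(lo, hi) if ends[j] > iv.start]


@dataclass
class RepeatContext:
    """Genomic placement of one modulated repeat locus."""

    feature_id: str
    location_class: str  # exonic | intronic | genic-other | intergenic
    host_gene_ids: list[str]
    host_modulated: bool


def locate_repeats(
    de_repeats: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    intron_annotation: CompartmentAnnotation,
    modulated_gene_ids: Iterable[str] = (),
    exon_annotation: CompartmentAnnotation | None = None,
) -> list[RepeatContext]:
    """Classify repeat loci by >=1-base overlap against gene structure.

    Precedence when a locus touches several compartments: exonic > intronic >
    genic-other; a locus overlapping no gene span is intergenic (and then has
    no host genes). host_modulated is True when any host gene is in
    `modulated_gene_ids` (typically the UP/DOWN gene ids from the
    exon-compartment DE).
    """
    exon_ann = exon_annotation or build_exon_annotation(genes)
    exon_tab = _interval_table(exon_ann.features)
    intron_tab = _interval_table(intron_annotation.features)
    span_feats = [
        GenomicInterval(g.span.seq_id, g.span.start, g.span.end, g.strand, g.gene_id)
        for g in genes
    ]
    span_tab = _interval_table(span_feats)
    modulated = set(modulated_gene_ids)
    out = []
    for rep in de_repeats:
        hosts = sorted(set(_overlapping_ids(rep, span_tab)))
        if _overlapping_ids(rep, exon_tab):
            loc = "exonic"
        elif _overlapping_ids(rep, intron_tab):
            loc = "intronic"
        elif hosts:
            loc = "genic-other"
        else:
            loc = "intergenic"
        if loc == "intergenic":
            hosts = []
        out.append(RepeatContext(rep.feature_id, loc, hosts, bool(modulated & set(hosts))))
    return out


def context_table(contexts: Sequence[RepeatContext]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": [c.feature_id for c in contexts],
            "location_class": [c.location_class for c in contexts],
            "host_gene_ids": [",".join(c.host_gene_ids) for c in contexts],
            "host_modulated": [c.host_modulated for c in contexts],
        }
    )


def intersect_de_repeats_with_de_introns(
    de_repeats: Sequence[GenomicInterval],
    de_introns: Sequence[GenomicInterval],
) -> tuple[pd.DataFrame, list[str]]:
    """All (repeat, intron) pairs of modulated features overlapping >=1 base.

    Both inputs should already be restricted to modulated (UP/DOWN) features.
    Returns the match table and the distinct host gene ids of matched introns
    (from their comma-joined gene_id attributes).
    """
    intron_tab = _interval_table(de_introns)
    intron_by_id = {iv.feature_id: iv for iv in de_introns}
    rows = []
    host_genes: set[str] = set()
    for rep in de_repeats:
        for intron_id in _overlapping_ids(rep, intron_tab):
            intron = intron_by_id[intron_id]
            rows.append(
                {
                    "repeat_id": rep.feature_id,
                    "intron_id": intron_id,
                    "seq_id": rep.seq_id,
                    "repeat_interval": f"{rep.start}-{rep.end}",
                    "intron_interval": f"{intron.start}-{intron.end}",
                }
            )
            for gid in intron.attributes.get("gene_id", "").split(","):
                if gid:
                    host_genes.add(gid)
    cols = ["repeat_id", "intron_id", "seq_id", "repeat_interval", "intron_interval"]
    return pd.DataFrame(rows, columns=cols), sorted(host_genes)


@dataclass
class GeneSetOverlap:
    """Overlap of exon- and intron-compartment DEG lists with a gene set."""

    set_name: str
    n_set: int
    n_degs: int  # size of the exon/intron DEG union
    n_overlap: int
    exon_only: int
    intron_only: int
    both: int

    def __post_init__(self) -> None:
        if self.exon_only + self.intron_only + self.both != self.n_overlap:
            raise ValueError("overlap partition does not add up")


def gene_set_overlap(
    deg_exon: Iterable[str],
    deg_intron: Iterable[str],
    gene_set: Iterable[str],
    set_name: str = "",
) -> GeneSetOverlap:
    """Intersect the DEG union with a curated gene-id set.

    The overlap is partitioned into genes modulated in the exon compartment
    only, the intron compartment only, or both ("full gene" modulation).
    """
    ex, intr, gs = set(deg_exon), set(deg_intron), set(gene_set)
    union = ex | intr
    overlap = union & gs
    both = len(ex & intr & gs)
    exon_only = len((ex - intr) & gs)
    intron_only = len((intr - ex) & gs)
    return GeneSetOverlap(set_name, len(gs), len(union), len(overlap), exon_only, intron_only, both)


def read_gene_set(path) -> list[str]:
    """One gene id per line; blank lines and #-comments ignored."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip() and not line.startswith("#")]


def select_full_length_l1(
    repeat_annotation: CompartmentAnnotation,
    min_length: int = 6000,
    family: str = "L1",
) -> CompartmentAnnotation:
    """Heuristic stand-in for a curated full-length LINE-1 annotation.

    Picks repeat loci of the given family at least `min_length` bp long. This
    is a length-based heuristic for synthetic runs, not a sequence-intactness
    definition — supply a curated annotation when one exists.
    """
    feats = [
        iv
        for iv in repeat_annotation.features
        if iv.attributes.get("repeat_family") == family and len(iv) >= min_length
    ]
    return CompartmentAnnotation(
        "repeat", feats, provenance=f"heuristic full-length {family} (>= {min_length} bp)"
    )


def full_length_line1_de(
    cm: CountMatrix,
    design,
    l1_annotation: CompartmentAnnotation,
    fpkm_threshold: float = 5.0,
    sample_fraction: float = 0.8,
    lfc_threshold: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Run the DE stage restricted to full-length LINE-1 loci.

    `cm` is a repeat-compartment count matrix keyed by locus feature_id;
    loci absent from the matrix are ignored. Size factors come from the FULL
    matrix, not the L1 subset: the handful of L1 loci may all move in the
    same direction and would otherwise normalize their own signal away.
    Loci removed by the expression filter are reported as NS (log2FC 0,
    p = q = 1) so every annotated locus appears in the output.
    """
    if len(l1_annotation) == 0:
        raise ValueError("full-length LINE-1 annotation is empty")
    ids = [iv.feature_id for iv in l1_annotation.features if iv.feature_id in cm.counts.index]
    if not ids:
        raise ValueError("no full-length LINE-1 locus present in the count matrix")
    sf = size_factors(cm.counts)
    sub = filter_low_expression(cm.subset(ids), fpkm_threshold, sample_fraction)
    if len(sub.counts) == 0:
        res = pd.DataFrame(columns=["feature_id", "base_mean", "log2FC", "p_value", "q_value", "call"])
    else:
        res = nb_test(sub, design, lfc_threshold=lfc_threshold, alpha=alpha,
                      sample_size_factors=sf)
    dropped = [f for f in ids if f not in set(res["feature_id"])]
    if dropped:
        norm_mean = (cm.counts.loc[dropped] / sf).mean(axis=1)
        ns_rows = pd.DataFrame({
            "feature_id": dropped,
            "base_mean": norm_mean.to_numpy(),
            "log2FC": 0.0, "p_value": 1.0, "q_value": 1.0, "call": "NS",
        })
        res = ns_rows if res.empty else pd.concat([res, ns_rows], ignore_index=True)
    return res
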