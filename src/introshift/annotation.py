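"""Compartment annotations from gene and repeat models.

The central construction is the "negative" annotation: intron space obtained
by subtracting the union of all exons (from every isoform of every gene) from
the union of all gene spans. Because both unions are taken genome-wide before
subtraction, the construction is robust to multiple isoforms and to
overlapping genes — an exon of gene B carves bases out of an intron of an
overlapping gene A.

Coordinates are 0-based, half-open internally. GTF I/O is 1-based inclusive;
BED I/O is 0-based half-open.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

STRANDS = {"+", "-", "."}


@dataclass
class GenomicInterval:
    """A named, stranded interval on a named sequence (0-based, half-open)."""

    seq_id: str
    start: int
    end: int
    strand: str = "."
    feature_id: str = ""
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.seq_id:
            raise ValueError("seq_id must be non-empty")
        if not self.start < self.end:
            raise ValueError(
                f"empty or inverted interval [{self.start}, {self.end}) on {self.seq_id}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {sorted(STRANDS)}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GeneModel:
    """One gene: its span and the exons of all its isoforms, stored as given.

    Exons may mutually overlap (multiple isoforms); they are never merged or
    deduplicated here.
    """

    gene_id: str
    span: GenomicInterval
    exons: list[GenomicInterval]
    strand: str = "."

    def __post_init__(self) -> None:
        for ex in self.exons:
            if ex.seq_id != self.span.seq_id or ex.start < self.span.start or ex.end > self.span.end:
                raise ValueError(
                    f"gene {self.gene_id}: exon [{ex.start}, {ex.end}) on {ex.seq_id} "
                    f"outside gene span [{self.span.start}, {self.span.end}) on {self.span.seq_id}"
                )


@dataclass
class CompartmentAnnotation:
    """A set of features for one genomic compartment.

    compartment is one of {"exon", "intron", "repeat", "intergenic"}.
    provenance records how the annotation was built.
    """

    compartment: str
    features: list[GenomicInterval]
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.compartment not in {"exon", "intron", "repeat", "intergenic"}:
            raise ValueError(f"unknown compartment {self.compartment!r}")

    def __len__(self) -> int:
        return len(self.features)

    def seq_ids(self) -> list[str]:
        return sorted({f.seq_id for f in self.features})

    def total_bases(self) -> int:
        """Bases in the union of all features (overlaps counted once)."""
        return sum(len(iv) for iv in merge_intervals(self.features))


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------

def _by_seq(intervals: Iterable[GenomicInterval]) -> dict[str, list[GenomicInterval]]:
    out: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        out.setdefault(iv.seq_id, []).append(iv)
    return out


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals as a minimal sorted list of disjoint intervals.

    Strand-blind: intervals on opposite strands are merged together and the
    result carries strand ".". Abutting half-open intervals ([10,20), [20,30))
    merge into one.
    """
    merged: list[GenomicInterval] = []
    for seq_id in sorted(_by_seq(intervals)):
        ivs = sorted(_by_seq(intervals)[seq_id], key=lambda iv: (iv.start, iv.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                merged.append(GenomicInterval(seq_id, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        merged.append(GenomicInterval(seq_id, cur_s, cur_e))
    return merged


def subtract_intervals(
    minuend: Sequence[GenomicInterval], subtrahend: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Bases in the union of `minuend` but not in the union of `subtrahend`.

    Returns disjoint sorted intervals per sequence. Strand-blind.
    """
    minu = merge_intervals(minuend)
    subt = _by_seq(merge_intervals(subtrahend))
    out: list[GenomicInterval] = []
    for m in minu:
        cuts = [s for s in subt.get(m.seq_id, []) if s.start < m.end and s.end > m.start]
        pos = m.start
        for s in cuts:
            if s.start > pos:
                out.append(GenomicInterval(m.seq_id, pos, s.start))
            pos = max(pos, s.end)
        if pos < m.end:
            out.append(GenomicInterval(m.seq_id, pos, m.end))
    return out


# ---------------------------------------------------------------------------
# GTF parsing
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_gtf_attributes(text: str) -> dict[str, str]:
    return {k: v for k, v in _ATTR_RE.findall(text)}


def _parse_gtf_line(line: str, lineno: int):
    fields = line.rstrip("\n").split("\t")
    if len(fields) != 9:
        raise ValueError(f"malformed GTF line {lineno}: expected 9 tab-separated fields, got {len(fields)}")
    seq_id, source, feature, start, end, score, strand, frame, attrs = fields
    try:
        start_i, end_i = int(start), int(end)
    except ValueError as exc:
        raise ValueError(f"malformed GTF line {lineno}: non-integer coordinates") from exc
    if strand not in STRANDS:
        strand = "."
    # GTF is 1-based inclusive; internal is 0-based half-open.
    return seq_id, feature, start_i - 1, end_i, strand, _parse_gtf_attributes(attrs)


def parse_gene_gtf(path: str | Path) -> list[GeneModel]:
    """Parse an Ensembl-dialect GTF into gene models.

    Uses `gene` records for spans when present; genes seen only through their
    `exon` records get the hull of those exons as span. Exon records lacking
    a gene_id are rejected (logged), not fatal. A gene_id appearing on more
    than one sequence is an error.
    """
    spans: dict[str, GenomicInterval] = {}
    exons: dict[str, list[GenomicInterval]] = {}
    strands: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            seq_id, feature, start, end, strand, attrs = _parse_gtf_line(line, lineno)
            if feature not in ("gene", "exon"):
                continue
            gene_id = attrs.get("gene_id")
            if not gene_id:
                logger.warning("GTF line %d: %s record without gene_id rejected", lineno, feature)
                continue
            known_seq = spans[gene_id].seq_id if gene_id in spans else (
                exons[gene_id][0].seq_id if exons.get(gene_id) else None
            )
            if known_seq is not None and known_seq != seq_id:
                raise ValueError(
                    f"gene_id {gene_id!r} appears on multiple sequences ({known_seq}, {seq_id})"
                )
            if feature == "gene":
                spans[gene_id] = GenomicInterval(seq_id, start, end, strand, gene_id)
                strands.setdefault(gene_id, strand)
            else:
                exons.setdefault(gene_id, []).append(
                    GenomicInterval(seq_id, start, end, strand, gene_id, {"gene_id": gene_id})
                )
                strands.setdefault(gene_id, strand)
    genes = []
    for gene_id in sorted(set(spans) | set(exons)):
        gene_exons = exons.get(gene_id, [])
        if gene_id in spans:
            span = spans[gene_id]
        else:
            span = GenomicInterval(
                gene_exons[0].seq_id,
                min(e.start for e in gene_exons),
                max(e.end for e in gene_exons),
                strands[gene_id],
                gene_id,
            )
        genes.append(GeneModel(gene_id, span, gene_exons, strands[gene_id]))
    return genes


# ---------------------------------------------------------------------------
# Compartment construction
# ---------------------------------------------------------------------------

def build_exon_annotation(genes: Sequence[GeneModel]) -> CompartmentAnnotation:
    """Per-gene merged exon features (isoform overlaps within a gene collapsed).

    Exons of different genes that overlap stay as separate features, each
    carrying its own gene_id — counting decides how to treat that ambiguity.
    """
    feats: list[GenomicInterval] = []
    for g in genes:
        for i, iv in enumerate(merge_intervals(g.exons)):
            feats.append(
                GenomicInterval(
                    iv.seq_id, iv.start, iv.end, g.strand,
                    f"{g.gene_id}:exon:{i}", {"gene_id": g.gene_id},
                )
            )
    feats.sort(key=lambda iv: (iv.seq_id, iv.start, iv.end))
    return CompartmentAnnotation("exon", feats, provenance=f"merged exons of {len(genes)} genes")


def _strand_groups(genes: Sequence[GeneModel], strand_aware: bool):
    if not strand_aware:
        return [(".", list(genes))]
    # "." genes participate in both strand groups
    plus = [g for g in genes if g.strand in ("+", ".")]
    minus = [g for g in genes if g.strand in ("-", ".")]
    return [("+", plus), ("-", minus)]


def build_intron_annotation(
    genes: Sequence[GeneModel], strand_aware: bool = False
) -> CompartmentAnnotation:
    """Intron compartment: union of gene spans minus union of all exons.

    Each resulting interval is annotated with the gene_id of every gene span
    containing it (comma-joined, sorted). Intervals are split wherever the set
    of host genes changes, so each stored feature is fully contained in every
    one of its host spans. By default the subtraction is strand-blind (an exon
    removes intronic bases from overlapping genes on either strand); with
    strand_aware=True the subtraction is done per strand, unstranded genes
    participating in both groups.
    """
    if not genes:
        raise ValueError("at least one gene required")
    feats: list[GenomicInterval] = []
    for group_strand, group in _strand_groups(genes, strand_aware):
        if not group:
            continue
        spans = [g.span for g in group]
        exons = [e for g in group for e in g.exons]
        raw = subtract_intervals(spans, exons)
        # split at gene-span boundaries so host attribution is exact
        bounds: dict[str, set[int]] = {}
        for g in group:
            bounds.setdefault(g.span.seq_id, set()).update((g.span.start, g.span.end))
        for iv in raw:
            cutpoints = sorted(
                {iv.start, iv.end} | {b for b in bounds.get(iv.seq_id, ()) if iv.start < b < iv.end}
            )
            for s, e in zip(cutpoints[:-1], cutpoints[1:]):
                hosts = sorted(
                    g.gene_id
                    for g in group
                    if g.span.seq_id == iv.seq_id and g.span.start <= s and e <= g.span.end
                )
                feats.append(
                    GenomicInterval(iv.seq_id, s, e, group_strand, "",
                                    {"gene_id": ",".join(hosts)})
                )
    # merge adjacent pieces that share a host set (splitting may over-fragment)
    feats.sort(key=lambda iv: (iv.seq_id, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in feats:
        if (
            merged
            and merged[-1].seq_id == iv.seq_id
            and merged[-1].end == iv.start
            and merged[-1].attributes["gene_id"] == iv.attributes["gene_id"]
            and merged[-1].strand == iv.strand
        ):
            merged[-1] = GenomicInterval(
                iv.seq_id, merged[-1].start, iv.end, merged[-1].strand,
                merged[-1].feature_id, merged[-1].attributes,
            )
        else:
            merged.append(iv)
    for i, iv in enumerate(merged):
        iv.feature_id = f"intron:{i:06d}"
    return CompartmentAnnotation(
        "intron",
        merged,
        provenance=f"gene spans minus exons, {len(genes)} genes, strand_aware={strand_aware}",
    )


def build_intergenic_annotation(
    genes: Sequence[GeneModel], sequence_lengths: Mapping[str, int]
) -> CompartmentAnnotation:
    """Complement of merged gene spans within [0, length) per sequence."""
    spans = merge_intervals([g.span for g in genes])
    for iv in spans:
        if iv.seq_id not in sequence_lengths:
            raise ValueError(f"no declared length for sequence {iv.seq_id}")
        if iv.end > sequence_lengths[iv.seq_id]:
            raise ValueError(
                f"gene span ends at {iv.end} beyond declared length "
                f"{sequence_lengths[iv.seq_id]} of {iv.seq_id}"
            )
    universe = [
        GenomicInterval(seq, 0, length)
        for seq, length in sorted(sequence_lengths.items())
        if length > 0
    ]
    feats = subtract_intervals(universe, spans)
    for i, iv in enumerate(feats):
        iv.feature_id = f"intergenic:{i:06d}"
    return CompartmentAnnotation(
        "intergenic", feats, provenance=f"complement of {len(genes)} gene spans"
    )


# ---------------------------------------------------------------------------
# Repeat annotation (UCSC rmsk table or GTF)
# ---------------------------------------------------------------------------

# column indices in a UCSC rmsk dump (with leading `bin` column)
_RMSK17 = {"seq": 5, "start": 6, "end": 7, "strand": 9, "name": 10, "class": 11, "family": 12}
_RMSK16 = {k: v - 1 for k, v in _RMSK17.items()}  # same dump without `bin`
_SIMPLE7 = {"seq": 0, "start": 1, "end": 2, "strand": 3, "name": 4, "class": 5, "family": 6}


def _repeat_feature(seq, start, end, strand, name, rclass, rfamily, lineno) -> GenomicInterval:
    if not rclass:
        logger.warning("repeat record line %d (%s) missing class; kept as Unknown", lineno, name)
        rclass = "Unknown"
    if not rfamily:
        rfamily = rclass
    fid = f"{name}|{seq}:{start}-{end}"
    return GenomicInterval(
        seq, start, end, strand if strand in STRANDS else ".", fid,
        {"repeat_name": name, "repeat_class": rclass, "repeat_family": rfamily},
    )


def parse_repeat_annotation(path: str | Path, dialect: str = "auto") -> CompartmentAnnotation:
    """Parse a repeat annotation preserving name, class and family per locus.

    Dialects: "rmsk" — UCSC RepeatMasker table dump, tab-separated, 0-based
    genoStart (17 columns with `bin`, 16 without, or a simplified 7-column
    seq/start/end/strand/name/class/family layout); "gtf" — 1-based inclusive
    GTF with repeat_name/repeat_class/repeat_family (or TEtranscripts-style
    gene_id/class_id/family_id) attributes. "auto" picks GTF for .gtf/.gff
    paths, rmsk otherwise. Each locus gets a unique feature_id of the form
    name|seq:start-end.
    """
    path = Path(path)
    if dialect == "auto":
        dialect = "gtf" if path.suffix.lower() in (".gtf", ".gff", ".gff3") else "rmsk"
    feats: list[GenomicInterval] = []
    if dialect == "gtf":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith("#"):
                    continue
                seq_id, _feature, start, end, strand, attrs = _parse_gtf_line(line, lineno)
                name = attrs.get("repeat_name") or attrs.get("gene_id") or "Unknown"
                rclass = attrs.get("repeat_class") or attrs.get("class_id") or ""
                rfamily = attrs.get("repeat_family") or attrs.get("family_id") or ""
                feat = _repeat_feature(seq_id, start, end, strand, name, rclass, rfamily, lineno)
                if "feature_id" in attrs:  # written by write_gtf: keep locus identity
                    feat.feature_id = attrs["feature_id"]
                feats.append(feat)
    elif dialect == "rmsk":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith("#"):
                    continue
                cols = line.rstrip("\n").split("\t")
                if len(cols) >= 17:
                    ix = _RMSK17
                elif len(cols) >= 15:
                    ix = _RMSK16
                elif len(cols) >= 6:
                    ix = _SIMPLE7
                else:
                    raise ValueError(f"rmsk line {lineno}: unrecognized column count {len(cols)}")
                seq = cols[ix["seq"]]
                start, end = int(cols[ix["start"]]), int(cols[ix["end"]])  # already 0-based half-open
                strand = cols[ix["strand"]]
                if strand == "C":  # RepeatMasker writes C for minus strand
                    strand = "-"
                name = cols[ix["name"]]
                rclass = cols[ix["class"]] if len(cols) > ix["class"] else ""
                rfamily = cols[ix["family"]] if len(cols) > ix["family"] else ""
                feats.append(_repeat_feature(seq, start, end, strand, name, rclass, rfamily, lineno))
    else:
        raise ValueError(f"unknown repeat dialect {dialect!r}")
    feats.sort(key=lambda iv: (iv.seq_id, iv.start, iv.end, iv.feature_id))
    return CompartmentAnnotation("repeat", feats, provenance=f"{dialect} table {path.name}")


# ---------------------------------------------------------------------------
# GTF / BED output and generic annotation reading
# ---------------------------------------------------------------------------

def write_gtf(annotation: CompartmentAnnotation, path: str | Path) -> None:
    """Write a formally correct 9-field GTF (1-based inclusive).

    Attributes are emitted as gene_id first (falling back to the feature_id
    when the feature has no gene_id attribute), then feature_id, then the
    remaining attributes in sorted order. read_gtf_annotation() inverts this
    exactly.
    """
    with open(path, "w") as fh:
        for iv in annotation.features:
            for v in iv.attributes.values():
                if '"' in str(v) or ";" in str(v):
                    raise ValueError(f"attribute value {v!r} not representable in GTF")
            attrs = {"gene_id": iv.attributes.get("gene_id", iv.feature_id), "feature_id": iv.feature_id}
            for k in sorted(iv.attributes):
                if k != "gene_id":
                    attrs[k] = iv.attributes[k]
            attr_text = " ".join(f'{k} "{v}";' for k, v in attrs.items())
            fh.write(
                f"{iv.seq_id}\tintroshift\t{annotation.compartment}\t"
                f"{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t{attr_text}\n"
            )


def read_gtf_annotation(path: str | Path, compartment: str | None = None) -> CompartmentAnnotation:
    """Read a GTF written by write_gtf back into a CompartmentAnnotation.

    A gene_id attribute equal to the feature_id is treated as the synthesized
    write-time default and dropped, making parse(write(x)) == x.
    """
    feats: list[GenomicInterval] = []
    comp = compartment
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            seq_id, feature, start, end, strand, attrs = _parse_gtf_line(line, lineno)
            comp = comp or feature
            fid = attrs.pop("feature_id", None) or attrs.get("gene_id", f"feature:{lineno}")
            if attrs.get("gene_id") == fid and "feature_id" not in attrs:
                attrs.pop("gene_id", None)
            feats.append(GenomicInterval(seq_id, start, end, strand, fid, attrs))
    if comp is None:
        comp = compartment or "exon"
    return CompartmentAnnotation(comp, feats, provenance=f"read from {Path(path).name}")


def write_bed(annotation: CompartmentAnnotation, path: str | Path) -> None:
    """BED6 export (0-based half-open, as BED requires)."""
    with open(path, "w") as fh:
        for iv in annotation.features:
            fh.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{iv.feature_id}\t0\t{iv.strand}\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column name/length table; .fai layout (5 columns) also accepted."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split()
            sizes[cols[0]] = int(cols[1])
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in sizes.items():
            fh.write(f"{name}\t{length}\n")
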