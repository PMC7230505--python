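"""Fragment-to-compartment assignment and count matrices.

Counting follows the featureCounts default semantics: a fragment is assigned
to a grouping key (gene_id for exon/intron compartments, the repeat locus for
the repeat compartment) when it overlaps any feature of that key by at least
one base; a fragment overlapping features of two or more distinct keys is
ambiguous and assigned to none; multiple overlapped features of the same key
count once. Counting is unstranded.

Compartment percentages are computed against each compartment's annotation
independently (three separate passes), so exon + intron + repeat + intergenic
percentages need not total 100 — a fragment inside an intronic repeat counts
for both the intron and the repeat compartment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .annotation import CompartmentAnnotation, GenomicInterval, merge_intervals

logger = logging.getLogger(__name__)


@dataclass
class FragmentSet:
    """One sample's uniquely-mapped aligned fragments.

    Mate pairs are pre-merged: one interval per sequenced fragment (the hull
    of the two mates on one sequence).
    """

    sample_id: str
    fragments: list[GenomicInterval]
    condition: str = ""
    subject_id: str = ""
    stats: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.fragments)

    def arrays(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-sequence (starts, ends) arrays, in input order."""
        out: dict[str, tuple[list[int], list[int]]] = {}
        for iv in self.fragments:
            s = out.setdefault(iv.seq_id, ([], []))
            s[0].append(iv.start)
            s[1].append(iv.end)
        return {
            seq: (np.asarray(s, dtype=np.int64), np.asarray(e, dtype=np.int64))
            for seq, (s, e) in out.items()
        }


@dataclass
class CountMatrix:
    """Features × samples integer counts with feature lengths and library sizes.

    `lengths` is the merged base count of each feature's intervals; `library_sizes`
    is the total number of retained alignments per sample in the counting
    universe (not the column sum, which excludes ambiguous/unassigned fragments).
    """

    counts: pd.DataFrame
    lengths: pd.Series
    library_sizes: pd.Series

    def __post_init__(self) -> None:
        c = self.counts
        if (c.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(c.to_numpy().dtype, np.integer):
            raise ValueError("counts must be integers")
        self.lengths = self.lengths.reindex(c.index)
        if self.lengths.isna().any():
            raise ValueError("every feature needs a length")
        self.library_sizes = self.library_sizes.reindex(c.columns)
        if self.library_sizes.isna().any():
            raise ValueError("every sample needs a library size")
        too_big = c.sum(axis=0) > self.library_sizes
        if too_big.any():
            raise ValueError(
                f"assigned counts exceed library size for {list(c.columns[too_big])}"
            )

    @property
    def feature_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def subset(self, feature_ids) -> "CountMatrix":
        return CountMatrix(
            self.counts.loc[feature_ids], self.lengths.loc[feature_ids], self.library_sizes
        )

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            sizes = ",".join(f"{s}={int(v)}" for s, v in self.library_sizes.items())
            fh.write(f"#library_sizes: {sizes}\n")
            df = self.counts.copy()
            df.insert(0, "length", self.lengths)
            df.index.name = "feature_id"
            df.to_csv(fh, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountMatrix":
        with open(path) as fh:
            first = fh.readline()
            sizes = None
            if first.startswith("#library_sizes:"):
                sizes = {
                    kv.split("=")[0]: int(kv.split("=")[1])
                    for kv in first.split(":", 1)[1].strip().split(",")
                }
                df = pd.read_csv(fh, sep="\t", index_col=0)
            else:
                fh.seek(0)
                df = pd.read_csv(fh, sep="\t", index_col=0)
        lengths = df.pop("length")
        counts = df.astype(np.int64)
        if sizes is None:
            lib = counts.sum(axis=0)
            logger.warning("%s carries no library sizes; using column sums", path)
        else:
            lib = pd.Series(sizes)
        return cls(counts, lengths, lib)


# ---------------------------------------------------------------------------
# Fragment loading
# ---------------------------------------------------------------------------

def load_fragments(
    path: str | Path,
    sample_id: str | None = None,
    condition: str = "",
    subject_id: str = "",
    min_mapq: int = 30,
) -> FragmentSet:
    """Load uniquely-mapped fragments from BED or SAM/BAM.

    SAM/BAM: secondary, supplementary, unmapped and duplicate-flagged records
    are dropped; a record is unique when its NH tag equals 1, or — if NH is
    absent — when MAPQ >= `min_mapq`. Mates of a proper pair on one sequence
    are merged into a single fragment spanning their hull; mates on different
    sequences are discarded. BAM input must be coordinate-sorted.
    BED: one interval per line (0-based half-open), taken as-is.
    """
    path = Path(path)
    sample_id = sample_id or path.stem
    suffix = path.suffix.lower()
    if suffix in (".bed", ".tsv", ".txt"):
        frags, n_in = _load_bed(path)
    elif suffix in (".sam", ".bam", ".cram"):
        frags, n_in = _load_alignments(path, min_mapq)
    else:
        raise ValueError(f"unrecognized fragment file type: {path.name}")
    stats = {"input_records": n_in, "retained_fragments": len(frags)}
    logger.info("%s: retained %d fragments from %d records", sample_id, len(frags), n_in)
    return FragmentSet(sample_id, frags, condition, subject_id, stats)


def _load_bed(path: Path):
    frags: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"BED line {lineno}: fewer than 3 columns")
            name = cols[3].strip() if len(cols) > 3 else f"frag:{lineno}"
            frags.append(GenomicInterval(cols[0], int(cols[1]), int(cols[2]), ".", name))
    return frags, len(frags)


def _is_unique(read, min_mapq: int) -> bool:
    if read.has_tag("NH"):
        return read.get_tag("NH") == 1
    return read.mapping_quality >= min_mapq


def _load_alignments(path: Path, min_mapq: int):
    mode = "rb" if path.suffix.lower() == ".bam" else "r"
    frags: list[GenomicInterval] = []
    n_in = 0
    with pysam.AlignmentFile(str(path), mode) as af:
        if path.suffix.lower() == ".bam":
            so = (af.header.to_dict().get("HD") or {}).get("SO")
            if so != "coordinate":
                raise ValueError(
                    f"{path.name} is not coordinate-sorted (SO={so}); run `samtools sort` first"
                )
        pending: dict[str, tuple[str, int, int]] = {}
        for read in af:
            n_in += 1
            if read.is_unmapped or read.is_secondary or read.is_supplementary or read.is_duplicate:
                continue
            if not _is_unique(read, min_mapq):
                continue
            ref = read.reference_name
            start, end = read.reference_start, read.reference_end
            if end is None or end <= start:
                continue
            if not read.is_paired:
                frags.append(GenomicInterval(ref, start, end, ".", read.query_name))
                continue
            mate = pending.pop(read.query_name, None)
            if mate is None:
                pending[read.query_name] = (ref, start, end)
            else:
                mref, ms, me = mate
                if mref != ref:
                    continue  # mates on different sequences: discard fragment
                frags.append(
                    GenomicInterval(ref, min(ms, start), max(me, end), ".", read.query_name)
                )
        # paired reads whose mate never passed the filters: use the single mate
        for name, (ref, start, end) in pending.items():
            frags.append(GenomicInterval(ref, start, end, ".", name))
    return frags, n_in


# ---------------------------------------------------------------------------
# Counting
# ---------------------------------------------------------------------------

def _segment_index(annotation: CompartmentAnnotation, group_by: str):
    """Disjoint breakpoint segments per sequence, each labeled with the set of
    grouping keys whose features cover it. Also returns merged bases per key."""
    per_seq: dict[str, tuple[np.ndarray, list[frozenset]]] = {}
    key_lengths: dict[str, int] = {}
    by_seq: dict[str, list[tuple[int, int, str]]] = {}
    for iv in annotation.features:
        key = iv.attributes.get(group_by, iv.feature_id) if group_by != "feature_id" else iv.feature_id
        by_seq.setdefault(iv.seq_id, []).append((iv.start, iv.end, key))
    for seq, triples in by_seq.items():
        bps = np.unique(np.array([t[0] for t in triples] + [t[1] for t in triples], dtype=np.int64))
        events: dict[int, tuple[list[str], list[str]]] = {}
        for s, e, k in triples:
            events.setdefault(s, ([], []))[0].append(k)
            events.setdefault(e, ([], []))[1].append(k)
        active: dict[str, int] = {}
        labels: list[frozenset] = []
        for i, bp in enumerate(bps[:-1]):
            adds, removes = events.get(bp, ([], []))
            for k in removes:
                active[k] -= 1
                if active[k] == 0:
                    del active[k]
            for k in adds:
                active[k] = active.get(k, 0) + 1
            label = frozenset(active)
            labels.append(label)
            seg_len = int(bps[i + 1] - bp)
            for k in label:
                key_lengths[k] = key_lengths.get(k, 0) + seg_len
        per_seq[seq] = (bps, labels)
    return per_seq, key_lengths


def count_features(
    fragments: FragmentSet,
    annotation: CompartmentAnnotation,
    group_by: str = "gene_id",
) -> tuple[pd.Series, pd.Series, dict]:
    """Count fragments per grouping key with the ambiguity rule.

    Returns (counts indexed by key, merged feature lengths per key, stats).
    Keys come from the feature attribute named by `group_by` (falling back to
    the feature_id); pass group_by="feature_id" for per-locus repeat counting.
    An intron feature hosted by several overlapping genes carries their ids
    comma-joined; such a fragment is attributed to that joint key as stored.
    """
    index, key_lengths = _segment_index(annotation, group_by)
    counts: dict[str, int] = {k: 0 for k in key_lengths}
    ambiguous = unassigned = 0
    for seq, (starts, ends) in sorted(fragments.arrays().items()):
        if seq not in index:
            unassigned += len(starts)
            continue
        bps, labels = index[seq]
        lo = np.searchsorted(bps, starts, side="right") - 1
        hi = np.searchsorted(bps, ends, side="left")
        lo = np.clip(lo, 0, len(labels))
        hi = np.clip(hi, 0, len(labels))
        for i in range(len(starts)):
            keys: set[str] = set()
            for j in range(lo[i], hi[i]):
                keys |= labels[j]
            if len(keys) == 1:
                counts[next(iter(keys))] += 1
            elif len(keys) > 1:
                ambiguous += 1
            else:
                unassigned += 1
    keys_sorted = sorted(key_lengths)
    count_s = pd.Series([counts[k] for k in keys_sorted], index=keys_sorted, dtype=np.int64)
    length_s = pd.Series([key_lengths[k] for k in keys_sorted], index=keys_sorted, dtype=np.int64)
    stats = {
        "assigned": int(count_s.sum()),
        "ambiguous": ambiguous,
        "unassigned": unassigned,
        "total": len(fragments),
    }
    return count_s, length_s, stats


def build_count_matrix(
    fragment_sets: Sequence[FragmentSet],
    annotation: CompartmentAnnotation,
    group_by: str = "gene_id",
) -> CountMatrix:
    """Count every sample against one annotation and assemble the matrix."""
    cols = {}
    lengths = None
    for fs in fragment_sets:
        c, lengths, _ = count_features(fs, annotation, group_by)
        cols[fs.sample_id] = c
    counts = pd.DataFrame(cols)
    lib = pd.Series({fs.sample_id: len(fs) for fs in fragment_sets})
    return CountMatrix(counts, lengths, lib)


# ---------------------------------------------------------------------------
# Compartment summaries (Table-2-shaped input)
# ---------------------------------------------------------------------------

def overlaps_any(fragments: FragmentSet, annotation: CompartmentAnnotation) -> np.ndarray:
    """Boolean per fragment: does it overlap the annotation's merged space?"""
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for iv in merge_intervals(annotation.features):
        s = merged.setdefault(iv.seq_id, ([], []))
        s[0].append(iv.start)
        s[1].append(iv.end)
    merged = {
        seq: (np.asarray(s, dtype=np.int64), np.asarray(e, dtype=np.int64))
        for seq, (s, e) in merged.items()
    }
    out = np.zeros(len(fragments), dtype=bool)
    by_seq: dict[str, list[int]] = {}
    for idx, iv in enumerate(fragments.fragments):
        by_seq.setdefault(iv.seq_id, []).append(idx)
    arrays = fragments.arrays()
    for seq, indices in by_seq.items():
        if seq not in merged:
            continue
        fs, fe = arrays[seq]
        ms, me = merged[seq]
        # leftmost merged interval ending after the fragment start;
        # overlap iff it also begins before the fragment end
        i = np.searchsorted(me, fs, side="right")
        hit = (i < len(ms)) & (ms[np.minimum(i, len(ms) - 1)] < fe)
        out[np.asarray(indices)] = hit
    return out


def summarize_compartments(
    fragments: FragmentSet,
    exon_ann: CompartmentAnnotation,
    intron_ann: CompartmentAnnotation,
    repeat_ann: CompartmentAnnotation,
) -> dict:
    """Per-sample assigned counts and percentages per compartment.

    Each compartment is assessed independently against its own annotation
    (three separate passes), so the percentages are not constrained to sum
    to 100. Raises on an empty fragment set (undefined percentages).
    """
    total = len(fragments)
    if total == 0:
        raise ValueError(f"sample {fragments.sample_id}: no fragments; percentages undefined")
    row: dict = {
        "sample_id": fragments.sample_id,
        "subject_id": fragments.subject_id,
        "condition": fragments.condition,
        "total_alignments": total,
    }
    for name, ann in (("exon", exon_ann), ("intron", intron_ann), ("repeat", repeat_ann)):
        n = int(overlaps_any(fragments, ann).sum())
        row[f"{name}_count"] = n
        row[f"{name}_pct"] = 100.0 * n / total
    return row


@dataclass
class CompartmentSummary:
    """Per-sample compartment assignment table (the Table-2-shaped object)."""

    table: pd.DataFrame  # one row per sample, columns from summarize_compartments

    COLUMNS = [
        "sample_id", "subject_id", "condition", "total_alignments",
        "exon_count", "exon_pct", "intron_count", "intron_pct",
        "repeat_count", "repeat_pct",
    ]

    @classmethod
    def from_rows(cls, rows: Sequence[dict]) -> "CompartmentSummary":
        return cls(pd.DataFrame(rows)[cls.COLUMNS])

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CompartmentSummary":
        return cls(pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subject_id": str}))

    def percentages(self, compartment: str) -> pd.Series:
        return self.table.set_index("sample_id")[f"{compartment}_pct"]
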