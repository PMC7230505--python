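"""Shared fixtures and brute-force oracles.

The interval-algebra oracles work on explicit per-base boolean arrays; the
counting oracle enumerates all fragment x feature pairs with numpy
broadcasting. Both are deliberately independent of the package's sweep- and
searchsorted-based implementations.
"""

from __future__ import annotations

import numpy as np
import pytest

from introshift.annotation import GeneModel, GenomicInterval


# ---------------------------------------------------------------------------
# per-base boolean oracle
# ---------------------------------------------------------------------------

def base_mask(intervals, seq_id: str, length: int) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    for iv in intervals:
        if iv.seq_id == seq_id:
            mask[iv.start : iv.end] = True
    return mask


def mask_to_intervals(mask: np.ndarray, seq_id: str) -> list[tuple[str, int, int]]:
    """Maximal runs of True as (seq, start, end) triples."""
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return [(seq_id, int(s), int(e)) for s, e in zip(starts, ends)]


def intervals_as_triples(intervals, seq_id=None):
    return sorted(
        (iv.seq_id, iv.start, iv.end)
        for iv in intervals
        if seq_id is None or iv.seq_id == seq_id
    )


# ---------------------------------------------------------------------------
# all-pairs overlap oracle
# ---------------------------------------------------------------------------

def overlap_matrix(fragments, features) -> np.ndarray:
    """Boolean [n_fragments, n_features]: >=1-base overlap, same sequence."""
    fseq = np.array([f.seq_id for f in fragments])
    fs = np.array([f.start for f in fragments])
    fe = np.array([f.end for f in fragments])
    gseq = np.array([g.seq_id for g in features])
    gs = np.array([g.start for g in features])
    ge = np.array([g.end for g in features])
    return (
        (fseq[:, None] == gseq[None, :])
        & (fs[:, None] < ge[None, :])
        & (gs[None, :] < fe[:, None])
    )


def brute_force_counts(fragments, features, keys):
    """featureCounts-rule counts per key: unique-key fragments only."""
    keys = np.asarray(keys, dtype=object)
    counts = {k: 0 for k in set(keys)}
    ambiguous = 0
    m = overlap_matrix(fragments, features)
    for row in m:
        hit = set(keys[row])
        if len(hit) == 1:
            counts[hit.pop()] += 1
        elif len(hit) > 1:
            ambiguous += 1
    return counts, ambiguous


# ---------------------------------------------------------------------------
# random toy genomes
# ---------------------------------------------------------------------------

def random_gene_set(rng: np.random.Generator, seq_len: int = 10_000, n_genes: int = 6,
                    seq_id: str = "chr1") -> list[GeneModel]:
    """Random genes with random exon structure; overlaps allowed."""
    genes = []
    for g in range(n_genes):
        start = int(rng.integers(0, seq_len - 500))
        length = int(rng.integers(300, min(3000, seq_len - start)))
        end = start + length
        n_ex = int(rng.integers(1, 5))
        cuts = np.sort(rng.choice(np.arange(start, end + 1), size=2 * n_ex, replace=False))
        exons = []
        gid = f"G{g}"
        for i in range(0, 2 * n_ex, 2):
            s, e = int(cuts[i]), int(cuts[i + 1])
            if e > s:
                exons.append(GenomicInterval(seq_id, s, e, "+", f"{gid}:e{i}", {"gene_id": gid}))
        if not exons:
            exons = [GenomicInterval(seq_id, start, end, "+", f"{gid}:e0", {"gene_id": gid})]
        genes.append(GeneModel(gid, GenomicInterval(seq_id, start, end, "+", gid), exons, "+"))
    return genes


def random_intervals(rng, n, seq_len, seq_id="chr1", max_len=400):
    out = []
    for i in range(n):
        s = int(rng.integers(0, seq_len - 1))
        e = s + int(rng.integers(1, max_len))
        out.append(GenomicInterval(seq_id, s, min(e, seq_len), ".", f"iv{i}"))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


# Table 2's per-sample compartment percentages (subject order S10,S5,S6,S8,S9)
TABLE2_PCT = {
    "exon": {"T0": [55.4, 53.8, 57.0, 55.3, 59.9], "T1": [51.8, 54.3, 53.7, 53.5, 53.8]},
    "intron": {"T0": [24.2, 25.6, 21.7, 24.4, 19.9], "T1": [29.8, 27.0, 27.3, 26.6, 27.2]},
    "repeat": {"T0": [14.8, 15.4, 13.3, 15.3, 12.7], "T1": [16.8, 15.6, 15.7, 15.4, 15.5]},
}
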