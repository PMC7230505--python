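"""Paired compartment-shift statistics.

For each compartment (exon, intron, repeat) the per-subject assignment
percentage at rest (T0) is compared with the percentage immediately after the
race (T1) using a paired Student t-test on the per-subject differences:

    t = d_bar / (s_d / sqrt(n)),   df = n - 1

The default sidedness is one-sided in the direction of the observed mean
difference; the two-sided p-value is always reported alongside. Percentages
are carried at full precision; rounding happens only at report time (one
decimal for per-sample percentages, two for means and deltas, three for p).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import CompartmentSummary

CONDITIONS = ("T0", "T1")
COMPARTMENTS = ("exon", "intron", "repeat")


@dataclass
class PairedDesign:
    """Subjects with one sample per condition (T0 at rest, T1 post-race)."""

    samples: dict[str, dict[str, str]]  # subject_id -> {condition -> sample_id}

    def __post_init__(self) -> None:
        if len(self.samples) < 2:
            raise ValueError("paired design needs at least 2 subjects")
        for subject, by_cond in self.samples.items():
            if set(by_cond) != set(CONDITIONS):
                raise ValueError(
                    f"subject {subject}: needs exactly one sample per condition "
                    f"{CONDITIONS}, got {sorted(by_cond)}"
                )

    @property
    def subjects(self) -> list[str]:
        return sorted(self.samples)

    def sample_ids(self, condition: str) -> list[str]:
        return [self.samples[s][condition] for s in self.subjects]

    def condition_of(self, sample_id: str) -> str:
        for by_cond in self.samples.values():
            for cond, sid in by_cond.items():
                if sid == sample_id:
                    return cond
        raise KeyError(f"sample {sample_id!r} not in design")

    @classmethod
    def from_table(cls, df: pd.DataFrame) -> "PairedDesign":
        """Build from a table with sample_id, subject_id, condition columns."""
        samples: dict[str, dict[str, str]] = {}
        for _, row in df.iterrows():
            cond = str(row["condition"])
            if cond not in CONDITIONS:
                raise ValueError(f"condition must be one of {CONDITIONS}, got {cond!r}")
            sub = samples.setdefault(str(row["subject_id"]), {})
            if cond in sub:
                raise ValueError(f"subject {row['subject_id']}: duplicate {cond} sample")
            sub[cond] = str(row["sample_id"])
        return cls(samples)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PairedDesign":
        return cls.from_table(pd.read_csv(path, sep="\t", dtype=str))

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {"sample_id": sid, "subject_id": subject, "condition": cond}
            for subject in self.subjects
            for cond, sid in sorted(self.samples[subject].items())
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class ShiftResult:
    """Paired-test result for one compartment (one Table-2 bottom block)."""

    compartment: str
    mean_t0: float
    mean_t1: float
    delta: float  # percentage points, T1 - T0
    t_statistic: float | None
    df: int
    p_value: float | None  # under the requested sidedness
    p_two_sided: float | None
    sidedness: str
    degenerate: bool = False  # zero-variance differences: no p emitted


def paired_shift_test(
    percentages_t0: Sequence[float],
    percentages_t1: Sequence[float],
    sidedness: str = "one-sided",
    compartment: str = "",
) -> ShiftResult:
    """Paired t-test on per-subject compartment percentages.

    One-sided p is taken in the direction of the observed mean difference
    (p = P(T_{n-1} > |t|)); for a zero mean difference it is 0.5. When every
    per-subject difference is identical to machine precision the variance is
    zero and the result is flagged degenerate with no p-value.
    """
    if sidedness not in ("one-sided", "two-sided"):
        raise ValueError(f"sidedness must be one-sided or two-sided, got {sidedness!r}")
    x0 = np.asarray(percentages_t0, dtype=float)
    x1 = np.asarray(percentages_t1, dtype=float)
    if x0.shape != x1.shape or x0.ndim != 1:
        raise ValueError("T0 and T1 percentage vectors must be equal-length 1-D")
    n = len(x0)
    if n < 2:
        raise ValueError("paired test needs at least 2 subjects")
    d = x1 - x0
    df = n - 1
    sd = float(np.std(d, ddof=1))
    mean_t0, mean_t1 = float(x0.mean()), float(x1.mean())
    delta = float(d.mean())
    if sd == 0.0:
        return ShiftResult(compartment, mean_t0, mean_t1, delta, None, df,
                           None, None, sidedness, degenerate=True)
    t = delta / (sd / np.sqrt(n))
    p_two = 2.0 * float(stats.t.sf(abs(t), df))
    p_one = float(stats.t.sf(abs(t), df)) if delta != 0 else 0.5
    p = p_one if sidedness == "one-sided" else p_two
    return ShiftResult(compartment, mean_t0, mean_t1, delta, float(t), df, p, p_two, sidedness)


def summarize_design(
    summary: CompartmentSummary,
    design: PairedDesign,
    sidedness: str = "one-sided",
) -> list[ShiftResult]:
    """One ShiftResult per compartment from a per-sample summary table."""
    pct = summary.table.set_index("sample_id")
    for cond in CONDITIONS:
        for sid in design.sample_ids(cond):
            if sid not in pct.index:
                raise KeyError(f"design sample {sid!r} missing from summary")
    results = []
    for comp in COMPARTMENTS:
        col = f"{comp}_pct"
        t0 = [float(pct.loc[sid, col]) for sid in design.sample_ids("T0")]
        t1 = [float(pct.loc[sid, col]) for sid in design.sample_ids("T1")]
        results.append(paired_shift_test(t0, t1, sidedness, compartment=comp))
    return results


def shift_table(results: Sequence[ShiftResult]) -> pd.DataFrame:
    """Report-ready table: means at 2 decimals, deltas signed at 2, p at 3."""
    rows = []
    for r in results:
        rows.append(
            {
                "compartment": r.compartment,
                "mean_T0": round(r.mean_t0, 2),
                "mean_T1": round(r.mean_t1, 2),
                "delta": round(r.delta, 2),
                "t": None if r.t_statistic is None else round(r.t_statistic, 3),
                "df": r.df,
                "p": None if r.p_value is None else round(r.p_value, 3),
                "p_two_sided": None if r.p_two_sided is None else round(r.p_two_sided, 3),
                "sidedness": r.sidedness,
                "degenerate_variance": r.degenerate,
            }
        )
    return pd.DataFrame(rows)
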