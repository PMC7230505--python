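"""Report tables mirroring the study's summary-table shapes.

Two renderings: a sequencing-summary table (per-sample read totals, the
quality-check passed rate, the unique-alignment rate, plus an Average row)
and a compartment-assignment table (per-sample totals, assigned counts and
percentages per compartment with condition-wise Average rows, the paired
delta row and the paired-test p row).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .quantify import CompartmentSummary
from .shift import PairedDesign, ShiftResult, summarize_design


def sequencing_summary(table: pd.DataFrame, reads_per_fragment: int = 2) -> pd.DataFrame:
    """Per-sample sequencing accounting with derived rates and an Average row.

    Input columns: sample_id, reads_before_trimming, reads_after_trimming,
    uniquely_mapped_reads. The QC-passed rate is 100 * after / before at one
    decimal. uniquely_mapped_reads counts fragments, so for paired-end data
    (reads_per_fragment=2, the default) the alignment rate is
    100 * unique * reads_per_fragment / after. Averages of the count columns
    are plain means of the per-sample values.
    """
    req = ["sample_id", "reads_before_trimming", "reads_after_trimming", "uniquely_mapped_reads"]
    missing = [c for c in req if c not in table.columns]
    if missing:
        raise ValueError(f"sequencing summary input missing columns {missing}")
    df = table[req].copy()
    df["qc_passed_rate"] = (
        100.0 * df["reads_after_trimming"] / df["reads_before_trimming"]
    ).round(1)
    df["alignment_rate"] = (
        100.0 * reads_per_fragment * df["uniquely_mapped_reads"] / df["reads_after_trimming"]
    ).round(1)
    avg = {
        "sample_id": "Average",
        "reads_before_trimming": df["reads_before_trimming"].mean(),
        "reads_after_trimming": df["reads_after_trimming"].mean(),
        "uniquely_mapped_reads": df["uniquely_mapped_reads"].mean(),
        "qc_passed_rate": round(df["qc_passed_rate"].mean(), 1),
        "alignment_rate": round(df["alignment_rate"].mean(), 2),
    }
    return pd.concat([df, pd.DataFrame([avg])], ignore_index=True)


def compartment_report(
    summary: CompartmentSummary,
    design: PairedDesign,
    results: Sequence[ShiftResult] | None = None,
    sidedness: str = "one-sided",
) -> pd.DataFrame:
    """Compartment-assignment report with per-condition blocks.

    Rows: each T0 sample, the T0 Average, each T1 sample, the T1 Average,
    then a delta row (T1 average minus T0 average per compartment) and a
    p-value row from the paired test.
    """
    if results is None:
        results = summarize_design(summary, design, sidedness)
    by_comp = {r.compartment: r for r in results}
    tbl = summary.table.set_index("sample_id")
    rows = []
    for cond in ("T0", "T1"):
        sids = design.sample_ids(cond)
        for sid in sids:
            r = tbl.loc[sid]
            rows.append(
                {
                    "sample": sid,
                    "total_alignments": int(r["total_alignments"]),
                    "exon_count": int(r["exon_count"]), "exon_pct": round(float(r["exon_pct"]), 1),
                    "intron_count": int(r["intron_count"]), "intron_pct": round(float(r["intron_pct"]), 1),
                    "repeat_count": int(r["repeat_count"]), "repeat_pct": round(float(r["repeat_pct"]), 1),
                }
            )
        sub = tbl.loc[sids]
        rows.append(
            {
                "sample": f"Average {cond}",
                "total_alignments": round(float(sub["total_alignments"].mean()), 2),
                "exon_count": round(float(sub["exon_count"].mean()), 2),
                "exon_pct": round(float(sub["exon_pct"].mean()), 2),
                "intron_count": round(float(sub["intron_count"].mean()), 2),
                "intron_pct": round(float(sub["intron_pct"].mean()), 2),
                "repeat_count": round(float(sub["repeat_count"].mean()), 2),
                "repeat_pct": round(float(sub["repeat_pct"].mean()), 2),
            }
        )
    delta_row = {"sample": "Race VS. Basal"}
    p_row = {"sample": "t-Test"}
    for comp in ("exon", "intron", "repeat"):
        r = by_comp[comp]
        delta_row[f"{comp}_pct"] = f"{r.delta:+.2f}"
        p_row[f"{comp}_pct"] = None if r.p_value is None else round(r.p_value, 3)
    rows.extend([delta_row, p_row])
    return pd.DataFrame(rows)


def write_report(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
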