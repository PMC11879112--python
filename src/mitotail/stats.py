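"""Tail-length summaries and replicate-level group comparisons.

Replicate libraries (the analysis mirrors biological triplicates) yield one
value per replicate for each metric — canonical-end fraction, alternate-end
fraction, mean tail length — and genotypes/conditions are compared with the
classic equal-variance two-sample Student's t test (two-tailed, pooled SD,
n1 + n2 - 2 degrees of freedom).  Welch's correction is available via
``equal_var=False``.  No multiple-testing correction is applied by default:
comparisons are reported per metric, as in small targeted panels.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .endmap import EndClassification
from .tailcall import TailCall

COMPARISON_METRICS = ("canonical_fraction", "alternate_fraction", "mean_tail_length")


@dataclass(frozen=True)
class TailDistribution:
    gene: str
    sample: str
    lengths: np.ndarray
    n: int
    mean: float
    median: float
    mode: int
    sd: float


@dataclass(frozen=True)
class GroupComparison:
    metric: str
    group_means: tuple[float, float]
    group_sds: tuple[float, float]
    t_statistic: float
    p_value: float
    df: int


def summarize_tails(
    lengths: Iterable[int], gene: str = "", sample: str = ""
) -> TailDistribution:
    """Mean/median/mode/SD of per-read tail lengths (mode: smallest of the
    most frequent lengths; SD with ddof=1, zero for a single read)."""
    arr = np.asarray(sorted(lengths), dtype=np.int64)
    if arr.size == 0:
        raise ValueError("no tail lengths to summarize")
    values, counts = np.unique(arr, return_counts=True)
    return TailDistribution(
        gene=gene,
        sample=sample,
        lengths=arr,
        n=int(arr.size),
        mean=float(arr.mean()),
        median=float(np.median(arr)),
        mode=int(values[np.argmax(counts)]),
        sd=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
    )


def modal_tail_length(calls: Sequence[TailCall]) -> int:
    """Most frequent called tail length (smallest on ties)."""
    return summarize_tails([c.tail_length for c in calls]).mode


def tail_length_summary(
    calls: Sequence[TailCall],
    classifications: Optional[Sequence[EndClassification]] = None,
    sample: str = "",
) -> dict[str, TailDistribution]:
    """Per-gene tail distributions for one sample.

    With ``classifications`` given, reads are grouped by their assigned gene;
    otherwise all reads are summarized under a single unnamed gene.
    """
    if classifications is None:
        return {"": summarize_tails([c.tail_length for c in calls], sample=sample)}
    gene_of = {c.read_id: c.gene for c in classifications}
    groups: dict[str, list[int]] = {}
    for call in calls:
        gene = gene_of.get(call.read_id)
        if gene is None:
            continue
        groups.setdefault(gene, []).append(call.tail_length)
    return {
        gene: summarize_tails(lengths, gene=gene, sample=sample)
        for gene, lengths in sorted(groups.items())
    }


def compare_groups(
    group_a: Sequence[float],
    group_b: Sequence[float],
    metric: str = "",
    equal_var: bool = True,
) -> GroupComparison:
    """Two-tailed unpaired Student's t test on replicate values.

    Equal-variance (pooled SD) by default; with both groups constant and
    equal the comparison is degenerate and reported as t=0, p=1.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 replicates per group")
    df = int(a.size + b.size - 2)
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        if a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            t = np.inf if a.mean() > b.mean() else -np.inf
            p = 0.0
    else:
        res = sps.ttest_ind(a, b, equal_var=equal_var)
        t, p = float(res.statistic), float(res.pvalue)
        if not equal_var:
            df = int(np.floor(res.df))
    return GroupComparison(
        metric=metric,
        group_means=(float(a.mean()), float(b.mean())),
        group_sds=(float(a.std(ddof=1)), float(b.std(ddof=1))),
        t_statistic=t,
        p_value=p,
        df=df,
    )


def build_report(
    metrics: pd.DataFrame, compare: Optional[tuple[str, str]] = None
) -> tuple[pd.DataFrame, list[GroupComparison]]:
    """Aggregate per-replicate metrics into a gene x sample report.

    ``metrics`` needs columns sample, replicate, gene plus the metric columns
    (canonical_fraction, alternate_fraction, other_fraction,
    mean_tail_length, ... and any counters).  Rows are averaged over
    replicates (mean and SD); with ``compare=(sample_a, sample_b)`` a
    Student's t test per gene and metric is appended.
    """
    required = {"sample", "replicate", "gene"}
    if not required.issubset(metrics.columns):
        missing = sorted(required - set(metrics.columns))
        raise ValueError(f"metrics table missing columns: {missing}")
    value_cols = [c for c in metrics.columns if c not in ("sample", "replicate", "gene")]
    grouped = metrics.groupby(["gene", "sample"], sort=True)
    agg = grouped[value_cols].agg(["mean", "std", "count"])
    agg.columns = ["_".join(col) for col in agg.columns]
    report = agg.reset_index().sort_values(["gene", "sample"]).reset_index(drop=True)

    comparisons: list[GroupComparison] = []
    if compare is not None:
        sample_a, sample_b = compare
        for gene, sub in metrics.groupby("gene", sort=True):
            a = sub[sub["sample"] == sample_a]
            b = sub[sub["sample"] == sample_b]
            for metric in COMPARISON_METRICS:
                if metric not in sub.columns:
                    continue
                cmp_res = compare_groups(
                    a.sort_values("replicate")[metric].to_numpy(),
                    b.sort_values("replicate")[metric].to_numpy(),
                    metric=f"{gene}:{metric}",
                )
                comparisons.append(cmp_res)
                report.loc[report["gene"] == gene, f"p_{metric}"] = cmp_res.p_value
                report.loc[report["gene"] == gene, f"t_{metric}"] = cmp_res.t_statistic
    return report, comparisons


def report(run_dir) -> tuple[pd.DataFrame, list[GroupComparison]]:
    """Combined report over a run directory.

    Expects ``<run_dir>/<sample>/<replicate>/metrics.tsv`` files as written
    by the pipeline drivers; missing stage outputs are named explicitly.
    With exactly two samples they are compared per gene and metric.
    Deterministic ordering throughout, so reruns are byte-identical.
    """
    run_dir = Path(run_dir)
    frames = []
    for sample_dir in sorted(p for p in run_dir.iterdir() if p.is_dir()):
        for rep_dir in sorted(p for p in sample_dir.iterdir() if p.is_dir()):
            path = rep_dir / "metrics.tsv"
            if not path.exists():
                raise FileNotFoundError(
                    f"missing stage output: {path} (expected per-replicate metrics)"
                )
            frame = pd.read_csv(path, sep="\t")
            frame["sample"] = sample_dir.name
            frame["replicate"] = rep_dir.name
            frames.append(frame)
    if not frames:
        return (
            pd.DataFrame(columns=["gene", "sample"]),
            [],
        )
    metrics = pd.concat(frames, ignore_index=True)
    samples = sorted(metrics["sample"].unique())
    compare = (samples[0], samples[1]) if len(samples) == 2 else None
    return build_report(metrics, compare=compare)


def plot_tail_histogram(dist: TailDistribution, path) -> None:
    """PNG histogram of one sample's per-read tail lengths."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    lo, hi = int(dist.lengths.min()), int(dist.lengths.max())
    ax.hist(dist.lengths, bins=range(lo, hi + 2), color="#4477aa", edgecolor="white")
    ax.axvline(dist.mean, color="#cc3311", lw=1, label=f"mean {dist.mean:.1f} nt")
    ax.set_xlabel("poly(A) tail length (nt)")
    ax.set_ylabel("reads")
    title = " / ".join(x for x in (dist.gene, dist.sample) if x)
    if title:
        ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_end_fractions(report_df: pd.DataFrame, path) -> None:
    """Grouped bars of mean canonical/alternate/other fractions per gene and
    sample, with SD error bars, from a report table."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = ("canonical", "alternate", "other")
    rows = report_df.reset_index(drop=True)
    x = np.arange(len(rows))
    width = 0.8 / len(labels)
    fig, ax = plt.subplots(figsize=(1.5 + 1.2 * len(rows), 3.2))
    for k, label in enumerate(labels):
        mean_col, sd_col = f"{label}_fraction_mean", f"{label}_fraction_std"
        if mean_col not in rows.columns:
            continue
        ax.bar(
            x + (k - 1) * width,
            rows[mean_col],
            width,
            yerr=rows.get(sd_col),
            capsize=2,
            label=label,
        )
    ax.set_xticks(x)
    ax.set_xticklabels(rows["gene"] + " / " + rows["sample"], rotation=20)
    ax.set_ylabel("fraction of reads")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
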