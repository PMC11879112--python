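"""Aggregate replicates and compare conditions, Figure-4 style.

Builds the gene x sample report (mean +/- SD over triplicates for end-usage
fractions and tail lengths) and runs two-tailed unpaired Student's t tests
between the two conditions for canonical fraction, alternate fraction and
mean tail length.  Writes results/report.tsv and tail-length histograms.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
import common

from mitotail.stats import plot_end_fractions, plot_tail_histogram, report, summarize_tails


def main() -> None:
    report_df, comparisons = report(common.RUN)
    out = common.ROOT / "results" / "report.tsv"
    report_df.to_csv(out, sep="\t", index=False)

    cols = [
        "gene",
        "sample",
        "canonical_fraction_mean",
        "canonical_fraction_std",
        "alternate_fraction_mean",
        "mean_tail_length_mean",
        "mean_tail_length_std",
    ]
    print(report_df[cols].to_string(index=False))
    print()
    for cmp_res in comparisons:
        print(
            f"{cmp_res.metric}: t = {cmp_res.t_statistic:.3f}, df = {cmp_res.df}, "
            f"p = {cmp_res.p_value:.3g}"
        )

    for sample in common.SAMPLES:
        lengths = pd.concat(
            pd.read_csv(common.rep_dir(sample, rep) / "tails.tsv", sep="\t")["tail_length"]
            for rep in common.REPLICATES
        )
        dist = summarize_tails(lengths, gene="ND3", sample=sample)
        plot_tail_histogram(dist, common.ROOT / "results" / f"tails_{sample}.png")
    plot_end_fractions(report_df, common.ROOT / "results" / "end_fractions.png")
    print(f"\nreport written to {out}")


if __name__ == "__main__":
    main()
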