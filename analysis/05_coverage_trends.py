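#!/usr/bin/env python
"""Classify transcript-coverage trends around the promoter hexamer.

Generates Poisson coverage for a benchmark genome (step from rate 1 to rate
10 at the motif's 3' end for leaderless genes, at -80 for leadered genes),
classifies every gene's trend with the ratio statistic, and writes the class
counts plus the motif-anchored mean trend curve. Expected: sensitivity and
specificity >= 0.95 for the step-increase call, and the mean curve's sharpest
rise immediately after the motif.
"""

import os

import pandas as pd

from leaderless_scan import pipeline

RESULTS = os.path.join(os.path.dirname(__file__), "..", "results")


def main():
    bench = pipeline.step_classifier_benchmark(n_per_class=500)

    os.makedirs(RESULTS, exist_ok=True)
    pd.DataFrame(
        [{"trend": k, "n_genes": v} for k, v in sorted(bench.class_counts.items())]
    ).to_csv(os.path.join(RESULTS, "05_trend_counts.tsv"), sep="\t", index=False)
    bench.curve.to_csv(os.path.join(RESULTS, "05_mean_trend_curve.tsv"),
                       sep="\t", index=False, float_format="%.5g")
    pd.DataFrame(
        [
            {"quantity": "step_sensitivity", "value": bench.sensitivity},
            {"quantity": "step_specificity", "value": bench.specificity},
            {"quantity": "gradient_peak_offset_nt", "value": bench.gradient_peak_offset},
        ]
    ).to_csv(os.path.join(RESULTS, "05_operating_point.tsv"), sep="\t", index=False)

    print(f"trend classes: {bench.class_counts}")
    print(f"sensitivity: {bench.sensitivity:.3f}  specificity: {bench.specificity:.3f}")
    print(f"mean-curve max gradient at {bench.gradient_peak_offset} nt after the "
          f"motif's last base (planted step at +{bench.planted_step_offset})")


if __name__ == "__main__":
    main()
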