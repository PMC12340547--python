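#!/usr/bin/env python
"""Scan 450-bp windows with the discovered PWM and compute positional statistics.

Runs the full motif chain on the default genome: exact-p-value scan at
p <= 0.015 (given strand only), spacer-distance histogram, motif location
classes, and the background-corrected motif-carrying fraction. Expected:
spacer mode 6-7 bp, fraction ~ 0.30.
"""

import os

import pandas as pd

from leaderless_scan import motif_scan, pipeline, synthetic

RESULTS = os.path.join(os.path.dirname(__file__), "..", "results")


def main():
    spec = synthetic.SyntheticSpec(n_genes=3000, rng_seed=0)
    contigs, genes, truth = synthetic.gen_genome(spec)
    result = pipeline.run_motif_chain(contigs, genes)

    os.makedirs(RESULTS, exist_ok=True)
    result.spacer_hist.to_frame().to_csv(
        os.path.join(RESULTS, "03_spacer_histogram.tsv"), sep="\t", index=False
    )
    motif_scan.sites_to_table(result.sites).head(1000).to_csv(
        os.path.join(RESULTS, "03_sites_head1000.tsv"), sep="\t", index=False,
        float_format="%.6g",
    )
    pd.DataFrame(
        [{"location": k, "n_genes": v} for k, v in sorted(result.location_counts.items())]
    ).to_csv(os.path.join(RESULTS, "03_location_classes.tsv"), sep="\t", index=False)
    pd.DataFrame(
        [
            {"quantity": "corrected_motif_fraction", "value": result.fraction},
            {"quantity": "raw_in_band_gene_share",
             "value": result.summary.n_motif_genes / result.summary.n_genes},
            {"quantity": "planted_fraction_realized", "value": truth.has_motif.mean()},
            {"quantity": "spacer_mode", "value": result.spacer_hist.mode},
        ]
    ).to_csv(os.path.join(RESULTS, "03_fraction.tsv"), sep="\t", index=False)
    result.summary.top_variants.head(10).to_csv(
        os.path.join(RESULTS, "03_top_variants.tsv"), sep="\t", index=False
    )

    print(f"passing sites: {len(result.sites)} across {result.summary.n_genes} genes")
    print(f"spacer mode: {result.spacer_hist.mode} bp")
    print(f"corrected motif-carrying fraction: {result.fraction:.3f} "
          f"(planted {truth.has_motif.mean():.3f})")
    print("location classes:", result.location_counts)


if __name__ == "__main__":
    main()
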