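#!/usr/bin/env python
"""Reference-sample batch consistency QC.

Each of the 20 processing batches contains a replicate of the same reference
RNA; pairwise Pearson correlation of those 20 profiles (190 pairs) measures
cross-batch stability of the platform. QC passes when the minimum pairwise
correlation reaches 0.95.
"""

import recurpred as rp

COHORT_DIR = "scratch/cohort"


def main() -> None:
    expr = rp.read_expression(f"{COHORT_DIR}/expression.tsv")
    samples = rp.read_sample_table(f"{COHORT_DIR}/samples.tsv")
    expr, samples = rp.align(expr, samples)

    report = rp.batch_qc(expr, samples, threshold=0.95)
    report.to_json("results/batch_qc.json")

    print(f"{len(report.correlations)} batch pairs compared")
    print(f"min / median reference correlation: {report.min_correlation:.4f} / "
          f"{sorted(report.correlations.values())[len(report.correlations) // 2]:.4f}")
    print(f"QC {'PASS' if report.passed else 'FAIL'} at threshold {report.threshold}")


if __name__ == "__main__":
    main()
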