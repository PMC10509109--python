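#!/usr/bin/env python
"""Recompute the published agreement statistics from the embedded tables.

The three 5x5 risk-class contingency tables of the clinical study (80 kVp
vs 120 kVp, 70 kVp vs 120 kVp, and reader 2 vs reader 1 at 120 kVp) are
embedded in the package; this script recomputes Cohen's kappa, Kendall's
tau-b, and the reclassification summaries from the raw counts and checks
them against the published values at 3-decimal precision.

Writes results/printed_agreement.csv.
"""

from pathlib import Path

from cacsim import reproduce_printed

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    df = reproduce_printed()
    df.to_csv(OUT / "printed_agreement.csv", index=False)
    print(df.to_string(index=False))
    if df[["kappa_ok", "tau_b_ok", "rate_ok"]].to_numpy().all():
        print("\nAll recomputed statistics match the published values "
              "(kappa/tau-b to +-0.001, rates to the printed decimal).")
    else:
        print("\nWARNING: some recomputed statistics disagree with the published values.")


if __name__ == "__main__":
    main()
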