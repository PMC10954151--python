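#!/usr/bin/env python
"""Seasonal binary diagnostic ratios with ANOVA / t significance.

On the calibrated dataset the ten diagnostic ratios (Ca/Al ... Se/V) are
summarised per season bin (March-June, July-October, November-February).
Sites with three populated seasons are tested by one-way ANOVA, Bangkok
(no wet-season samples) by a pooled two-sample t test.  Na/Mg sits at
1.00 everywhere -- the crustal signature -- and the calibrated dataset,
which carries no injected seasonality, shows mostly non-significant
seasonal contrasts, as expected.
"""

from pathlib import Path

from pm25elements.ratios import seasonal_ratio_table
from pm25elements.synth import table1_fixture

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)


def main():
    table = table1_fixture(seed=0)
    out = seasonal_ratio_table(table)
    out.round(5).to_csv(OUT / "seasonal_ratios.tsv", sep="\t")

    namg = out.xs("Na/Mg", level="ratio")
    print("Na/Mg season means:",
          {f"{s[0]}|{s[1]}": round(v, 3)
           for s, v in namg["mean"].dropna().items()})
    tested = out[out["test"] != ""].droplevel("season").drop_duplicates()
    n_sig = int(tested["significant"].sum())
    print(f"significant seasonal contrasts: {n_sig} of {len(tested)} "
          "(site, ratio) pairs")


if __name__ == "__main__":
    main()
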