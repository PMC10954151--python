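#!/usr/bin/env python
"""Source apportionment by PCA/varimax/APCS-MLR, validated on known truth.

A k=3 synthetic mixture (n=200, 10% multiplicative noise) is fed through
the full receptor chain.  The model retains exactly the three
eigenvalue>1 components, the rotated loadings reproduce the model-implied
loading patterns, the regression contributions track the true per-sample
source activities, and the measured/predicted (M/P) ratio stays within a
few percent of one -- the receptor model's goodness check.
"""

from itertools import permutations
from pathlib import Path

import numpy as np
import pandas as pd

from pm25elements.receptor import fit_receptor_model, site_mean_mp
from pm25elements.synth import SynthConfig, make_source_profiles, simulate_dataset

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)


def match(columns, targets, absolute=True):
    best, best_perm = None, None
    for perm in permutations(range(columns.shape[1]), targets.shape[1]):
        rs = [np.corrcoef(columns[:, perm[i]], targets[:, i])[0, 1]
              for i in range(targets.shape[1])]
        rs = [abs(r) if absolute else r for r in rs]
        if best is None or min(rs) > min(best):
            best, best_perm = rs, perm
    return best, best_perm


def main():
    profiles = make_source_profiles(3, seed=1)
    cfg = SynthConfig(n_samples={"SYN": 200}, cv=0.10, seed=7)
    table, _, truth = simulate_dataset(profiles, cfg)
    model, apcs, mp = fit_receptor_model(table)

    print(f"components retained (eigenvalue > 1): {model.retained}")
    print("top eigenvalues:", np.round(model.eigenvalues[:5], 2))

    x = table.matrix().to_numpy()
    g = truth[list(profiles.names)].to_numpy()
    implied = np.array([[np.corrcoef(x[:, j], g[:, s])[0, 1]
                         for s in range(3)] for j in range(x.shape[1])])
    load_r, _ = match(model.rotated_loadings, implied)
    contrib_r, _ = match(apcs.apcs, g, absolute=False)
    print("loading-pattern |r| per source:", np.round(load_r, 3))
    print("contribution r per source:", np.round(contrib_r, 3))
    print("site-mean M/P:", site_mean_mp(mp).round(3).to_dict())

    loadings = pd.DataFrame(model.rotated_loadings,
                            index=list(model.columns),
                            columns=[f"PC{i+1}" for i in range(model.retained)])
    loadings.loc["% of Total Variance"] = model.rotated_variance_pct()
    loadings.round(3).to_csv(OUT / "receptor_loadings.tsv", sep="\t")
    mp.to_csv(OUT / "receptor_mp_ratios.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
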