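"""Do the two morphospaces agree taxon by taxon?

Phylogenetic independent contrasts of each principal component are
correlated (through the origin) with the contrasts of its positionally
paired principal coordinate, over the k axes positive in both spaces.
Weak per-axis correlations alongside congruent disparity curves mean the
two character types disagree about individual taxon placement while
agreeing about the amount of variation per time bin.  Outputs to
results/contrasts/.
"""

from pathlib import Path

import pandas as pd

from dispartime import io as dio
from dispartime.contrasts import axis_correlations
from dispartime.ordination import OrdinationResult

ORD = Path("results/ordination")
CAL = Path("results/calibration")
FIX = Path("results/fixture")
OUT = Path("results/contrasts")
OUTGROUP = "t1"


def load_scores(path) -> OrdinationResult:
    df = pd.read_csv(path, index_col=0)
    arr = df.to_numpy()
    return OrdinationResult(
        taxa=list(df.index), scores=arr,
        axis_variances=arr.var(axis=0, ddof=1), method="scores",
    )


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    pc = load_scores(ORD / "scores_pca.csv")
    pco = load_scores(ORD / "scores_pcoa.csv")
    tree = dio.read_newick(CAL / "dated.nwk")
    tree.perturb_zero_branches()

    k = min(pc.n_positive_axes, pco.n_positive_axes)
    rows = axis_correlations(pc, pco, tree, k=k)
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "pic_correlations.csv", index=False)

    weak = (df["abs_r"] < 0.5).sum()
    print(f"PIC correlations over the first {k} axis pairs "
          f"(positive variance in both spaces):")
    print(f"  median |r| = {df['abs_r'].median():.3f}; "
          f"{weak}/{k} axes with |r| < 0.5")
    print(df.to_string(index=False, float_format=lambda v: f"{v:.3f}"))


if __name__ == "__main__":
    main()
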