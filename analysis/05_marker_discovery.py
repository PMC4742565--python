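"""One-vs-rest marker discovery per cluster with Gini importance.

For each named cluster an extremely-randomized-trees classifier is
trained against the rest of the cells; genes are ranked by Gini feature
importance and the per-cluster expressed fraction (TPM > 1) of the top
marker is reported.
"""

from pathlib import Path

import pandas as pd

from thrombotraj import markers
from thrombotraj.io import read_matrix_tsv

QC = Path("results/qc")
OUT = Path("results/markers")


def main() -> None:
    matrix = read_matrix_tsv(QC / "matrix_qc.tsv")
    stages = pd.read_csv("results/trajectory/clusters.csv", index_col=0).iloc[:, 0]
    OUT.mkdir(parents=True, exist_ok=True)
    rankings = markers.rank_all_markers(matrix, stages, n_trees=1000, seed=0)
    for cluster, ranking in rankings.items():
        ranking.ranking.rename("importance").to_csv(OUT / f"markers_{cluster}.csv")
        top = ranking.ranking.index[0]
        frac = markers.expression_fraction(matrix, stages, top)
        print(
            f"cluster {cluster}: top marker {top} "
            f"(importance {ranking.ranking.iloc[0]:.4f}; expressed fraction "
            + ", ".join(f"{k}={v:.2f}" for k, v in frac.items())
            + ")"
        )


if __name__ == "__main__":
    main()
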