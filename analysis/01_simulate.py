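"""Generate the default synthetic index-sorted dataset with ground truth.

Emulates a single-fish kidney-marrow sort of cd41:EGFP cells: 363 cells
on a five-state differentiation continuum plus three high-FSC/SSC
outliers, ~500 endogenous genes (monotone markers, three trend groups,
state programs, planted ohnolog pairs) and 20 spike-ins.
"""

from pathlib import Path

import pandas as pd

from thrombotraj import synthdata
from thrombotraj.io import write_matrix_mtx, write_matrix_tsv

OUT = Path("results/data")


def main() -> None:
    params = synthdata.GeneratorParams()
    matrix, meta, truth = synthdata.generate_dataset(params)
    OUT.mkdir(parents=True, exist_ok=True)
    write_matrix_tsv(matrix, OUT / "matrix.tsv")
    write_matrix_mtx(matrix, OUT / "mtx")
    meta.to_csv(OUT / "meta.csv")
    truth.cells.to_csv(OUT / "truth_cells.csv")
    truth.genes.to_csv(OUT / "truth_genes.csv")
    truth.ohnolog_pairs.to_csv(OUT / "truth_ohnolog_pairs.csv", index=False)
    print(
        f"wrote {matrix.shape[0]} cells x {matrix.shape[1]} genes "
        f"(seed {params.seed}) to {OUT}"
    )
    print(meta["population"].value_counts().to_string())


if __name__ == "__main__":
    main()
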