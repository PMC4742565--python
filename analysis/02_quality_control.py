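"""Cell/gene QC and TPM renormalization of the simulated plate set.

Cells with fewer than 50,000 paired reads or fewer than 150 expressed
genes (TPM > 1; 150 is the threshold scaled to the ~500-gene synthetic
world) are excluded; spike-ins are stripped, each cell is rescaled to
one million TPM, and genes above 1 TPM in fewer than three cells are
dropped.  Also records the endogenous/spike-in mRNA-content proxy.
"""

from pathlib import Path

import pandas as pd

from thrombotraj import qcnorm
from thrombotraj.io import read_matrix_tsv, write_matrix_tsv

DATA = Path("results/data")
OUT = Path("results/qc")


def main() -> None:
    matrix = read_matrix_tsv(DATA / "matrix.tsv")
    meta = pd.read_csv(DATA / "meta.csv", index_col=0)
    processed, meta_kept, report = qcnorm.run_qc(
        matrix, meta, thresholds=qcnorm.QcThresholds(min_reads=50_000, min_genes=150)
    )
    OUT.mkdir(parents=True, exist_ok=True)
    write_matrix_tsv(processed, OUT / "matrix_qc.tsv")
    meta_kept.to_csv(OUT / "meta_qc.csv")
    report["mrna_content"].to_csv(OUT / "mrna_content.csv")
    for cell, reason in report["cells_excluded"].items():
        print(f"excluded {cell}: {reason}")
    print(
        f"retained {report['cells_retained']}/{report['cells_in']} cells and "
        f"{report['genes_retained']}/{report['genes_in']} genes"
    )


if __name__ == "__main__":
    main()
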