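"""Shared fixtures: one default-scale dataset and its derived stages.

The expensive objects (default dataset, QC, ICA ordering, GPLVM fit) are
session-scoped so the acceptance tests and the module tests share them.
"""

import warnings

import numpy as np
import pytest

from thrombotraj import latentgp, qcnorm, synthdata, trajectory

warnings.filterwarnings("ignore", message="FastICA did not converge")

QC = qcnorm.QcThresholds(min_reads=50_000, min_genes=150)


@pytest.fixture(scope="session")
def default_dataset():
    return synthdata.generate_dataset(synthdata.GeneratorParams())


@pytest.fixture(scope="session")
def processed(default_dataset):
    matrix, meta, _ = default_dataset
    return qcnorm.run_qc(matrix, meta, thresholds=QC)


@pytest.fixture(scope="session")
def ordered(processed):
    proc, meta, _ = processed
    return trajectory.order_cells(proc, meta)


@pytest.fixture(scope="session")
def gplvm_fit(processed, ordered):
    proc, meta, _ = processed
    latent = latentgp.fit_gplvm_1d(proc, seed=0, restarts=3)
    return latentgp.align_orientation(latent, meta["fluorescence"])


@pytest.fixture(scope="session")
def small_dataset():
    return synthdata.generate_dataset(synthdata.small_params(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
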