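import numpy as np
import pandas as pd
import pytest

import triomix as tm
from triomix.layers import GRADES, sample_id


def make_layer(values: np.ndarray, name: str = "rna", scale: str = "log",
               features=None, patients=None, grades=GRADES) -> tm.OmicsLayer:
    """Build a layer from a (features x patients*grades) array, grade-major
    per patient in the order given."""
    values = np.asarray(values, dtype=float)
    n_feat = values.shape[0]
    if patients is None:
        n_pat = values.shape[1] // len(grades)
        patients = [f"P{i}" for i in range(1, n_pat + 1)]
    cols = [sample_id(p, g) for p in patients for g in grades]
    if features is None:
        features = [f"F{i}" for i in range(1, n_feat + 1)]
    return tm.OmicsLayer(name, pd.DataFrame(values, index=features, columns=cols),
                         scale)


def paired_layer(diff_per_patient, name: str = "rna",
                 grades=("osteophytic", "low")) -> tm.OmicsLayer:
    """Layer with two grades whose within-patient differences are given."""
    diffs = np.atleast_2d(np.asarray(diff_per_patient, dtype=float))
    n_feat, n_pat = diffs.shape
    vals = np.zeros((n_feat, n_pat * 2))
    vals[:, 0::2] = diffs  # first grade carries the difference
    return make_layer(vals, name=name, grades=grades)


@pytest.fixture(scope="session")
def small_dataset() -> tm.SimulatedDataset:
    """A quick dataset with planted effects shared across module tests."""
    cfg = tm.SimConfig(n_genes=400, n_proteins=150, probes_per_gene=3,
                       n_decoy_sets=20, decoy_set_size=20,
                       planted_sets=[tm.PlantedSet("planted_a", 25, 1.0)],
                       seed=11)
    return tm.generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_rna_results(small_dataset) -> tm.DifferentialResults:
    return tm.PairedDifferential(small_dataset.layers["rna"], "O_vs_L").fit()
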