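"""Shared setup for the analysis scripts.

The study dataset is a synthetic 13-day x 3-donor differentiation time
course with planted regulatory structure (2,000 DHSs of which 30% change,
300 target genes, 40 TFs in 5 modules), generated deterministically from
one seed so every numbered script sees the same data.  Desk-scale analysis
settings that differ from the genome-scale defaults (reduced elastic-net
grid, proportional TF-connectivity cutoff) live here too.
"""
from pathlib import Path

import numpy as np

from regmodkit import SimulationConfig, TimeCourseMatrix, generate_dataset
from regmodkit.devreg import quantile_normalize
from regmodkit.tfmodel import ElasticNetConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 42

STUDY_CONFIG = SimulationConfig(n_dhs=2000, n_genes=300, n_tf=40, seed=SEED)

# reduced hyperparameter search for desk-scale runs (the full published
# grid is 101 alphas x 100 lambdas x 100 repeats)
ENET_CONFIG = ElasticNetConfig(
    alpha_grid=np.linspace(0.0, 1.0, 11),
    lambda_grid=np.logspace(-5, 5, 20),
    n_repeats=20,
    seed=SEED,
)

# proportional analogue of the published >=200-DHS connectivity cutoff
# (52 of 214 TFs at 11,805 changing DHSs ~ 1.7%)
def connectivity_cutoff(n_changing_dhs: int) -> int:
    return max(5, round(0.017 * n_changing_dhs))


def get_dataset():
    return generate_dataset(STUDY_CONFIG)


def normalized(ds):
    """Quantile-normalized DHS and gene matrices."""
    dhs = TimeCourseMatrix(quantile_normalize(ds.dhs_matrix.values), ds.dhs_matrix.samples)
    gene = TimeCourseMatrix(quantile_normalize(ds.gene_matrix.values), ds.gene_matrix.samples)
    return dhs, gene
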