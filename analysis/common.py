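"""Shared study configuration for the numbered analysis scripts.

The synthetic trial emulates the motivating study's design: 43 clonal
genotypes x 4 replicates, 9 bean + 8 cherry geometric traits with
means and variance components anchored to the published ANOVA
summaries, and 4 latent divergence groups on a morphological gradient
(adjacent groups 4 within-SDs apart per trait).
"""

from pathlib import Path

import pandas as pd

from seedpheno.io import PhenotypeTable
from seedpheno.simulate import default_config, simulate_phenotypes

STUDY_SEED = 1234
RESULTS = Path(__file__).resolve().parent.parent / "results"
DATA_DIR = RESULTS / "data"


def study_config(seed: int = STUDY_SEED):
    return default_config(g=43, r=4, n_groups=4, delta=4.0, seed=seed)


def load_or_simulate():
    """Load the trial written by 01_simulate_trial.py, or regenerate it."""
    path = DATA_DIR / "phenotypes.csv"
    if path.exists():
        table = PhenotypeTable(pd.read_csv(path))
        labels_path = DATA_DIR / "true_groups.csv"
        labels = None
        if labels_path.exists():
            labels = pd.read_csv(labels_path).set_index("genotype")["group"]
        return table, labels
    table, truth = simulate_phenotypes(study_config())
    return table, truth.group_labels
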