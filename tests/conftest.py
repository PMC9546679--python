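import logging

import numpy as np
import pandas as pd
import pytest

from gcaxis.consensus import consensus_cluster, label_modules
from gcaxis.io import ExpressionMatrix, Unit
from gcaxis.preprocess import extract_signature_matrix, filter_low_expression
from gcaxis.simulate import SimulationConfig, simulate_cohort
from gcaxis.subtyping import assign_subtype, compute_axis_scores

logging.getLogger("gcaxis").setLevel(logging.ERROR)

COHORT_SEED = 7

PIPELINE_CONFIG = {
    "seed": COHORT_SEED,
    "simulate": {},  # default study conditions
    "consensus": {"k": 4, "n_reps": 100, "p_item": 0.8},
    "estimate": {
        "stromal_set": "GLYCOLYSIS_SIGNATURE",
        "immune_set": "CHOLESTEROL_SIGNATURE",
    },
}


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full pipeline run on the default synthetic cohort."""
    from gcaxis.pipeline import run_pipeline

    out = tmp_path_factory.mktemp("pipeline")
    return run_pipeline(PIPELINE_CONFIG, out)


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort shared across the suite."""
    return simulate_cohort(SimulationConfig(seed=COHORT_SEED))


@pytest.fixture(scope="session")
def signature_tumor(cohort):
    """Low-expression-filtered signature matrix restricted to tumor samples."""
    filtered, _ = filter_low_expression(cohort.expression)
    sig = extract_signature_matrix(
        filtered, cohort.gene_sets, ["GLYCOLYSIS_SIGNATURE", "CHOLESTEROL_SIGNATURE"]
    )
    return sig.subset_samples(cohort.tumor_samples)


@pytest.fixture(scope="session")
def consensus_k4(signature_tumor):
    """Consensus clustering of the signature genes at the planted k."""
    return consensus_cluster(signature_tumor, [4], n_reps=100, p_item=0.8, seed=11)[0]


@pytest.fixture(scope="session")
def modules(cohort, consensus_k4):
    return label_modules(
        consensus_k4.assignments,
        cohort.gene_sets,
        "GLYCOLYSIS_SIGNATURE",
        "CHOLESTEROL_SIGNATURE",
    )


@pytest.fixture(scope="session")
def subtype_calls(cohort, modules):
    scores = compute_axis_scores(cohort.expression, modules, cohort.tumor_samples)
    return assign_subtype(scores)


@pytest.fixture()
def small_matrix():
    """4 genes x 4 samples TPM matrix with simple values."""
    data = pd.DataFrame(
        np.array(
            [
                [10.0, 20.0, 30.0, 40.0],
                [5.0, 5.0, 5.0, 5.0],
                [1.0, 2.0, 1.0, 2.0],
                [100.0, 50.0, 25.0, 12.5],
            ]
        ),
        index=["G1", "G2", "G3", "G4"],
        columns=["S1", "S2", "S3", "S4"],
    )
    return ExpressionMatrix(data, Unit.TPM)


def planted_module_matrix(
    n_modules: int, genes_per_module: int, n_samples: int, noise_sd: float, seed: int
) -> tuple[ExpressionMatrix, dict[str, int]]:
    """Log-scale matrix with equal-sized co-expressed gene modules."""
    rng = np.random.default_rng(seed)
    factors = rng.normal(0.0, 1.0, (n_modules, n_samples))
    rows, names, truth = [], [], {}
    for m in range(n_modules):
        for i in range(genes_per_module):
            name = f"M{m}_{i:02d}"
            rows.append(5.0 + factors[m] + rng.normal(0.0, noise_sd, n_samples))
            names.append(name)
            truth[name] = m
    df = pd.DataFrame(rows, index=names, columns=[f"S{j}" for j in range(n_samples)])
    return ExpressionMatrix(df, Unit.LOG2TPM1), truth
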