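import warnings

import numpy as np
import pandas as pd
import pytest

import iquantdep as iq


@pytest.fixture(scope="session")
def default_run():
    """One full pipeline run at the benchmark condition, shared across tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cfg = iq.SimulationConfig(seed=1)
        psms, truth, collection = iq.generate_dataset(cfg)
        passed = iq.filter_fdr(iq.compute_fdr(psms))
        matrix = iq.quantile_normalize(iq.build_reporter_matrix(passed))
        proteins = iq.aggregate_proteins(iq.peptide_ratios(matrix))
        deps = iq.select_deps(proteins)
    return {
        "config": cfg,
        "psms": psms,
        "truth": truth,
        "collection": collection,
        "passed": passed,
        "matrix": matrix,
        "proteins": proteins,
        "deps": deps,
    }


@pytest.fixture
def six_psm_table():
    """Hand-built table: target scores {10,9,8,7}, decoy scores {8.5,6}."""
    return pd.DataFrame(
        {
            "psm_id": [f"PSM{i}" for i in range(6)],
            "peptide": ["AAAK", "CCCK", "DDDK", "EEEK", "FFFK", "GGGK"],
            "protein": ["P1", "P1", "P2", "P2", "REV_P1", "REV_P2"],
            "is_decoy": [False, False, False, False, True, True],
            "score": [10.0, 9.0, 8.0, 7.0, 8.5, 6.0],
            "replicate": [1] * 6,
            "i114": [100.0] * 6,
            "i115": [100.0] * 6,
            "i116": [100.0] * 6,
            "i117": [100.0] * 6,
        }
    )


def make_psm_table(rng, n_targets, n_decoys, target_mean=5.0, decoy_mean=0.0, sd=1.5):
    """Random small PSM score table with labels, for oracle comparisons."""
    n = n_targets + n_decoys
    return pd.DataFrame(
        {
            "psm_id": [f"PSM{i}" for i in range(n)],
            "peptide": ["PEPK"] * n,
            "protein": ["P1"] * n_targets + ["REV_P1"] * n_decoys,
            "is_decoy": [False] * n_targets + [True] * n_decoys,
            "score": np.concatenate(
                [
                    rng.normal(target_mean, sd, n_targets),
                    rng.normal(decoy_mean, sd, n_decoys),
                ]
            ),
            "replicate": 1,
            "i114": 1.0,
            "i115": 1.0,
            "i116": 1.0,
            "i117": 1.0,
        }
    )
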