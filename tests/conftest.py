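import numpy as np
import pandas as pd
import pytest

from constraintscope.constraint_core import oe_confidence_bounds


def make_constraint_frame(obs, exp, cds=None, symbols=None):
    """Canonical constraint frame from observed/expected LoF count arrays."""
    obs = np.asarray(obs, dtype=float)
    exp = np.asarray(exp, dtype=float)
    n = obs.size
    lo, up = oe_confidence_bounds(obs, exp)
    return pd.DataFrame(
        {
            "gene_symbol": symbols if symbols is not None else [f"G{i:04d}" for i in range(n)],
            "transcript_id": [f"T{i:04d}.1" for i in range(n)],
            "cds_length": cds if cds is not None else np.full(n, 2000, dtype=int),
            "obs_lof": obs,
            "exp_lof": exp,
            "loe": obs / exp,
            "loelf": lo,
            "loeuf": up,
            "obs_mis": obs * 10,
            "exp_mis": exp * 10,
            "moe": obs / exp,
            "moelf": lo,
            "moeuf": up,
            "lof_metrics_defined": True,
        }
    )


@pytest.fixture(scope="session")
def small_universe():
    """A 600-gene universe with a 30-gene depleted risk group."""
    from constraintscope.synthetic_data import GeneUniverseSpec, generate_gene_universe

    spec = GeneUniverseSpec(
        n_genes=600,
        group_fractions={"risk": 30 / 600},
        depletion_by_group={"risk": 0.2, "background": 1.0},
        seed=11,
    )
    return generate_gene_universe(spec)


@pytest.fixture(scope="session")
def pcps_panel():
    from constraintscope.constraint_core import load_pcps_panel

    return load_pcps_panel()
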