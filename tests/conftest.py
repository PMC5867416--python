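import numpy as np
import pandas as pd
import pytest

from oastrat.synthdata import SimulationDesign, simulate_counts, write_fixture_bundle


@pytest.fixture(scope="session")
def small_design() -> SimulationDesign:
    """A scaled-down cohort for fast unit tests."""
    return SimulationDesign(
        n_genes=300,
        n_control=6,
        n_groupA=8,
        n_groupB=8,
        n_shared_de=40,
        n_specificA=20,
        n_specificB=20,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_design):
    return simulate_counts(small_design)


@pytest.fixture(scope="session")
def default_cohort():
    """The full-size default design (10 control, 24 A, 18 B)."""
    return simulate_counts(SimulationDesign(seed=7))


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory, small_design):
    path = tmp_path_factory.mktemp("bundle")
    write_fixture_bundle(path, small_design)
    return path


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def toy_de_table(genes, lfcs, padjs, fc_min=1.5, fdr_max=0.10) -> pd.DataFrame:
    """Hand-built DE table with the DEG rule applied as stated."""
    lfcs = np.asarray(lfcs, dtype=float)
    padjs = np.asarray(padjs, dtype=float)
    return pd.DataFrame(
        {
            "baseMean": np.full(len(genes), 100.0),
            "log2FC": lfcs,
            "pvalue": padjs,
            "padj": padjs,
            "is_deg": (np.abs(lfcs) >= np.log2(fc_min)) & (padjs <= fdr_max),
        },
        index=pd.Index(genes, name="gene"),
    )
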