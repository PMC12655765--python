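from pathlib import Path

import pytest

import pgxnet as px

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def small_blueprint() -> px.TargetBlueprint:
    return px.build_target_blueprint(
        n_drugs=10, n_genes=80, n_families=2,
        targets_per_drug=(5, 8), shared_fraction=0.8, seed=1,
    )


@pytest.fixture(scope="session")
def small_panel(small_blueprint) -> px.SyntheticPanel:
    """10 drugs, 80 genes, 60 cell lines, exact planted correlations."""
    return px.generate_panel(px.PanelConfig(
        n_genes=80, n_drugs=10, blueprint=small_blueprint, seed=3,
    ))


@pytest.fixture(scope="session")
def small_records(small_panel):
    return px.correlate_all(small_panel.expression, small_panel.activity)


@pytest.fixture(scope="session")
def smiles_path() -> Path:
    return DATA_DIR / "drug_structures.smi"
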