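import numpy as np
import pytest
from hypothesis import settings

from fusbbbd import glial, simulate as sim

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


def desk_cav_config(seed: int = 0, **overrides) -> sim.CavSimConfig:
    """Desk-scale sonication: same spectral structure as the full geometry
    (1.1 MHz fundamental, 1 Hz PRF) with shorter bursts and duration."""
    kwargs = dict(
        sampling_rate=10e6,
        burst_length=0.002,
        duration=30.0,
        seed=seed,
    )
    kwargs.update(overrides)
    return sim.CavSimConfig(**kwargs)


@pytest.fixture
def cav_config():
    return desk_cav_config(seed=11)


def panelled_expr_config(seed: int = 0, n_genes: int = 600) -> sim.ExprSimConfig:
    """Expression time course whose first genes are named after the shipped
    glial marker panels, with A2-dominant astrocyte effects at later hours."""
    panels = glial.load_default_panels()
    gene_ids = [f"gene{i:05d}" for i in range(n_genes)]
    assignments = {}
    idx = 0
    for p in panels:
        ids = []
        for g in p.genes:
            gene_ids[idx] = g
            ids.append(idx)
            idx += 1
        assignments[p.name] = tuple(ids)
    effects = {
        "pan_microglia": (0.5, 1.0, 1.5, 1.5, 1.5),
        "M1": (0.1, 0.3, 0.4, 0.3, 0.3),
        "M2": (0.1, 0.2, 0.3, 0.4, 0.3),
        "pan_astrocyte": (0.2, 1.0, 1.5, 1.8, 2.0),
        "A1": (0.1, 0.2, 0.5, 0.5, 0.5),
        "A2": (0.2, 0.8, 2.0, 2.0, 2.0),
    }
    return sim.ExprSimConfig(
        n_genes=n_genes,
        gene_ids=tuple(gene_ids),
        panel_assignments=assignments,
        panel_effects=effects,
        seed=seed,
    )


@pytest.fixture(scope="session")
def expr_dataset():
    matrix, truth = sim.gen_expression_dataset(panelled_expr_config(seed=7))
    return matrix, truth


@pytest.fixture(scope="session")
def de_results(expr_dataset):
    from fusbbbd.transcriptomics import TimecourseDEModel

    matrix, _ = expr_dataset
    return TimecourseDEModel(matrix).fit()
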