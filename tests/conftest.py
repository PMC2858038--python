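import numpy as np
import pytest

from rnaclad import (
    CharacterDef,
    CharacterMatrix,
    SimulationConfig,
    add_ancestor,
    simulate_matrix,
    simulate_tree,
)


def make_matrix(values, kinds=None, taxa=None, ancestor=False):
    """Small helper: integer grid -> CharacterMatrix."""
    values = np.asarray(values, np.int16)
    n, c = values.shape
    kinds = kinds or ["stabilizing"] * c
    chars = [
        CharacterDef(
            f"c{j + 1}",
            k,
            metric="stem_bp" if k == "stabilizing" else "loop_nt",
            ordered=k != "sequence",
        )
        for j, k in enumerate(kinds)
    ]
    taxa = taxa or [f"t{i + 1}" for i in range(n)]
    M = CharacterMatrix(taxa, chars, values)
    return add_ancestor(M) if ancestor else M


@pytest.fixture(scope="session")
def erosion_sim():
    """One erosion-model replicate: all substructures ancestrally present."""
    cfg = SimulationConfig(
        n_taxa=12,
        n_stem_chars=10,
        n_loop_chars=6,
        accretion_schedule=[0] * 16,
        change_rate=0.3,
        loss_prob=0.05,
        seed=11,
    )
    tree = simulate_tree(cfg)
    M, truth = simulate_matrix(cfg, tree)
    return cfg, tree, M, truth


@pytest.fixture(scope="session")
def accretion_sim():
    """One accretion replicate under the default study conditions."""
    cfg = SimulationConfig(seed=7)
    tree = simulate_tree(cfg)
    M, truth = simulate_matrix(cfg, tree)
    return cfg, tree, M, truth
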