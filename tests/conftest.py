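import numpy as np
import pandas as pd
import pytest

from decnet import generate_reference_panel, simulate_mixtures


@pytest.fixture(scope="session")
def small_panel():
    """k=2 panel: stroma + cancer, two expression variants, 100 probes."""
    return generate_reference_panel(k=2, n_probes=100, n_genes=50, variant_fold=10, seed=1)


@pytest.fixture(scope="session")
def panel4():
    """k=4 panel mirroring the four-reference study design."""
    return generate_reference_panel(k=4, n_probes=400, n_genes=60, variant_fold=10, seed=1)


@pytest.fixture(scope="session")
def mixtures4(panel4):
    """100 noisy mixtures (50 per cancer variant) from the k=4 panel."""
    return simulate_mixtures(panel4, n_per_variant=50, noise_precision=100, seed=2)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def toy_expression_groups(
    seed: int,
    n_genes: int = 200,
    n_de: int = 40,
    fold: float = 2.5,
    n_per_group: int = 30,
    noise_frac: float = 0.1,
    k: int = 3,
):
    """Two sample groups with a fold-change planted in cancer cells only.

    Returns (G_hi, P_hi, G_lo, P_lo, planted_gene_set).
    """
    cell_types = ["cancer", "stroma", "immune", "epithelial"][:k]
    master = np.random.default_rng(seed)
    base = master.lognormal(3, 1, (n_genes, k))
    E_lo = base
    E_hi = base.copy()
    E_hi[:n_de, 0] *= fold

    def mix(E, sub_seed, tag):
        r = np.random.default_rng(sub_seed)
        P = r.dirichlet(np.ones(k), size=n_per_group).T
        G = E @ P
        G = np.clip(G * (1 + noise_frac * r.standard_normal(G.shape)), 0, None)
        cols = [f"{tag}{i:02d}" for i in range(n_per_group)]
        genes = [f"g{i:04d}" for i in range(n_genes)]
        return (
            pd.DataFrame(G, index=genes, columns=cols),
            pd.DataFrame(P, index=cell_types, columns=cols),
        )

    G_hi, P_hi = mix(E_hi, seed + 1, "hi")
    G_lo, P_lo = mix(E_lo, seed + 2, "lo")
    planted = {f"g{i:04d}" for i in range(n_de)}
    return G_hi, P_hi, G_lo, P_lo, planted
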