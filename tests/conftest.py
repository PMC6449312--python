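import numpy as np
import pandas as pd
import pytest

from soypop.genio import GenotypeMatrix


def _make_matrix(calls, samples=None, pos=None, chrom="1"):
    calls = np.asarray(calls, dtype=np.int8)
    n, L = calls.shape
    snps = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos if pos is not None else np.arange(1, L + 1),
            "id": [f"s{j}" for j in range(L)],
            "ref": "A",
            "alt": "C",
        }
    )
    samples = samples or [f"x{i}" for i in range(n)]
    return GenotypeMatrix(samples, snps, calls)


@pytest.fixture
def gm():
    """Factory building a GenotypeMatrix from a raw dosage array."""
    return _make_matrix


@pytest.fixture(scope="session")
def default_collection():
    """The standard synthetic collection: 4 wild subpops, a swept
    domesticated derivative, hybrids, duplicates, light missingness."""
    from soypop.sim import SimConfig, simulate_collection

    cfg = SimConfig(n_snps=3000, seed=2, missing_rate=0.01)
    m, meta, truth = simulate_collection(cfg)
    return m, meta.set_index("sample_id", drop=False), truth


@pytest.fixture(scope="session")
def hybrid_panel_fit():
    """Two-pool hybrid panel with a converged K=2 ancestry fit."""
    from soypop import structure
    from soypop.sim import simulate_hybrid_panel

    m, labels, q_true = simulate_hybrid_panel(
        n_snps=3000, n_per_pool=50, pool_F=0.3, n_hybrids=10,
        q_range=(0.35, 0.65), seed=101,
    )
    model = structure.fit_admixture(m, K=2, seed=102)
    is_dom = np.array([labels[s] == "pool1" for s in m.samples])
    q_dom = structure.dominant_cluster_fractions(model, is_dom)
    return m, labels, q_true, model, pd.Series(q_dom, index=m.samples)


@pytest.fixture(scope="session")
def origin_panel():
    """40-leaf collection for domestication-origin recovery: 4 wild
    subpops (6 each) + 16 swept domesticates, no contaminants."""
    from soypop.sim import SimConfig, simulate_collection

    cfg = SimConfig(
        n_snps=3000, n_per_wild_subpop=6, n_domesticated=16,
        n_hybrids=0, n_duplicate_pairs=0, missing_rate=0.0, seed=11,
    )
    m, meta, truth = simulate_collection(cfg)
    return m, meta.set_index("sample_id", drop=False), truth


@pytest.fixture(scope="session")
def dedup_collection():
    """60-sample, 2000-SNP collection with 5 planted duplicate pairs at
    1.0% discordance."""
    from soypop.sim import SimConfig, simulate_collection

    cfg = SimConfig(
        n_snps=2000, n_per_wild_subpop=10, n_domesticated=15,
        n_hybrids=0, n_duplicate_pairs=5, duplicate_discordance=0.01,
        missing_rate=0.0, seed=401,
    )
    m, meta, truth = simulate_collection(cfg)
    return m, truth
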