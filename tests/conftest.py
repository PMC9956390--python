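import itertools

import numpy as np
import pytest

from impbarcode.panel_io import HaplotypePanel, Site
from impbarcode.popsim import SimConfig


def make_panel(alleles, positions=None, groups=None, chrom="1"):
    """Handmade panel: alleles (S, N), optional positions and group labels."""
    alleles = np.asarray(alleles, dtype=np.int8)
    S, N = alleles.shape
    if positions is None:
        positions = [100 * (i + 1) for i in range(S)]
    if groups is None:
        groups = ["G1"] * N
    hap_ids = [f"S{c // 2}_{c % 2 + 1}" for c in range(N)]
    sites = [Site(chrom, int(p), "A", "G") for p in positions]
    return HaplotypePanel(sites=sites, alleles=alleles, haplotype_ids=hap_ids,
                          groups={h: g for h, g in zip(hap_ids, groups)})


def brute_force_posteriors(obs, panel, params):
    """Exhaustive path-sum oracle for the copying-model posteriors.

    Enumerates every hidden donor path over the panel's sites, multiplying
    initial (uniform over the recombination-scale count), transition
    (stay 1-q plus uniform jump q/n_total) and emission (1-eps match / eps
    mismatch) weights, then marginalises per site.  Independent of the
    scaled forward-backward implementation it checks.
    """
    obs = np.asarray(obs)
    S, N = panel.alleles.shape
    n_total = params.n_total or N
    g = np.diff(params.morgans(panel.positions))
    q = 1.0 - np.exp(-4.0 * params.ne * g / n_total)
    eps = params.error_rate
    emit = np.where(panel.alleles == obs[:, None], 1.0 - eps, eps)
    post = np.zeros((S, N))
    for path in itertools.product(range(N), repeat=S):
        w = emit[0, path[0]] / n_total
        for i in range(1, S):
            trans = q[i - 1] / n_total + (1.0 - q[i - 1]) * (path[i] == path[i - 1])
            w *= trans * emit[i, path[i]]
        for i, k in enumerate(path):
            post[i, k] += w
    return post / post.sum(axis=1, keepdims=True)


@pytest.fixture(scope="session")
def small_config():
    """A quick-to-run admixture scenario used by several integration tests."""
    return SimConfig(n_groups=3, haps_per_group=30, founder_count=8,
                     n_sites=800, chrom_length=1_600_000, fst=0.15,
                     admix_proportions=(0.6, 0.3, 0.1),
                     tract_mean_bp=400_000, n_targets=8,
                     private_rare_per_group=10, seed=11)


@pytest.fixture(scope="session")
def small_scenario(small_config):
    from impbarcode import pipeline

    return pipeline.simulate_scenario(small_config)


@pytest.fixture(scope="session")
def small_first_pass(small_scenario):
    from impbarcode import pipeline

    return pipeline.first_pass(small_scenario)
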