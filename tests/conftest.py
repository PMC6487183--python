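import numpy as np
import pytest

import virionkit as vk


@pytest.fixture(scope="session")
def small_params():
    """Two small genomes: cheap community for read-level tests."""
    return vk.SimParams(
        n_genomes=2, genome_length_range=(20_000, 40_000), seed=11
    )


@pytest.fixture(scope="session")
def small_community(small_params):
    return vk.make_community(small_params, n_strains=1)


@pytest.fixture(scope="session")
def strain_cloud():
    """50-strain cloud at pi=0.01 around a 50 kbp parent, no islands."""
    parent = vk.generate_genome(50_000, 0.45, seed=7, id="cloud_parent")
    return vk.make_strain_cloud(parent, target_pi=0.01, n_strains=50, seed=8)


def pairwise_pi(strains):
    """Brute-force mean pairwise per-site difference between strains."""
    arrs = [np.frombuffer(s.seq.encode(), dtype=np.uint8) for s in strains]
    diffs = []
    for i in range(len(arrs)):
        for j in range(i + 1, len(arrs)):
            diffs.append(float(np.mean(arrs[i] != arrs[j])))
    return float(np.mean(diffs))
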