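import numpy as np
import pandas as pd
import pytest

from beakrates import simulate
from beakrates.tree import PhyloTree


@pytest.fixture(scope="session")
def template():
    return simulate.beak_template()


@pytest.fixture(scope="session")
def balanced4():
    return PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture(scope="session")
def star8():
    """True star tree (root polytomy, equal branch lengths): C = I."""
    tips = ",".join(f"t{i}:1.0" for i in range(1, 9))
    return PhyloTree.from_newick(f"({tips});")


def random_binary_tree(n, rng, min_len=0.2, max_len=2.0):
    """Random topology by successive pairwise joins; branch lengths uniform."""
    parent = [-1] * n
    lengths = list(rng.uniform(min_len, max_len, n))
    labels = [f"t{i}" for i in range(n)]
    avail = list(range(n))
    while len(avail) > 1:
        i = avail.pop(int(rng.integers(len(avail))))
        j = avail.pop(int(rng.integers(len(avail))))
        new = len(parent)
        parent.append(-1)
        lengths.append(float(rng.uniform(min_len, max_len)))
        labels.append(None)
        parent[i] = parent[j] = new
        avail.append(new)
    lengths[avail[0]] = 0.0
    return PhyloTree(np.array(parent), np.array(lengths), labels)


def dense_mvbm_loglik(tree, traits: pd.DataFrame, rates=None):
    """Independent oracle: explicit kron(Sigma, C) MVN profile log-density."""
    order = list(traits.index)
    scaled = PhyloTree(tree.parent.copy(), np.ones_like(tree.lengths), list(tree.labels))
    eff = np.ones(tree.n_nodes) if rates is None else np.asarray(rates, float)
    scaled.lengths = tree.lengths * eff
    scaled.lengths[tree.root] = 0.0
    C = scaled.vcv(order=order)
    X = traits.to_numpy(float)
    n, p = X.shape
    Ci = np.linalg.inv(C)
    one = np.ones(n)
    a = (one @ Ci @ X) / (one @ Ci @ one)
    R = X - a
    Sig = R.T @ Ci @ R / n
    _, ld_sig = np.linalg.slogdet(Sig)
    _, ld_c = np.linalg.slogdet(C)
    ll = -0.5 * (n * p * np.log(2 * np.pi) + p * ld_c + n * ld_sig + n * p)
    return ll, Sig, a
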