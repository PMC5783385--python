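import numpy as np
import pytest

from pacavoc import phylo, synth


@pytest.fixture(scope="session")
def element_table():
    """400-row synthetic element table drawn from the published per-type
    parameter distributions (50 per call type)."""
    return synth.generate_element_table(n_per_type=50, seed=11)


@pytest.fixture(scope="session")
def seven_species_tree():
    return phylo.nee_branch_lengths(phylo.load_caviomorph_tree(include_focal=False))


def random_binary_tree(rng, n_tips, min_bl=0.05):
    """Random rooted binary topology with exponential branch lengths."""
    nodes = [phylo.Node(f"t{i}", length=min_bl + rng.exponential(1.0)) for i in range(n_tips)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(phylo.Node(children=[a, b], length=min_bl + rng.exponential(1.0)))
    root = nodes[0]
    root.length = None
    return phylo.Phylogeny(root)


def loo_refit_oracle(table, feats):
    """Literal leave-one-out refit loop, re-implemented with raw numpy
    (standardize, generalized eigensolve, nearest centroid) independently of
    the package's classifier code. Returns the confusion matrix."""
    import math

    import pandas as pd
    import scipy.linalg

    feats = list(feats)
    classes = sorted(table["call_type"].unique())
    oracle = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    x_all = table[feats].to_numpy()
    y_all = table["call_type"].to_numpy()
    n = len(table)
    for i in range(n):
        mask = np.arange(n) != i
        xt, yt = x_all[mask], y_all[mask]
        mu, sd = xt.mean(axis=0), xt.std(axis=0, ddof=1)
        z = (xt - mu) / sd
        grand = z.mean(axis=0)
        sw = np.zeros((len(feats), len(feats)))
        sb = np.zeros_like(sw)
        for c in classes:
            zc = z[yt == c]
            d = zc - zc.mean(axis=0)
            sw += d.T @ d
            sb += len(zc) * np.outer(zc.mean(axis=0) - grand, zc.mean(axis=0) - grand)
        evals, evecs = scipy.linalg.eigh(sb, sw)
        order = np.argsort(evals)[::-1][: len(classes) - 1]
        axes = evecs[:, order].T
        for k in range(axes.shape[0]):
            wv = axes[k] @ sw @ axes[k] / (len(z) - len(classes))
            axes[k] /= math.sqrt(wv)
            j = int(np.argmax(np.abs(axes[k])))
            if axes[k][j] < 0:
                axes[k] = -axes[k]
        scores = z @ axes.T
        cents = np.vstack([scores[yt == c].mean(axis=0) for c in classes])
        zi = (x_all[i] - mu) / sd
        si = zi @ axes.T
        pred = classes[int(np.argmin(((si - cents) ** 2).sum(axis=1)))]
        oracle.loc[y_all[i], pred] += 1
    return oracle


def gls_contrast_oracle(tree, traits):
    """Independent contrasts via explicit Brownian GLS algebra.

    For each internal node, the ancestral value of each child subtree is
    estimated by generalized least squares under the Brownian covariance of
    that subtree's tips (shared path length from the subtree root), with
    estimation variance 1 / (1' V^-1 1); the contrast is the difference of
    the two estimates standardized by the total variance of that
    difference. Matrix-based and recursion-free, so it is an independent
    check of the pruning recursion.
    """

    def subtree_mean_var(node):
        tips = node.tip_labels()
        if len(tips) == 1:
            return float(traits[tips[0]]), 0.0
        # path length from `node` down to each tip, and shared paths
        paths = {}

        def collect(n, acc):
            if n.is_tip:
                paths[n.label] = acc + [n]
                return
            for c in n.children:
                collect(c, acc + [n])

        collect(node, [])
        labels = list(tips)
        v = np.zeros((len(labels), len(labels)))
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                shared = [m for m in paths[a] if m in paths[b] and m is not node]
                v[i, j] = sum(m.length for m in shared)
            v[i, i] = sum(m.length for m in paths[a] if m is not node)
        vinv = np.linalg.inv(v)
        one = np.ones(len(labels))
        x = np.array([traits[l] for l in labels])
        w = one @ vinv
        mean = float(w @ x / (w @ one))
        var = float(1.0 / (w @ one))
        return mean, var

    out = {}
    for node in tree.root.postorder():
        if node.is_tip:
            continue
        c1, c2 = node.children
        m1, v1 = subtree_mean_var(c1)
        m2, v2 = subtree_mean_var(c2)
        den = np.sqrt(c1.length + v1 + c2.length + v2)
        out[frozenset(node.tip_labels())] = (m1 - m2) / den
    return out
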