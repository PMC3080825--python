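"""Shared fixtures and independent scoring oracles.

The oracles here deliberately avoid the library's vectorised scoring path:
the prequential oracle multiplies sequential Dirichlet-multinomial
predictive probabilities row by row, and the generic two-node scorer builds
each family's counts by explicit loops, so they can certify the closed-form
log-gamma implementation.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from epibn import GenotypeDataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def four_row_dataset():
    """Tiny fixture whose family counts are easy to tally by hand."""
    return GenotypeDataset(
        ["S1", "S2"],
        np.array([[0, 2], [1, 1], [0, 0], [2, 1]]),
        np.array([1, 0, 1, 0]),
    )


def random_dataset(rng, m=6, n=3):
    return GenotypeDataset(
        [f"S{i + 1}" for i in range(n)],
        rng.integers(0, 3, size=(m, n)),
        rng.integers(0, 2, size=m),
    )


def prequential_logml(genotypes, phenotype, parents, a):
    """Sequential predictive product for the disease family, natural log.

    ``a`` is the (2, 3**k) pseudo-count table.  Independent of the gamma
    closed form: each row's probability is (a + s) / (a_col + s_col) at the
    counts accumulated so far.
    """
    a = np.asarray(a, dtype=float)
    s = np.zeros_like(a)
    total = 0.0
    for row, y in zip(genotypes, phenotype):
        j = 0
        for p in parents:
            j = j * 3 + int(row[p])
        total += math.log((a[y, j] + s[y, j]) / (a[:, j].sum() + s[:, j].sum()))
        s[y, j] += 1
    return total


def loop_family_logml(s, a):
    """Direct double-loop evaluation of the Dirichlet-multinomial marginal."""
    s = np.asarray(s, dtype=float)
    a = np.asarray(a, dtype=float)
    total = 0.0
    for j in range(s.shape[1]):
        total += math.lgamma(a[:, j].sum()) - math.lgamma(a[:, j].sum() + s[:, j].sum())
        for k in range(s.shape[0]):
            total += math.lgamma(a[k, j] + s[k, j]) - math.lgamma(a[k, j])
    return total


def two_node_scores(geno_col, pheno, alpha=None):
    """Generic scorer for both orientations of the two-node network (SNP, D).

    Returns (score of S->D, score of D->S), each the sum of the root family
    and the child-given-parent family marginal likelihoods; every family's
    counts are tallied by explicit loops.  ``alpha=None`` means K2 priors.
    """
    geno_col = np.asarray(geno_col)
    pheno = np.asarray(pheno)

    def hyper(r, q):
        if alpha is None:
            return np.ones((r, q))
        return np.full((r, q), alpha / (r * q))

    root_s = np.zeros((3, 1))
    for g in geno_col:
        root_s[g, 0] += 1
    d_given_s = np.zeros((2, 3))
    s_given_d = np.zeros((3, 2))
    root_d = np.zeros((2, 1))
    for g, y in zip(geno_col, pheno):
        d_given_s[y, g] += 1
        s_given_d[g, y] += 1
        root_d[y, 0] += 1
    forward = loop_family_logml(root_s, hyper(3, 1)) + loop_family_logml(d_given_s, hyper(2, 3))
    reverse = loop_family_logml(root_d, hyper(2, 1)) + loop_family_logml(s_given_d, hyper(3, 2))
    return forward, reverse
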