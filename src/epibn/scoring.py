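"""Scoring criteria for DDAG epistasis models.

All criteria score a DDAG — a Bayesian network in which k parent SNPs point
into the binary disease node D — from the family sufficient statistics:

* **Bayesian scores** (K2 and BDeu(alpha)): the log marginal likelihood of
  the data under Dirichlet parameter priors, computed per family as

      sum_j [ lnG(a_j.) - lnG(a_j. + s_j.) + sum_k ( lnG(a_jk + s_jk) - lnG(a_jk) ) ]

  where ``s_jk`` counts child state k under joint parent state j, ``a_jk``
  are Dirichlet pseudo-counts and ``lnG`` is the log-gamma function.  K2
  sets every a_jk = 1; BDeu sets a_jk = alpha / (r q) so that Markov
  equivalent structures receive equal scores and ``alpha`` acts as a prior
  equivalent sample size (larger alpha = weaker implicit complexity
  penalty).  Higher is better.

* **MDL scores**: a structure penalty in bits plus the data-encoding length
  ``m * H(child | parents)`` estimated from the data.  Penalty variants:
  ``suzuki`` charges (d/2) log2 m per node with d free parameters; ``aic``
  charges d bits flat; ``epi`` is the BNMBL penalty tailored to DDAGs,
  (3^k/2) log2(m / 3^k) + k log2 m, which prices each disease parameter at
  the expected per-cell sample size m/3^k; ``none`` charges nothing.  Lower
  is better.

* **MML**: the K2 log2-score minus a (d/2) log2 m parameter penalty.
  Higher is better.

MDL and MML come in two versions.  Version 1 models all n SNPs as present,
so only the disease node's penalty varies across models; version 2 models
only the k parent SNPs, so their parameter penalties enter too.  The
version split concerns the structure penalty only.

A note on SNP family terms.  In a DDAG every SNP is a root node, so a SNP's
family term (its root-family marginal likelihood, or its marginal encoding
length) has the same value in every model that contains the SNP, and the
sum over all n SNPs is a model-independent constant.  Model comparison is
therefore carried out on the disease family alone: adding per-parent root
terms instead would act as an enormous spurious penalty (roughly the m x
H(SNP) data cost of each parent) that no data signal could overcome, and
would make criteria that demonstrably select multi-SNP models always pick a
single parent.  :func:`log_family_marginal` remains fully general, so joint
multi-family networks can still be composed from it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .io import DDAG, FamilyCounts, GenotypeDataset, family_counts, snp_marginal_counts

__all__ = [
    "Hyperparameters",
    "ScoreReport",
    "Criterion",
    "log_family_marginal",
    "k2_hyper",
    "bdeu_hyper",
    "score_bayesian",
    "encoding_length_bits",
    "dag_penalty_bits",
    "score_mdl",
    "score_mml",
    "get_criterion",
    "available_criteria",
]

_LN2 = math.log(2.0)

HIGHER = "higher-better"
LOWER = "lower-better"


@dataclass(frozen=True)
class Hyperparameters:
    """Dirichlet pseudo-counts for one family, shape (r, q) matching the counts."""

    a: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        if (a <= 0).any():
            raise ValueError("Dirichlet hyperparameters must be strictly positive")
        object.__setattr__(self, "a", a)


@dataclass(frozen=True)
class ScoreReport:
    criterion_id: str
    value: float
    orientation: str  # HIGHER or LOWER


def k2_hyper(r: int, q: int) -> Hyperparameters:
    """The K2 prior: every pseudo-count equal to 1 (uniform parameter prior)."""
    if r < 1 or q < 1:
        raise ValueError("r and q must be >= 1")
    return Hyperparameters(np.ones((r, q)))


def bdeu_hyper(alpha: float, r: int, q: int) -> Hyperparameters:
    """The BDeu prior: a_jk = alpha / (r q); entries sum to alpha."""
    if alpha <= 0:
        raise ValueError("prior equivalent sample size alpha must be > 0")
    if r < 1 or q < 1:
        raise ValueError("r and q must be >= 1")
    return Hyperparameters(np.full((r, q), alpha / (r * q)))


def _family_logml(s: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Natural-log Dirichlet-multinomial marginal likelihood of one family.

    ``s`` has shape (..., r, q); ``a`` broadcasts against it.  Vectorised over
    leading axes so batches of models are scored in one call.
    """
    aj = np.asarray(a).sum(axis=-2)
    sj = s.sum(axis=-2)
    return (
        (gammaln(aj) - gammaln(aj + sj)).sum(axis=-1)
        + (gammaln(a + s) - gammaln(a)).sum(axis=(-2, -1))
    )


def log_family_marginal(counts: FamilyCounts, hyper: Hyperparameters) -> float:
    """Natural-log marginal likelihood of one family under a Dirichlet prior."""
    if hyper.a.shape != counts.s.shape:
        raise ValueError(f"hyperparameter shape {hyper.a.shape} != counts shape {counts.s.shape}")
    return float(_family_logml(counts.s.astype(float), hyper.a))


def _encoding_bits(s: np.ndarray) -> np.ndarray:
    """m * H(child | parents) in bits from counts of shape (..., r, q)."""
    s = np.asarray(s, dtype=float)
    sj = s.sum(axis=-2, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = s * (np.log2(s) - np.log2(sj))
    return -np.where(s > 0, term, 0.0).sum(axis=(-2, -1))


def encoding_length_bits(counts: FamilyCounts) -> float:
    """Bits needed to encode the child data given its parents.

    Equals m times the empirical conditional entropy of the child given the
    joint parent state; empty parent states contribute zero bits.
    """
    return float(_encoding_bits(counts.s))


def dag_penalty_bits(k: int, m: int, variant: str = "suzuki", version: str = "v2") -> float:
    """Structure penalty in bits for a DDAG with k parent SNPs and m data items.

    Parameter counts: the binary disease node has 3**k free parameters (one
    per joint parent state); each ternary parent SNP has 2.  Version 1
    charges the disease node only; version 2 adds the k parent SNPs.
    """
    if k < 0 or m < 1:
        raise ValueError("need k >= 0 and m >= 1")
    if version not in ("v1", "v2"):
        raise ValueError(f"unknown version {version!r}")
    q = 3 ** k
    if variant == "none":
        return 0.0
    if variant == "suzuki":
        pen = (q / 2.0) * math.log2(m)
        if version == "v2":
            pen += k * math.log2(m)  # (2/2) * log2 m per parent SNP
        return pen
    if variant == "aic":
        pen = float(q)
        if version == "v2":
            pen += 2.0 * k
        return pen
    if variant == "epi":
        if m < q:
            warnings.warn(
                f"BNMBL penalty with m={m} < 3^k={q}: expected per-cell sample "
                "size below 1 makes the disease term negative",
                RuntimeWarning,
                stacklevel=2,
            )
        pen = (q / 2.0) * math.log2(m / q)
        if version == "v2":
            pen += k * math.log2(m)
        return pen
    raise ValueError(f"unknown MDL penalty variant {variant!r}")


# ---------------------------------------------------------------------------
# Criterion objects


class Criterion:
    """One scoring criterion, exposing a batch interface used by the search.

    A model's score decomposes as a disease-family term (depending on the
    full joint counts) plus an additive per-parent-SNP term that depends
    only on that SNP's marginal genotype counts, so the per-SNP terms are
    precomputed once per dataset.
    """

    id: str
    orientation: str

    def disease_scores(self, s: np.ndarray, k: int, m: int) -> np.ndarray:
        """Score contribution of the disease family; ``s`` has shape (N, 2, 3**k)."""
        raise NotImplementedError

    def snp_terms(self, snp_counts: np.ndarray, m: int) -> np.ndarray:
        """Per-SNP additive contribution, shape (n,), from (n, 3) marginal counts."""
        raise NotImplementedError

    def oriented(self, values: np.ndarray) -> np.ndarray:
        """Map raw values to a 'larger is better' scale for ranking."""
        return values if self.orientation == HIGHER else -values

    def score(self, dataset: GenotypeDataset, ddag: DDAG) -> ScoreReport:
        fc = family_counts(dataset, ddag)
        value = float(self.disease_scores(fc.s[None].astype(float), ddag.k, dataset.m)[0])
        if ddag.k:
            counts = snp_marginal_counts(dataset)[list(ddag.parent_set)]
            value += float(self.snp_terms(counts, dataset.m).sum())
        return ScoreReport(self.id, value, self.orientation)


class BayesianCriterion(Criterion):
    """K2 or BDeu(alpha) log marginal likelihood of the disease family.

    Every SNP is a root node whose family term is identical across models,
    so the model-dependent part of the network's marginal likelihood is the
    disease family alone (see the module docstring).
    """

    orientation = HIGHER

    def __init__(self, alpha: float | None = None):
        if alpha is not None and alpha <= 0:
            raise ValueError("prior equivalent sample size alpha must be > 0")
        self.alpha = alpha
        self.id = "k2" if alpha is None else f"bdeu:{alpha:g}"

    def disease_scores(self, s: np.ndarray, k: int, m: int) -> np.ndarray:
        q = 3 ** k
        if self.alpha is None:
            a = np.ones((2, q))
        else:
            a = np.full((2, q), self.alpha / (2 * q))
        return _family_logml(s, a)

    def snp_terms(self, snp_counts: np.ndarray, m: int) -> np.ndarray:
        return np.zeros(snp_counts.shape[0])


class MdlCriterion(Criterion):
    """MDL bit total: DAG penalty + conditional-entropy encoding of the disease.

    The two versions differ only in the structure penalty (version 2 adds the
    parent SNPs' parameter bits); every MDL variant encodes the data the
    same way, through the disease family.
    """

    orientation = LOWER

    def __init__(self, variant: str, version: str = "v2"):
        if variant not in ("suzuki", "aic", "epi", "none"):
            raise ValueError(f"unknown MDL variant {variant!r}")
        self.variant = variant
        self.version = "v1" if variant == "none" else version
        self.id = "mdl-none" if variant == "none" else f"mdl-{variant}-{self.version}"

    def disease_scores(self, s: np.ndarray, k: int, m: int) -> np.ndarray:
        return _encoding_bits(s) + dag_penalty_bits(k, m, self.variant, self.version)

    def snp_terms(self, snp_counts: np.ndarray, m: int) -> np.ndarray:
        return np.zeros(snp_counts.shape[0])


class MmlCriterion(Criterion):
    """MML: the K2 score in log2 space minus a (d/2) log2 m parameter penalty."""

    orientation = HIGHER

    def __init__(self, version: str = "v1"):
        if version not in ("v1", "v2"):
            raise ValueError(f"unknown version {version!r}")
        self.version = version
        self.id = f"mml-{version}"

    def disease_scores(self, s: np.ndarray, k: int, m: int) -> np.ndarray:
        q = 3 ** k
        pen = (q / 2.0) * math.log2(m)
        if self.version == "v2":
            pen += k * math.log2(m)
        return _family_logml(s, np.ones((2, q))) / _LN2 - pen

    def snp_terms(self, snp_counts: np.ndarray, m: int) -> np.ndarray:
        return np.zeros(snp_counts.shape[0])


def score_bayesian(dataset: GenotypeDataset, ddag: DDAG, scheme: str = "k2") -> ScoreReport:
    """Bayesian score of a DDAG; ``scheme`` is ``"k2"`` or ``"bdeu:<alpha>"``."""
    crit = get_criterion(scheme)
    if not isinstance(crit, BayesianCriterion):
        raise ValueError(f"{scheme!r} is not a Bayesian scheme")
    return crit.score(dataset, ddag)


def score_mdl(dataset: GenotypeDataset, ddag: DDAG, variant: str = "suzuki",
              version: str = "v2") -> ScoreReport:
    return MdlCriterion(variant, version).score(dataset, ddag)


def score_mml(dataset: GenotypeDataset, ddag: DDAG, version: str = "v1") -> ScoreReport:
    return MmlCriterion(version).score(dataset, ddag)


def get_criterion(criterion_id: str) -> Criterion:
    """Resolve a string id to a criterion object.

    Recognised ids: ``k2``; ``bdeu:<alpha>`` (also ``bdeu:alpha=<alpha>``);
    ``mdl-{suzuki,aic,epi}-{v1,v2}``; ``mdl-none``; ``mml-{v1,v2}``.
    """
    cid = criterion_id.strip().lower()
    if cid == "k2":
        return BayesianCriterion()
    if cid.startswith("bdeu:"):
        arg = cid.split(":", 1)[1]
        for prefix in ("alpha=", "a="):
            if arg.startswith(prefix):
                arg = arg[len(prefix):]
        return BayesianCriterion(alpha=float(arg))
    if cid == "mdl-none":
        return MdlCriterion("none")
    if cid.startswith("mdl-"):
        parts = cid.split("-")
        if len(parts) == 3:
            return MdlCriterion(parts[1], parts[2])
    if cid in ("mml-v1", "mml-v2"):
        return MmlCriterion(cid.split("-")[1])
    raise ValueError(f"unknown criterion id {criterion_id!r}")


def available_criteria() -> list[str]:
    """The fixed criterion ids (BDeu takes any positive alpha, e.g. 'bdeu:15')."""
    ids = ["k2", "bdeu:<alpha>", "mdl-none", "mml-v1", "mml-v2"]
    ids += [f"mdl-{v}-{ver}" for v in ("suzuki", "aic", "epi") for ver in ("v1", "v2")]
    return ids
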