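"""Two-locus pure-epistasis case-control simulator.

Generates Velez-style benchmark data: two functional SNPs whose joint
genotype determines disease risk through a 3x3 penetrance table with exactly
zero marginal single-locus effects, plus unlinked noise SNPs in
Hardy-Weinberg equilibrium and a 1:1 case-control ratio.  The default study
grid crosses seven broad-sense heritabilities (0.01, 0.025, 0.05, 0.10,
0.20, 0.30, 0.40) with two minor allele frequencies (0.2, 0.4), 18 noise
SNPs, and sample sizes 200/400/800/1600.

Broad-sense heritability of a dichotomous penetrance model is the
variance-ratio definition

    h2 = sum_ab p_a p_b (f_ab - K)^2 / (K (1 - K)),

with K the population prevalence and p the Hardy-Weinberg genotype
frequencies.  Case-control sampling is retrospective and exact: genotype
pairs for cases are drawn from P(a,b | case) proportional to p_a p_b f_ab
and controls from p_a p_b (1 - f_ab), so the requested case and control
counts hold by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.linalg import null_space

from .io import DDAG, GenotypeDataset, write_genotype_table

__all__ = [
    "TwoLocusModel",
    "SimulationDesign",
    "SimulatedDataset",
    "InfeasibleModelError",
    "hwe_probs",
    "prevalence",
    "heritability",
    "marginal_penetrances",
    "build_pure_epistasis_model",
    "sample_dataset",
    "velez_grid",
    "HERITABILITY_GRID",
    "MAF_GRID",
]

HERITABILITY_GRID = (0.01, 0.025, 0.05, 0.10, 0.20, 0.30, 0.40)
MAF_GRID = (0.2, 0.4)


class InfeasibleModelError(ValueError):
    """No penetrance table with zero marginal effects reaches the target h2."""


def hwe_probs(maf: float) -> np.ndarray:
    """Hardy-Weinberg genotype frequencies ((1-q)^2, 2q(1-q), q^2) for dosage 0/1/2."""
    if not 0 < maf <= 0.5:
        raise ValueError(f"minor allele frequency must be in (0, 0.5], got {maf}")
    p = 1.0 - maf
    return np.array([p * p, 2 * p * maf, maf * maf])


@dataclass(frozen=True)
class TwoLocusModel:
    """A 3x3 penetrance table P(disease | genotypes a, b) with per-locus MAFs."""

    penetrance: np.ndarray
    maf1: float
    maf2: float

    def __post_init__(self) -> None:
        f = np.asarray(self.penetrance, dtype=float)
        if f.shape != (3, 3):
            raise ValueError("penetrance table must be 3x3")
        if (f < 0).any() or (f > 1).any():
            raise ValueError("penetrances must lie in [0, 1]")
        object.__setattr__(self, "penetrance", f)
        hwe_probs(self.maf1), hwe_probs(self.maf2)  # range checks

    @property
    def cell_probs(self) -> np.ndarray:
        """Joint genotype probabilities p_a p_b, shape (3, 3)."""
        return np.outer(hwe_probs(self.maf1), hwe_probs(self.maf2))


@dataclass(frozen=True)
class SimulationDesign:
    """One simulated data set: generating model, sizes, noise SNPs, seed."""

    model: TwoLocusModel
    n_cases: int
    n_controls: int
    n_noise: int = 18
    noise_maf: float | tuple[float, ...] | None = None  # None -> functional MAF
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 0 or self.n_controls < 0 or self.n_cases + self.n_controls < 1:
            raise ValueError("need at least one individual")
        if self.n_noise < 0:
            raise ValueError("n_noise must be >= 0")


@dataclass(frozen=True)
class SimulatedDataset:
    """A sampled dataset together with its ground truth."""

    dataset: GenotypeDataset
    functional_columns: tuple[int, int]

    @property
    def truth(self) -> DDAG:
        return DDAG(self.functional_columns)


def prevalence(model: TwoLocusModel) -> float:
    """Population disease prevalence K = sum_ab p_a p_b f_ab."""
    return float((model.cell_probs * model.penetrance).sum())


def heritability(model: TwoLocusModel) -> float:
    """Broad-sense heritability of the dichotomous trait."""
    K = prevalence(model)
    if K <= 0.0 or K >= 1.0:
        raise ValueError(f"heritability undefined at prevalence K={K}")
    w = model.cell_probs
    return float((w * (model.penetrance - K) ** 2).sum() / (K * (1.0 - K)))


def marginal_penetrances(model: TwoLocusModel) -> tuple[np.ndarray, np.ndarray]:
    """Single-locus penetrances; both are constant iff the model is purely epistatic."""
    p1 = hwe_probs(model.maf1)
    p2 = hwe_probs(model.maf2)
    return model.penetrance @ p2, model.penetrance.T @ p1


def _zero_marginal_basis(maf: float) -> np.ndarray:
    """Orthonormal basis (9 x 4) of penetrance deviations with zero marginal effects.

    Rows of the constraint matrix force each row- and column-marginal of the
    deviation table (weighted by HWE frequencies) to vanish; the null space
    has dimension 4.
    """
    p = hwe_probs(maf)
    A = np.zeros((6, 9))
    for a in range(3):
        for b in range(3):
            A[a, 3 * a + b] = p[b]       # locus-1 marginal at genotype a
            A[3 + b, 3 * a + b] = p[a]   # locus-2 marginal at genotype b
    return null_space(A)


def build_pure_epistasis_model(h2_target: float, maf: float, seed=0,
                               prevalence_k: float | None = None,
                               max_tries: int = 5000) -> TwoLocusModel:
    """Construct a penetrance table with exact zero marginals and target h2.

    A random deviation direction is drawn from the zero-marginal-effect
    subspace and rescaled about the prevalence K so the variance ratio hits
    ``h2_target`` exactly; draws whose rescaled table would leave [0, 1] are
    rejected and redrawn.  When ``prevalence_k`` is None, K is picked per
    draw from a fixed grid as the feasible value closest to 0.5 (least
    extreme table); strong targets at rare alleles are only reachable at
    prevalences away from one half.  Deterministic given seed.
    """
    if h2_target < 0:
        raise ValueError("heritability target must be >= 0")
    if prevalence_k is not None and not 0 < prevalence_k < 1:
        raise ValueError("prevalence must be in (0, 1)")
    if h2_target == 0:
        return TwoLocusModel(np.full((3, 3), prevalence_k or 0.5), maf, maf)
    if h2_target > 1:
        raise InfeasibleModelError(
            f"h2={h2_target} exceeds the maximum attainable value 1")
    basis = _zero_marginal_basis(maf)
    w = np.outer(hwe_probs(maf), hwe_probs(maf)).ravel()
    k_grid = (np.array([prevalence_k]) if prevalence_k is not None
              else np.linspace(0.02, 0.98, 49))
    rng = np.random.default_rng(seed)
    best_attainable = 0.0
    for _ in range(max_tries):
        e = basis @ rng.standard_normal(basis.shape[1])
        V = float(w @ e ** 2)
        if V < 1e-12:
            continue
        pos, neg = e[e > 0], e[e < 0]
        emax = pos.max() if pos.size else 0.0
        emin = -neg.min() if neg.size else 0.0
        with np.errstate(divide="ignore"):
            c_max = np.minimum(
                np.divide(1.0 - k_grid, emax) if emax else np.inf,
                np.divide(k_grid, emin) if emin else np.inf,
            )
        h2_max = c_max ** 2 * V / (k_grid * (1.0 - k_grid))
        best_attainable = max(best_attainable, float(h2_max.max()))
        feasible = h2_max >= h2_target
        if feasible.any():
            K = float(k_grid[feasible][np.argmin(np.abs(k_grid[feasible] - 0.5))])
            c = np.sqrt(h2_target * K * (1.0 - K) / V)
            f = np.clip(K + c * e, 0.0, 1.0).reshape(3, 3)
            return TwoLocusModel(f, maf, maf)
    raise InfeasibleModelError(
        f"no zero-marginal table with h2={h2_target} at maf={maf} found in "
        f"{max_tries} draws; best attainable was about {best_attainable:.4g}")


def sample_dataset(design: SimulationDesign) -> SimulatedDataset:
    """Draw one case-control dataset; case/control counts are exact.

    Functional genotype pairs come from the penetrance-weighted conditional
    distributions; noise SNPs are independent Hardy-Weinberg draws.  The two
    functional columns are placed at seed-randomised positions and reported
    as ground truth.
    """
    model, rng = design.model, np.random.default_rng(design.seed)
    w = model.cell_probs.ravel()
    f = model.penetrance.ravel()
    case_p, control_p = w * f, w * (1.0 - f)
    if design.n_cases > 0 and case_p.sum() <= 0:
        raise ValueError("cannot sample cases: penetrance is identically zero")
    if design.n_controls > 0 and control_p.sum() <= 0:
        raise ValueError("cannot sample controls: penetrance is identically one")
    cells = np.concatenate([
        rng.choice(9, size=design.n_cases, p=case_p / case_p.sum())
        if design.n_cases else np.empty(0, dtype=int),
        rng.choice(9, size=design.n_controls, p=control_p / control_p.sum())
        if design.n_controls else np.empty(0, dtype=int),
    ]).astype(int)
    m = design.n_cases + design.n_controls
    phenotype = np.concatenate([
        np.ones(design.n_cases, dtype=np.int8),
        np.zeros(design.n_controls, dtype=np.int8),
    ])
    functional = np.stack([cells // 3, cells % 3], axis=1)

    n_total = design.n_noise + 2
    if design.noise_maf is None:
        noise_mafs = [model.maf1] * design.n_noise
    elif np.isscalar(design.noise_maf):
        noise_mafs = [float(design.noise_maf)] * design.n_noise
    else:
        noise_mafs = [float(x) for x in design.noise_maf]
        if len(noise_mafs) != design.n_noise:
            raise ValueError("per-SNP noise_maf list must have length n_noise")
    noise = np.empty((m, design.n_noise), dtype=np.int8)
    for j, nm in enumerate(noise_mafs):
        noise[:, j] = rng.choice(3, size=m, p=hwe_probs(nm))

    perm = rng.permutation(n_total)
    genotypes = np.empty((m, n_total), dtype=np.int8)
    genotypes[:, perm[:2]] = functional
    genotypes[:, perm[2:]] = noise
    names = [f"S{i + 1}" for i in range(n_total)]
    dataset = GenotypeDataset(names, genotypes, phenotype)
    cols = tuple(sorted(int(c) for c in perm[:2]))
    return SimulatedDataset(dataset, cols)


def velez_grid(models_per_cell: int = 5, seed: int = 0) -> list[TwoLocusModel]:
    """The study grid: 7 heritabilities x 2 MAFs x models_per_cell pure models."""
    if models_per_cell < 1:
        raise ValueError("models_per_cell must be >= 1")
    children = np.random.SeedSequence(seed).spawn(
        len(HERITABILITY_GRID) * len(MAF_GRID) * models_per_cell)
    models, i = [], 0
    for h2 in HERITABILITY_GRID:
        for maf in MAF_GRID:
            for _ in range(models_per_cell):
                models.append(build_pure_epistasis_model(h2, maf, seed=children[i]))
                i += 1
    return models


def write_simulated(sim: SimulatedDataset, path, dialect: str = "tab") -> None:
    """Write the dataset plus a sidecar JSON with the functional column indices."""
    path = Path(path)
    write_genotype_table(sim.dataset, path, dialect=dialect)
    truth = {
        "functional_columns": list(sim.functional_columns),
        "functional_snps": [sim.dataset.snp_names[i] for i in sim.functional_columns],
    }
    path.with_suffix(path.suffix + ".truth.json").write_text(json.dumps(truth, indent=1))
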