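"""Combining the two component tests into one quadratic-form statistic.

Under the null, (X, Y) is approximately bivariate normal with mean zero,
unit variances and correlation rho (both components see the affected
families' genotypes). rho is estimated by conventional gene dropping at the
test SNP; the combined statistic is the quadratic form

    Q = (x, y) S_tau^{-1} (x, y)'   with  S_tau = [[1, rho*tau], [rho*tau, 1]]

where tau in [0, 1] scales the off-diagonal. tau = 1 recovers the 2-df
chi-square geometry under S; tau = 0 the Euclidean distance from the
origin; the recommended default is tau = 0.5. Because Q is evaluated with a
scaled correlation while (X, Y) keeps the unscaled one, its null
distribution is not chi-square(2); p-values come from a parametric
bootstrap drawing BVN(0, [[1, rho], [rho, 1]]) pairs. The MAX and 2-df
chi-square comparators are also provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .components import ComponentEngine, MafEstimate
from .pedigree import HybridDesign, KinshipMatrix

__all__ = [
    "CombinerConfig",
    "GeneDropResult",
    "gene_drop_counts",
    "estimate_null_correlation",
    "popfam_statistic",
    "bootstrap_pvalue",
    "max_test",
    "chi2_2df_test",
]


@dataclass
class CombinerConfig:
    """Tuning knobs for correlation estimation and p-value computation.

    tau: off-diagonal scaling in [0, 1] (default 0.5).
    n_gene_drops: gene-drop replicates for the null correlation.
    n_bootstrap: BVN draws for the bootstrap p-value.
    seed: master RNG seed; all randomness derives from it.
    maf_source: sample set used for the MAF plugged into gene dropping.
    """

    tau: float = 0.5
    n_gene_drops: int = 1000
    n_bootstrap: int = 10000
    seed: int = 0
    maf_source: str = "controls"

    def __post_init__(self):
        if not 0.0 <= self.tau <= 1.0:
            raise ValueError(f"tau must be in [0, 1], got {self.tau}")


@dataclass
class GeneDropResult:
    rho_hat: float
    n_used: int
    n_discarded: int


def gene_drop_counts(
    design: HybridDesign, p_hat: float, n_rep: int, rng: np.random.Generator
) -> np.ndarray:
    """Simulate null minor-allele counts through the pedigree.

    Founders (including every singleton control/case) receive two alleles
    drawn iid Bernoulli(p_hat); non-founders inherit one uniformly random
    allele from each parent. Processing is vectorized over replicates and
    over individuals within each generation level. Returns an
    (n_individuals, n_rep) count matrix. The observed missingness pattern is
    applied downstream by the scoring engine, which only reads entries that
    were non-missing in the data.
    """
    n = design.n_individuals
    pat = np.empty((n, n_rep), dtype=np.int8)
    mat = np.empty((n, n_rep), dtype=np.int8)
    founders = np.flatnonzero(design.founder_mask)
    pat[founders] = rng.random((len(founders), n_rep)) < p_hat
    mat[founders] = rng.random((len(founders), n_rep)) < p_hat
    for level in design.levels[1:]:
        fa = design.father_idx[level]
        mo = design.mother_idx[level]
        pick = rng.random((len(level), n_rep)) < 0.5
        pat[level] = np.where(pick, pat[fa], mat[fa])
        pick = rng.random((len(level), n_rep)) < 0.5
        mat[level] = np.where(pick, pat[mo], mat[mo])
    return (pat + mat).astype(float)


def estimate_null_correlation(
    design: HybridDesign,
    kin: KinshipMatrix,
    snp_id: str,
    maf: MafEstimate,
    cfg: CombinerConfig,
    rng: np.random.Generator | None = None,
    engine: ComponentEngine | None = None,
) -> GeneDropResult:
    """Gene-drop estimate of the null correlation between X and Y.

    Phenotypes, roles and the missingness pattern stay fixed; only genotypes
    are redrawn under the null at the estimated MAF. Replicates where either
    component is undefined (e.g., a monomorphic draw) are discarded; the
    Pearson correlation is computed over the remainder. Deterministic given
    ``cfg.seed`` (or an explicit ``rng``).
    """
    if not 0.0 < maf.p_hat < 1.0:
        raise ValueError(f"SNP {snp_id}: gene dropping needs 0 < MAF < 1, got {maf.p_hat}")
    if cfg.n_gene_drops < 2:
        raise ValueError("need at least 2 gene-drop replicates")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if engine is None:
        engine = ComponentEngine(design, kin, design.snp_index(snp_id))
    counts = gene_drop_counts(design, maf.p_hat, cfg.n_gene_drops, rng)
    x, y = engine.compute(counts)
    ok = np.isfinite(x) & np.isfinite(y)
    n_used = int(ok.sum())
    if n_used < 2:
        raise ValueError(f"SNP {snp_id}: fewer than 2 usable gene-drop replicates")
    xs, ys = x[ok], y[ok]
    sx, sy = xs.std(), ys.std()
    if sx == 0 or sy == 0:
        raise ValueError(f"SNP {snp_id}: degenerate gene-drop statistic variance")
    rho = float(np.corrcoef(xs, ys)[0, 1])
    if cfg.tau > 0 and abs(rho) >= 1.0 / cfg.tau:
        raise ValueError(f"SNP {snp_id}: |rho*tau| >= 1, combined form not invertible")
    return GeneDropResult(rho_hat=rho, n_used=n_used, n_discarded=cfg.n_gene_drops - n_used)


def popfam_statistic(x: float, y: float, rho_hat: float, tau: float = 0.5) -> float:
    """Quadratic form of (x, y) against the tau-scaled null covariance.

    Closed-form 2x2 inverse: with c = rho_hat * tau,

        Q = (x^2 - 2 c x y + y^2) / (1 - c^2)  >=  0.
    """
    c = rho_hat * tau
    if abs(c) >= 1.0:
        raise ValueError(f"|rho_hat * tau| must be < 1, got {c}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    q = (x * x - 2.0 * c * x * y + y * y) / (1.0 - c * c)
    return q if q.ndim else float(q)


def _bvn_draws(rho_hat: float, n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    return z1, rho_hat * z1 + np.sqrt(1.0 - rho_hat**2) * z2

def bootstrap_pvalue(
    x: float,
    y: float,
    rho_hat: float,
    tau: float = 0.5,
    n_bootstrap: int = 10000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Parametric-bootstrap p-value for the combined statistic.

    Draws BVN pairs with unit variances and correlation rho_hat (the
    unscaled correlation; tau enters only the quadratic form) and returns
    the add-one tail estimate (1 + #{Q* >= Q_obs}) / (1 + t), so p > 0
    always. Deterministic given ``seed``.
    """
    if n_bootstrap < 100:
        raise ValueError("n_bootstrap must be >= 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    q_obs = popfam_statistic(x, y, rho_hat, tau)
    xs, ys = _bvn_draws(rho_hat, n_bootstrap, rng)
    q = popfam_statistic(xs, ys, rho_hat, tau)
    return float((1 + int((q >= q_obs).sum())) / (1 + n_bootstrap))


def max_test(
    x: float,
    y: float,
    rho_hat: float,
    n_bootstrap: int = 10000,
    seed: int | np.random.Generator = 0,
    signed: bool = False,
) -> float:
    """MAX comparator: p-value of max(|x|, |y|) under the estimated BVN null.

    With ``signed=True`` the one-sided variant max(x, y) is used instead.
    Uses the same add-one bootstrap estimator as the combined test.
    """
    if n_bootstrap < 100:
        raise ValueError("n_bootstrap must be >= 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    xs, ys = _bvn_draws(rho_hat, n_bootstrap, rng)
    if signed:
        m_obs = max(x, y)
        m = np.maximum(xs, ys)
    else:
        m_obs = max(abs(x), abs(y))
        m = np.maximum(np.abs(xs), np.abs(ys))
    return float((1 + int((m >= m_obs).sum())) / (1 + n_bootstrap))


def chi2_2df_test(x: float, y: float) -> float:
    """2-df chi-square comparator: survival probability at x^2 + y^2."""
    return float(stats.chi2.sf(x * x + y * y, df=2))
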