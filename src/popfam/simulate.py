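"""Two-locus simulator for hybrid-design replicates and experiment runners.

Emulates a candidate-gene study: a biallelic disease locus and a tightly
linked biallelic test SNP (no recombination within families), with linkage
disequilibrium parameterized by Lewontin's D'. Affection is assigned by a
dominant or recessive penetrance model constrained to a fixed population
prevalence. Families are drawn to a fixed post-ascertainment structure table
(default: 47 case-parent triads plus 292 nuclear families of sizes 4-7),
with ascertainment on positive family history and a true-descent
IBD-sharing proxy for positive co-segregation evidence. Unrelated controls
are sampled conditional on being unaffected.

The experiment runners measure empirical type I error (D' = 0) and power
(D' = 0.8) of the combined test and its comparators over replicates.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .combine import CombinerConfig
from .pedigree import (
    AFF_AFFECTED,
    AFF_UNAFFECTED,
    ROLE_CASE,
    ROLE_CONTROL,
    ROLE_FAMILY,
    SEX_FEMALE,
    SEX_MALE,
    SEX_UNKNOWN,
    GenotypeVector,
    HybridDesign,
    Individual,
)

__all__ = [
    "DiseaseModel",
    "HaplotypeFreqs",
    "FamilyStructure",
    "TABLE1_STRUCTURES",
    "build_haplotype_freqs",
    "solve_penetrances",
    "simulate_family",
    "ascertain",
    "simulate_replicate",
    "run_type1_experiment",
    "run_power_experiment",
    "run_experiment",
]

# Haplotype index convention over (disease allele, test allele):
# 0 = DA, 1 = Da, 2 = dA, 3 = da, with D/A the minor (risk) alleles.


@dataclass(frozen=True)
class HaplotypeFreqs:
    """Joint haplotype distribution of the disease locus and test SNP."""

    freqs: tuple[float, float, float, float]  # (DA, Da, dA, da)

    def __post_init__(self):
        f = np.asarray(self.freqs)
        if (f < -1e-12).any() or abs(f.sum() - 1.0) > 1e-10:
            raise ValueError(f"invalid haplotype frequencies {self.freqs}")

    @property
    def maf_disease(self) -> float:
        return self.freqs[0] + self.freqs[1]

    @property
    def maf_test(self) -> float:
        return self.freqs[0] + self.freqs[2]

    @property
    def d_prime(self) -> float:
        pD, pA = self.maf_disease, self.maf_test
        d = self.freqs[0] - pD * pA
        if d >= 0:
            dmax = min(pD * (1 - pA), (1 - pD) * pA)
        else:
            dmax = min(pD * pA, (1 - pD) * (1 - pA))
        return 0.0 if dmax == 0 else d / dmax


def build_haplotype_freqs(maf_disease: float, maf_test: float, d_prime: float) -> HaplotypeFreqs:
    """Haplotype frequencies with the minor alleles positively associated.

    D = d_prime * Dmax with Dmax = min(p_D (1 - p_A), (1 - p_D) p_A);
    p(DA) = p_D p_A + D, remaining cells by the marginal constraints.
    """
    if not (0 < maf_disease < 0.5 and 0 < maf_test < 0.5):
        raise ValueError("MAFs must be in (0, 0.5)")
    if not 0.0 <= d_prime <= 1.0:
        raise ValueError("d_prime must be in [0, 1]")
    pD, pA = maf_disease, maf_test
    d = d_prime * min(pD * (1 - pA), (1 - pD) * pA)
    freqs = (
        pD * pA + d,
        pD * (1 - pA) - d,
        (1 - pD) * pA - d,
        (1 - pD) * (1 - pA) + d,
    )
    return HaplotypeFreqs(freqs=tuple(float(max(x, 0.0)) for x in freqs))


@dataclass
class DiseaseModel:
    """Penetrance-based disease model constrained to a fixed prevalence.

    The relative risk multiplies the baseline penetrance for carriers
    (dominant: one or two risk alleles; recessive: two). Penetrances are
    solved from the prevalence constraint under HWE at the disease locus.
    """

    maf: float
    d_prime: float
    mode: str  # 'dominant' | 'recessive'
    relative_risk: float
    prevalence: float = 0.05
    penetrances: tuple[float, float, float] = field(init=False)

    def __post_init__(self):
        if self.mode not in ("dominant", "recessive"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.relative_risk < 1.0:
            raise ValueError("relative_risk must be >= 1")
        self.penetrances = solve_penetrances(self)

    def haplotype_freqs(self) -> HaplotypeFreqs:
        return build_haplotype_freqs(self.maf, self.maf, self.d_prime)


def solve_penetrances(model: DiseaseModel) -> tuple[float, float, float]:
    """Closed-form penetrances satisfying the prevalence constraint.

    dominant:  f0 = K / (w RR + 1 - w), w = 1 - (1-q)^2, f1 = f2 = RR f0
    recessive: f0 = f1 = K / (q^2 RR + 1 - q^2), f2 = RR f0
    """
    q, rr, K = model.maf, model.relative_risk, model.prevalence
    if model.mode == "dominant":
        w = 1.0 - (1.0 - q) ** 2
        f0 = K / (w * rr + 1.0 - w)
        pen = (f0, rr * f0, rr * f0)
    else:
        w = q * q
        f0 = K / (w * rr + 1.0 - w)
        pen = (f0, f0, rr * f0)
    if max(pen) >= 1.0:
        raise ValueError(f"model infeasible: penetrance {max(pen):.3f} >= 1")
    # prevalence identity under HWE
    g = np.array([(1 - q) ** 2, 2 * q * (1 - q), q * q])
    assert abs(float(g @ np.asarray(pen)) - K) < 1e-10
    return pen


@dataclass(frozen=True)
class FamilyStructure:
    family_size: int
    count: int
    min_offspring: int


#: Default post-ascertainment structure: 47 triads + 292 nuclear families.
TABLE1_STRUCTURES: tuple[FamilyStructure, ...] = (
    FamilyStructure(3, 47, 1),
    FamilyStructure(4, 126, 2),
    FamilyStructure(5, 89, 3),
    FamilyStructure(6, 48, 4),
    FamilyStructure(7, 29, 5),
)


# -- family-level simulation -------------------------------------------


@dataclass
class FamilyBatch:
    """Vectorized batch of nuclear families with true descent labels.

    Arrays are indexed [family] or [family, member]; parents are member 0
    (father) and 1 (mother). ``cf``/``cm`` record which parental haplotype
    each offspring inherited (the descent labels used for IBD sharing).
    """

    gd_par: np.ndarray  # (n, 2) disease-locus genotypes
    gt_par: np.ndarray  # (n, 2) test-SNP genotypes
    gd_off: np.ndarray  # (n, k)
    gt_off: np.ndarray  # (n, k)
    aff_par: np.ndarray  # (n, 2) bool
    aff_off: np.ndarray  # (n, k) bool
    cf: np.ndarray  # (n, k) paternal haplotype chosen (0/1)
    cm: np.ndarray  # (n, k) maternal haplotype chosen (0/1)

    @property
    def n_offspring(self) -> int:
        return self.gd_off.shape[1]

    def take(self, idx: np.ndarray) -> "FamilyBatch":
        return FamilyBatch(*(getattr(self, f)[idx] for f in
                             ("gd_par", "gt_par", "gd_off", "gt_off",
                              "aff_par", "aff_off", "cf", "cm")))


def _simulate_batch(
    n_fam: int, n_off: int, haps: HaplotypeFreqs, pen: tuple[float, float, float],
    rng: np.random.Generator,
) -> FamilyBatch:
    f = np.asarray(pen)
    ph = rng.choice(4, size=(n_fam, 2, 2), p=np.asarray(haps.freqs))
    cf = rng.integers(0, 2, size=(n_fam, n_off))
    cm = rng.integers(0, 2, size=(n_fam, n_off))
    fam = np.arange(n_fam)[:, None]
    hf = ph[fam, 0, cf]  # haplotype inherited from father
    hm = ph[fam, 1, cm]
    gd_par = (ph < 2).sum(axis=2)
    gt_par = (ph % 2 == 0).sum(axis=2)
    gd_off = (hf < 2).astype(np.int64) + (hm < 2)
    gt_off = (hf % 2 == 0).astype(np.int64) + (hm % 2 == 0)
    aff_par = rng.random((n_fam, 2)) < f[gd_par]
    aff_off = rng.random((n_fam, n_off)) < f[gd_off]
    return FamilyBatch(gd_par, gt_par, gd_off, gt_off, aff_par, aff_off, cf, cm)


def simulate_family(
    family_size: int, model: DiseaseModel, haps: HaplotypeFreqs, rng: np.random.Generator
) -> FamilyBatch:
    """Simulate one nuclear family (size 3 => 1 offspring, else size - 2)."""
    if family_size < 3:
        raise ValueError("family_size must be >= 3")
    n_off = 1 if family_size == 3 else family_size - 2
    return _simulate_batch(1, n_off, haps, model.penetrances, rng)


def _sib_excess_sharing(batch: FamilyBatch) -> tuple[np.ndarray, np.ndarray]:
    """Summed excess IBD sharing over affected full-sib pairs, per family.

    Sharing between two sibs at the disease locus is read off the true
    descent labels; its pedigree expectation is 1/2. Parent-involving pairs
    share exactly their expectation by construction and carry no signal.
    Returns (excess, has_pair).
    """
    n = len(batch.gd_par)
    excess = np.zeros(n)
    has_pair = np.zeros(n, dtype=bool)
    for i, j in itertools.combinations(range(batch.n_offspring), 2):
        both = batch.aff_off[:, i] & batch.aff_off[:, j]
        share = ((batch.cf[:, i] == batch.cf[:, j]).astype(float)
                 + (batch.cm[:, i] == batch.cm[:, j])) / 2.0
        excess += both * (share - 0.5)
        has_pair |= both
    return excess, has_pair


def _ascertain_mask(batch: FamilyBatch, parent_pairs_pass: bool = False) -> np.ndarray:
    """Vectorized keep/drop decision per family.

    Triads (one offspring): keep iff the offspring is affected and the
    family has >= 2 affected members (positive family history).

    Larger families, with ``parent_pairs_pass=True`` (the lenient reading
    used for post-filter structure targets): keep iff >= 1 affected
    offspring and, whenever an affected full-sib pair exists, the summed
    excess IBD sharing at the disease locus over those pairs is strictly
    positive; families without an affected sib pair have a degenerate
    co-segregation statistic (no variable sharing) and pass. With
    ``parent_pairs_pass=False`` (the strict reading) the evidence must be
    affirmative: >= 2 affected members including an affected sib pair with
    strictly positive excess sharing.
    """
    n_off = batch.n_offspring
    n_aff = batch.aff_par.sum(axis=1) + batch.aff_off.sum(axis=1)
    if n_off == 1:
        return batch.aff_off[:, 0] & (n_aff >= 2)
    excess, has_pair = _sib_excess_sharing(batch)
    if parent_pairs_pass:
        return batch.aff_off.any(axis=1) & (~has_pair | (excess > 0))
    return (n_aff >= 2) & has_pair & (excess > 0)


def _proband_mask(batch: FamilyBatch) -> np.ndarray:
    """Proband sampling condition: at least one affected offspring."""
    return batch.aff_off.any(axis=1)


def ascertain(batch: FamilyBatch, parent_pairs_pass: bool = False) -> np.ndarray:
    """Keep/drop decisions for a family batch (see :func:`_ascertain_mask`)."""
    return _ascertain_mask(batch, parent_pairs_pass)


def _fill_cell(
    structure: FamilyStructure,
    model: DiseaseModel,
    haps: HaplotypeFreqs,
    rng: np.random.Generator,
    condition: str = "analysis",
    min_accept_rate: float = 1e-4,
) -> FamilyBatch:
    """Regenerate families of one size until the cell count is met.

    ``condition`` selects the sampling condition: 'proband' keeps families
    with at least one affected offspring (proband ascertainment);
    'analysis' applies the full history/co-segregation rule directly.
    """
    n_off = 1 if structure.family_size == 3 else structure.family_size - 2
    kept: list[FamilyBatch] = []
    n_kept = 0
    n_tried = 0
    batch_size = max(4 * structure.count, 2000)
    while n_kept < structure.count:
        batch = _simulate_batch(batch_size, n_off, haps, model.penetrances, rng)
        if condition == "proband":
            mask = _proband_mask(batch)
        else:
            mask = _ascertain_mask(batch, parent_pairs_pass=True)
        sel = batch.take(np.flatnonzero(mask))
        kept.append(sel)
        n_kept += len(sel.gd_par)
        n_tried += batch_size
        if n_tried >= 2e5 and n_kept / n_tried < min_accept_rate:
            raise RuntimeError(
                f"ascertainment acceptance rate {n_kept / n_tried:.2e} below "
                f"{min_accept_rate} for family size {structure.family_size}; "
                "check the disease model"
            )
        rate = max(n_kept, 1) / n_tried
        batch_size = int(min(max((structure.count - n_kept) / rate * 1.3, 1000), 200_000))
    merged = FamilyBatch(*(np.concatenate([getattr(b, f) for b in kept])
                           for f in ("gd_par", "gt_par", "gd_off", "gt_off",
                                     "aff_par", "aff_off", "cf", "cm")))
    return merged.take(np.arange(structure.count))


def _population_individuals(
    n: int, haps: HaplotypeFreqs, pen: tuple[float, float, float],
    rng: np.random.Generator, affected: bool | None,
) -> np.ndarray:
    """Test-SNP genotypes of unrelated individuals, optionally conditioned
    on affection status (rejection sampling)."""
    out = np.empty(0, dtype=np.int64)
    f = np.asarray(pen)
    while len(out) < n:
        m = max(2 * n, 1000)
        h = rng.choice(4, size=(m, 2), p=np.asarray(haps.freqs))
        gd = (h < 2).sum(axis=1)
        gt = (h % 2 == 0).sum(axis=1)
        if affected is None:
            out = np.concatenate([out, gt])
        else:
            aff = rng.random(m) < f[gd]
            out = np.concatenate([out, gt[aff == affected]])
    return out[:n]


def simulate_replicate(
    model: DiseaseModel,
    structures: tuple[FamilyStructure, ...] = TABLE1_STRUCTURES,
    n_controls: int = 100,
    rng: np.random.Generator | int = 0,
    n_independent_cases: int = 0,
    snp_id: str = "SNP1",
    ascertainment: str = "post",
) -> HybridDesign:
    """One hybrid-design replicate (test SNP only).

    ``ascertainment`` selects how the structure table is interpreted:

    * ``"post"`` (default) — the table gives post-filter targets: cells are
      regenerated until the retention rule is satisfied ``count`` times
      (triads: affected offspring and >= 2 affected members; larger
      families: >= 1 affected offspring, and strictly positive excess IBD
      sharing whenever an affected sib pair exists), so every replicate has
      an identical analyzed design size.
    * ``"pre"`` — the table describes the *simulated* datasets: each cell
      is filled with families conditioned on having at least one affected
      offspring (proband ascertainment), and the analysis subset is then
      selected per replicate by the positive-history rule plus a strict
      co-segregation proxy demanding affirmative excess sharing over
      affected sib pairs. The number of analyzed families varies across
      replicates and is much smaller.

    Controls are unrelated individuals conditioned on being unaffected;
    independent cases (if any) on being affected.
    """
    if ascertainment not in ("pre", "post"):
        raise ValueError(f"unknown ascertainment mode {ascertainment!r}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    haps = model.haplotype_freqs()
    individuals: list[Individual] = []
    counts: list[float] = []
    fam_no = 0
    for structure in structures:
        if ascertainment == "pre":
            batch = _fill_cell(structure, model, haps, rng, condition="proband")
            batch = batch.take(np.flatnonzero(_ascertain_mask(batch)))
        else:
            batch = _fill_cell(structure, model, haps, rng, condition="analysis")
        n_off = batch.n_offspring
        for k in range(len(batch.gd_par)):
            fam_no += 1
            fid = f"F{fam_no:04d}"
            individuals.append(Individual("1", fid, None, None, SEX_MALE,
                                          _aff(batch.aff_par[k, 0]), ROLE_FAMILY))
            individuals.append(Individual("2", fid, None, None, SEX_FEMALE,
                                          _aff(batch.aff_par[k, 1]), ROLE_FAMILY))
            counts.extend(batch.gt_par[k].tolist())
            for o in range(n_off):
                individuals.append(Individual(str(3 + o), fid, "1", "2", SEX_UNKNOWN,
                                              _aff(batch.aff_off[k, o]), ROLE_FAMILY))
            counts.extend(batch.gt_off[k].tolist())
    ctrl = _population_individuals(n_controls, haps, model.penetrances, rng, affected=False)
    for k in range(n_controls):
        fid = f"C{k + 1:04d}"
        individuals.append(Individual("1", fid, None, None, SEX_UNKNOWN,
                                      AFF_UNAFFECTED, ROLE_CONTROL))
        counts.append(int(ctrl[k]))
    if n_independent_cases:
        case = _population_individuals(n_independent_cases, haps, model.penetrances,
                                       rng, affected=True)
        for k in range(n_independent_cases):
            fid = f"K{k + 1:04d}"
            individuals.append(Individual("1", fid, None, None, SEX_UNKNOWN,
                                          AFF_AFFECTED, ROLE_CASE))
            counts.append(int(case[k]))
    gv = GenotypeVector(snp_id=snp_id, alleles=("A", "G"), minor_allele="A",
                        counts=np.asarray(counts, dtype=float))
    return HybridDesign(individuals, [gv])


def _aff(flag: bool) -> str:
    return AFF_AFFECTED if flag else AFF_UNAFFECTED


# -- experiment runners -------------------------------------------------

_TESTS = ("popfam", "wqls", "pdt", "max", "chi2")


def run_experiment(
    model: DiseaseModel,
    n_replicates: int,
    cfg: CombinerConfig | None = None,
    structures: tuple[FamilyStructure, ...] = TABLE1_STRUCTURES,
    n_controls: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
    ascertainment: str = "post",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicate-level p-values and a rejection-rate summary for all tests.

    Each replicate: simulate the design, estimate the MAF (controls, falling
    back to all samples if the control set is monomorphic), gene-drop the
    null correlation, compute the combined statistic and every comparator.
    Per-replicate RNG streams are spawned from ``seed`` so runs are
    reproducible and order-independent.

    Returns ``(per_replicate, summary)`` data frames; the summary is tidy
    long format with columns test, estimate, ci_low, ci_high, n_replicates.
    """
    from .model import PopfamModel  # deferred: model builds on this module's outputs

    cfg = cfg or CombinerConfig(n_gene_drops=200, n_bootstrap=2000)
    rows = []
    children = np.random.SeedSequence(seed).spawn(n_replicates)
    for rep in range(n_replicates):
        sim_ss, fit_ss = children[rep].spawn(2)
        design = simulate_replicate(model, structures, n_controls,
                                    np.random.default_rng(sim_ss),
                                    ascertainment=ascertainment)
        rep_cfg = CombinerConfig(
            tau=cfg.tau, n_gene_drops=cfg.n_gene_drops, n_bootstrap=cfg.n_bootstrap,
            seed=int(fit_ss.generate_state(1)[0] % 2**31), maf_source=cfg.maf_source,
        )
        res = PopfamModel(design, rep_cfg).fit()
        r = res.table.iloc[0]
        rows.append({
            "replicate": rep,
            "p_popfam": r["p_value"], "p_wqls": r["p_wqls"], "p_pdt": r["p_pdt"],
            "p_max": r["p_max"], "p_chi2": r["p_chi2"],
            "x": r["x"], "y": r["y"], "rho_hat": r["rho_hat"],
            "p_hat": r["p_hat"], "maf_source": r["maf_source"],
            "n_gene_drops_used": r["n_gene_drops_used"],
        })
    per_rep = pd.DataFrame(rows)
    srows = []
    z = 1.959963984540054
    for test in _TESTS:
        p = per_rep[f"p_{test}" if test != "popfam" else "p_popfam"].to_numpy(float)
        ok = np.isfinite(p)
        n = int(ok.sum())
        est = float((p[ok] < alpha).mean()) if n else np.nan
        half = z * np.sqrt(est * (1 - est) / n) if n else np.nan
        srows.append({
            "test": test, "estimate": est,
            "ci_low": max(est - half, 0.0) if n else np.nan,
            "ci_high": min(est + half, 1.0) if n else np.nan,
            "n_replicates": n, "alpha": alpha,
        })
    return per_rep, pd.DataFrame(srows)


def run_type1_experiment(
    maf: float,
    n_replicates: int,
    cfg: CombinerConfig | None = None,
    mode: str = "dominant",
    relative_risk: float = 2.0,
    **kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Type-I-error experiment: D' = 0 so the test SNP is null.

    A trait model is still required to drive ascertainment; with D' = 0 the
    test SNP segregates independently of it, so the choice cannot affect the
    size of the tests.
    """
    model = DiseaseModel(maf=maf, d_prime=0.0, mode=mode, relative_risk=relative_risk)
    return run_experiment(model, n_replicates, cfg, **kwargs)


def run_power_experiment(
    maf: float,
    n_replicates: int,
    cfg: CombinerConfig | None = None,
    mode: str = "dominant",
    relative_risk: float = 2.0,
    d_prime: float = 0.8,
    **kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Power experiment under the LD alternative (default D' = 0.8)."""
    model = DiseaseModel(maf=maf, d_prime=d_prime, mode=mode, relative_risk=relative_risk)
    return run_experiment(model, n_replicates, cfg, **kwargs)
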