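"""Component association statistics: signed-root wQLS and the PDT.

The hybrid test combines two asymptotically N(0, 1) components:

* ``X`` — the signed square root of the quasi-likelihood score (wQLS)
  statistic comparing minor-allele frequency between cases (affected family
  members plus independent cases) and controls, with the genotype
  correlation of relatives modelled through kinship coefficients.
* ``Y`` — the pedigree disequilibrium test (PDT, sum variant): per family,
  transmitted-minus-untransmitted minor alleles from heterozygous parents to
  affected offspring plus genotype differences in discordant sib pairs,
  normalized by the empirical standard deviation over families.

Both are exposed as scalar convenience functions and through
:class:`ComponentEngine`, which precomputes everything that depends only on
the design and the observed missingness pattern so that many genotype
replicates (gene drops) can be scored at once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pedigree import (
    AFF_AFFECTED,
    AFF_UNAFFECTED,
    ROLE_CASE,
    ROLE_CONTROL,
    ROLE_FAMILY,
    HybridDesign,
    KinshipMatrix,
)

__all__ = [
    "MafEstimate",
    "TestPair",
    "ComponentEngine",
    "estimate_maf",
    "wqls_statistic",
    "pdt_statistic",
    "DegenerateSnpError",
]


class DegenerateSnpError(ValueError):
    """Raised when a statistic is structurally unavailable for a SNP."""


@dataclass(frozen=True)
class MafEstimate:
    snp_id: str
    p_hat: float
    n_alleles: int
    source: str = "controls"


@dataclass(frozen=True)
class TestPair:
    """The two component statistics at one SNP (nan = undefined)."""

    x: float
    y: float
    n_informative_families: int
    n_used_pop: int


def estimate_maf(design: HybridDesign, snp_id: str, source: str = "controls") -> MafEstimate:
    """Allele-counting MAF estimate over a sample source.

    source: 'controls' (default), 'founders' or 'all'. Raises
    :class:`DegenerateSnpError` naming a fallback when the source has no
    non-missing genotypes.
    """
    s = design.snp_index(snp_id)
    counts = design.genotypes[s].counts
    if source == "controls":
        mask = design.roles == ROLE_CONTROL
    elif source == "founders":
        mask = design.founder_mask
    elif source == "all":
        mask = np.ones(design.n_individuals, bool)
    else:
        raise ValueError(f"unknown MAF source {source!r}")
    use = mask & ~np.isnan(counts)
    n_alleles = 2 * int(use.sum())
    if n_alleles == 0:
        raise DegenerateSnpError(
            f"SNP {snp_id}: no non-missing genotypes in source {source!r}; "
            "fall back to source='founders' or 'all'"
        )
    p_hat = float(counts[use].sum()) / n_alleles
    return MafEstimate(snp_id=snp_id, p_hat=p_hat, n_alleles=n_alleles, source=source)


class ComponentEngine:
    """Scores genotype matrices for one SNP's design/missingness pattern.

    Restricting to individuals with a non-missing observed genotype at the
    SNP (no imputation), precomputes:

    * wQLS: per-family solves of K a = 1 and K b = r where K has unit
      diagonal and off-diagonal 2 phi_ij, r indicates cases. The statistic
      for a genotype column g is built from dot products with a and b.
    * PDT: index arrays for transmission units (affected offspring with both
      parents genotyped) and discordant sib pairs, with their family labels.

    ``compute`` then evaluates (X, Y) for an (n_individuals, R) matrix of
    minor-allele count columns in one vectorized pass; undefined entries are
    nan (monomorphic draw for X, no informative family for Y).
    """

    def __init__(
        self,
        design: HybridDesign,
        kin: KinshipMatrix,
        snp_index: int,
        case_weights: np.ndarray | None = None,
        pdt_variant: str = "sum",
    ):
        if pdt_variant not in ("sum", "avg"):
            raise ValueError(f"unknown pdt_variant {pdt_variant!r}")
        self.pdt_variant = pdt_variant
        self.design = design
        counts = design.genotypes[snp_index].counts
        nonmiss = ~np.isnan(counts)
        roles = design.roles
        aff = design.affection

        case_mask = nonmiss & (
            ((roles == ROLE_FAMILY) & (aff == AFF_AFFECTED)) | (roles == ROLE_CASE)
        )
        ctrl_mask = nonmiss & (roles == ROLE_CONTROL)
        used = case_mask | ctrl_mask
        self.used_idx = np.flatnonzero(used)
        self.n_used_pop = len(self.used_idx)

        r = case_mask[self.used_idx].astype(float)
        if case_weights is not None:
            r = np.asarray(case_weights, dtype=float)[self.used_idx]
        pos_in_used = {g: k for k, g in enumerate(self.used_idx)}
        a = np.zeros(self.n_used_pop)
        b = np.zeros(self.n_used_pop)
        snp_id = design.genotypes[snp_index].snp_id
        for fid, (fam_idx, phi) in kin.blocks.items():
            sel = [k for k, g in enumerate(fam_idx) if g in pos_in_used]
            if not sel:
                continue
            rows = [pos_in_used[fam_idx[k]] for k in sel]
            K = 2.0 * phi[np.ix_(sel, sel)]
            np.fill_diagonal(K, 1.0)
            try:
                sol = np.linalg.solve(K, np.column_stack([np.ones(len(sel)), r[rows]]))
            except np.linalg.LinAlgError:
                raise DegenerateSnpError(
                    f"SNP {snp_id}: singular kinship correlation block in family {fid}"
                ) from None
            a[rows] = sol[:, 0]
            b[rows] = sol[:, 1]
        self.a = a
        self.b = b
        self.r = r
        self.s11 = float(a.sum())          # 1' K^-1 1
        self.sr1 = float(b.sum())          # r' K^-1 1
        self.srr = float(b @ r)            # r' K^-1 r
        self.wqls_ok = self.n_used_pop > 0 and r.sum() > 0 and (r == 0).any() and self.s11 > 0
        self.var_coef = self.srr - self.sr1**2 / self.s11 if self.wqls_ok else np.nan

        # --- PDT structure ---
        fam_of: dict[str, int] = {}
        tri_f: list[int] = []
        tri_m: list[int] = []
        tri_c: list[int] = []
        tri_fam: list[int] = []
        dsp_a: list[int] = []
        dsp_u: list[int] = []
        dsp_fam: list[int] = []

        def fam_slot(fid: str) -> int:
            if fid not in fam_of:
                fam_of[fid] = len(fam_of)
            return fam_of[fid]

        for fid, members in design.families.items():
            if len(members) < 2:
                continue
            # transmission units: affected offspring, both parents genotyped
            for i in members:
                fa, mo = design.father_idx[i], design.mother_idx[i]
                if fa < 0:
                    continue
                if aff[i] == AFF_AFFECTED and nonmiss[i] and nonmiss[fa] and nonmiss[mo]:
                    tri_f.append(fa)
                    tri_m.append(mo)
                    tri_c.append(i)
                    tri_fam.append(fam_slot(fid))
            # discordant full-sib pairs, both genotyped
            sibships: dict[tuple[int, int], list[int]] = {}
            for i in members:
                fa, mo = design.father_idx[i], design.mother_idx[i]
                if fa >= 0:
                    sibships.setdefault((fa, mo), []).append(i)
            for sibs in sibships.values():
                affd = [i for i in sibs if aff[i] == AFF_AFFECTED and nonmiss[i]]
                unaf = [i for i in sibs if aff[i] == AFF_UNAFFECTED and nonmiss[i]]
                for i in affd:
                    for j in unaf:
                        dsp_a.append(i)
                        dsp_u.append(j)
                        dsp_fam.append(fam_slot(fid))

        self.tri_f = np.asarray(tri_f, dtype=np.int64)
        self.tri_m = np.asarray(tri_m, dtype=np.int64)
        self.tri_c = np.asarray(tri_c, dtype=np.int64)
        self.tri_fam = np.asarray(tri_fam, dtype=np.int64)
        self.dsp_a = np.asarray(dsp_a, dtype=np.int64)
        self.dsp_u = np.asarray(dsp_u, dtype=np.int64)
        self.dsp_fam = np.asarray(dsp_fam, dtype=np.int64)
        self.n_pdt_families = len(fam_of)
        self.fam_units = np.bincount(
            np.concatenate([self.tri_fam, self.dsp_fam]),
            minlength=self.n_pdt_families,
        ).astype(float) if self.n_pdt_families else np.empty(0)

    # -- scoring --------------------------------------------------------

    def wqls(self, counts2d: np.ndarray) -> np.ndarray:
        """Signed-root wQLS for each genotype column; nan where undefined."""
        if not self.wqls_ok or self.var_coef <= 0:
            return np.full(counts2d.shape[1], np.nan)
        Y = counts2d[self.used_idx] / 2.0
        p_hat = (self.a @ Y) / self.s11
        sigma2 = p_hat * (1.0 - p_hat) / 2.0
        U = self.b @ Y - p_hat * self.sr1
        V = sigma2 * self.var_coef
        with np.errstate(invalid="ignore", divide="ignore"):
            x = np.where(V > 0, np.sign(U) * np.sqrt(U * U / V), np.nan)
        return x

    def pdt(self, counts2d: np.ndarray) -> np.ndarray:
        """PDT-sum statistic for each genotype column; nan where undefined."""
        R = counts2d.shape[1]
        if self.n_pdt_families == 0:
            return np.full(R, np.nan)
        D = np.zeros((self.n_pdt_families, R))
        if len(self.tri_c):
            gf = counts2d[self.tri_f]
            gm = counts2d[self.tri_m]
            gc = counts2d[self.tri_c]
            n_het = (gf == 1).astype(float) + (gm == 1)
            hom_trans = (gf == 2).astype(float) + (gm == 2)
            contrib = 2.0 * (gc - hom_trans) - n_het
            np.add.at(D, self.tri_fam, contrib)
        if len(self.dsp_a):
            contrib = counts2d[self.dsp_a] - counts2d[self.dsp_u]
            np.add.at(D, self.dsp_fam, contrib)
        if self.pdt_variant == "avg":
            D = D / np.maximum(self.fam_units, 1.0)[:, None]
        num = D.sum(axis=0)
        den = (D * D).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(den > 0, num / np.sqrt(den), np.nan)

    def pdt_informative_families(self, counts1d: np.ndarray) -> int:
        """Number of families with a nonzero variance contribution."""
        if self.n_pdt_families == 0:
            return 0
        D = np.zeros(self.n_pdt_families)
        if len(self.tri_c):
            gf = counts1d[self.tri_f]
            gm = counts1d[self.tri_m]
            gc = counts1d[self.tri_c]
            contrib = 2.0 * (gc - (gf == 2) - (gm == 2)) - ((gf == 1) + (gm == 1))
            np.add.at(D, self.tri_fam, contrib)
        if len(self.dsp_a):
            np.add.at(D, self.dsp_fam, counts1d[self.dsp_a] - counts1d[self.dsp_u])
        return int((D != 0).sum())

    def compute(self, counts2d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return self.wqls(counts2d), self.pdt(counts2d)


def _observed_counts(design: HybridDesign, snp_id: str) -> tuple[int, np.ndarray]:
    s = design.snp_index(snp_id)
    c = design.genotypes[s].counts.astype(float).copy()
    c[np.isnan(c)] = 0.0  # masked out by the engine's index structures
    return s, c[:, None]


def wqls_statistic(
    design: HybridDesign,
    kin: KinshipMatrix,
    snp_id: str,
    case_weights: np.ndarray | None = None,
) -> float:
    """Signed-root wQLS at one SNP (positive = minor allele enriched in cases).

    Individuals with a missing genotype are dropped. Returns nan when the
    statistic is undefined (monomorphic among used samples); raises
    :class:`DegenerateSnpError` when no cases or no controls are typed or
    the kinship correlation block is singular.
    """
    s, c = _observed_counts(design, snp_id)
    eng = ComponentEngine(design, kin, s, case_weights=case_weights)
    if not eng.wqls_ok:
        raise DegenerateSnpError(
            f"SNP {snp_id}: wQLS needs at least one typed case and one typed control"
        )
    return float(eng.wqls(c)[0])


def pdt_statistic(design: HybridDesign, snp_id: str, variant: str = "sum") -> float:
    """PDT statistic at one SNP; nan when no family is informative.

    ``variant`` selects the family summary: 'sum' (default) adds every
    transmission and discordant-sib-pair contribution within a family;
    'avg' averages them, down-weighting large families.
    """
    s, c = _observed_counts(design, snp_id)
    kin_stub = KinshipMatrix(ids=[ind.key for ind in design.individuals], blocks={})
    eng = ComponentEngine(design, kin_stub, s, pdt_variant=variant)
    return float(eng.pdt(c)[0])


def compute_test_pair(design: HybridDesign, kin: KinshipMatrix, snp_id: str) -> TestPair:
    """Both component statistics plus bookkeeping counts."""
    s, c = _observed_counts(design, snp_id)
    eng = ComponentEngine(design, kin, s)
    x = float(eng.wqls(c)[0]) if eng.wqls_ok else np.nan
    y = float(eng.pdt(c)[0])
    return TestPair(
        x=x,
        y=y,
        n_informative_families=eng.pdt_informative_families(c[:, 0]),
        n_used_pop=eng.n_used_pop,
    )
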