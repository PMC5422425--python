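"""Shared builders for small pedigree/genotype fixtures.

Everything is constructed programmatically; no data files.
"""

from __future__ import annotations

import numpy as np
import pytest

from popfam.pedigree import (
    AFF_AFFECTED,
    AFF_UNAFFECTED,
    AFF_UNKNOWN,
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

_AFF = {2: AFF_AFFECTED, 1: AFF_UNAFFECTED, 0: AFF_UNKNOWN}
_SEX = {1: SEX_MALE, 2: SEX_FEMALE, 0: SEX_UNKNOWN}


def build_design(rows, counts=None, snp_id="SNP1"):
    """Build a design from compact row tuples.

    rows: (fid, pid, pat, mat, sex, aff, role) with pat/mat '0' for founder,
    sex/aff coded 1/2/0 as in PED files. counts: per-individual minor-allele
    counts (np.nan = missing) aligned with rows.
    """
    individuals = [
        Individual(
            person_id=pid,
            family_id=fid,
            father_id=None if pat == "0" else pat,
            mother_id=None if mat == "0" else mat,
            sex=_SEX[sex],
            affection=_AFF[aff],
            role=role,
        )
        for fid, pid, pat, mat, sex, aff, role in rows
    ]
    genotypes = []
    if counts is not None:
        genotypes = [GenotypeVector(snp_id=snp_id, alleles=("A", "G"), minor_allele="A",
                                    counts=np.asarray(counts, dtype=float))]
    return HybridDesign(individuals, genotypes)


def trio_rows(fid, aff_child=2, aff_fa=1, aff_mo=1):
    return [
        (fid, "fa", "0", "0", 1, aff_fa, ROLE_FAMILY),
        (fid, "mo", "0", "0", 2, aff_mo, ROLE_FAMILY),
        (fid, "ch", "fa", "mo", 0, aff_child, ROLE_FAMILY),
    ]


def control_rows(n, start=0):
    return [(f"C{start + k}", "1", "0", "0", 0, 1, ROLE_CONTROL) for k in range(n)]


def case_rows(n, start=0):
    return [(f"K{start + k}", "1", "0", "0", 0, 2, ROLE_CASE) for k in range(n)]


def random_pedigree_rows(rng, max_members=12, fid="R1"):
    """Random multi-generation pedigree (founder couples, random matings).

    Produces 2-3 generations with occasional within-pedigree matings so that
    inbred individuals and half-sib structures occur.
    """
    rows = [
        (fid, "f1", "0", "0", 1, 1, ROLE_FAMILY),
        (fid, "m1", "0", "0", 2, 1, ROLE_FAMILY),
        (fid, "f2", "0", "0", 1, 1, ROLE_FAMILY),
        (fid, "m2", "0", "0", 2, 1, ROLE_FAMILY),
    ]
    males = ["f1", "f2"]
    females = ["m1", "m2"]
    k = 0
    while len(rows) < max_members and k < max_members:
        k += 1
        fa = males[rng.integers(len(males))]
        mo = females[rng.integers(len(females))]
        pid = f"c{k}"
        sex = int(rng.integers(1, 3))
        rows.append((fid, pid, fa, mo, sex, int(rng.integers(1, 3)), ROLE_FAMILY))
        (males if sex == 1 else females).append(pid)
    return rows


def gene_drop_phi(design, n_drops, rng):
    """Brute-force Monte-Carlo kinship estimate via founder-allele labels.

    Each founder gets two unique labels; descendants inherit one random
    parental label per drop. The estimate for (i, j) is the average over
    drops of the probability that one allele sampled from each matches.
    Returns (phi_hat, phi_se) matrices.
    """
    n = design.n_individuals
    pat = np.empty((n, n_drops), dtype=np.int32)
    mat = np.empty((n, n_drops), dtype=np.int32)
    founders = np.flatnonzero(design.founder_mask)
    pat[founders] = (2 * founders)[:, None]
    mat[founders] = (2 * founders + 1)[:, None]
    for level in design.levels[1:]:
        fa = design.father_idx[level]
        mo = design.mother_idx[level]
        pick = rng.random((len(level), n_drops)) < 0.5
        pat[level] = np.where(pick, pat[fa], mat[fa])
        pick = rng.random((len(level), n_drops)) < 0.5
        mat[level] = np.where(pick, pat[mo], mat[mo])
    phi = np.empty((n, n))
    se = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            match = ((pat[i] == pat[j]).astype(float) + (pat[i] == mat[j])
                     + (mat[i] == pat[j]) + (mat[i] == mat[j])) / 4.0
            phi[i, j] = phi[j, i] = match.mean()
            se[i, j] = se[j, i] = match.std(ddof=1) / np.sqrt(n_drops)
    return phi, se


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
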