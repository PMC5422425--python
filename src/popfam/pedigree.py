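"""Pedigree and genotype data model for hybrid association designs.

A *hybrid design* mixes affected families, unrelated controls, and
(optionally) unrelated cases in one study. This module holds the data model
(:class:`Individual`, :class:`GenotypeVector`, :class:`HybridDesign`),
LINKAGE/PLINK PED+MAP text I/O with a roles sidecar, structural validation,
and recursive kinship-coefficient computation.

Genotypes are coded as minor-allele counts (0/1/2, ``nan`` = missing) with
the minor allele determined from control genotypes, falling back to all
samples when no controls are present. Allele "0" is the missing sentinel;
phenotype 0 or -9 means unknown affection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Individual",
    "GenotypeVector",
    "HybridDesign",
    "KinshipMatrix",
    "Finding",
    "PedigreeError",
    "read_ped",
    "write_ped",
    "kinship_matrix",
    "validate",
    "ROLE_FAMILY",
    "ROLE_CASE",
    "ROLE_CONTROL",
    "ROLE_REFERENCE",
]

ROLE_FAMILY = "family_member"
ROLE_CASE = "independent_case"
ROLE_CONTROL = "control"
ROLE_REFERENCE = "reference"
_ROLES = {ROLE_FAMILY, ROLE_CASE, ROLE_CONTROL, ROLE_REFERENCE}

SEX_MALE = "male"
SEX_FEMALE = "female"
SEX_UNKNOWN = "unknown"

AFF_AFFECTED = "affected"
AFF_UNAFFECTED = "unaffected"
AFF_UNKNOWN = "unknown"


class PedigreeError(ValueError):
    """Structured error for malformed pedigree input.

    Carries the offending file and line number when raised by the parser.
    """

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


@dataclass(frozen=True)
class Individual:
    person_id: str
    family_id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: str = SEX_UNKNOWN
    affection: str = AFF_UNKNOWN
    role: str = ROLE_FAMILY

    def __post_init__(self):
        if (self.father_id is None) != (self.mother_id is None):
            raise PedigreeError(
                f"individual {self.family_id}/{self.person_id}: father and mother "
                "must both be given or both be absent"
            )
        if self.role not in _ROLES:
            raise PedigreeError(
                f"individual {self.family_id}/{self.person_id}: unknown role {self.role!r}"
            )

    @property
    def is_founder(self) -> bool:
        return self.father_id is None

    @property
    def key(self) -> tuple[str, str]:
        return (self.family_id, self.person_id)


@dataclass
class GenotypeVector:
    """Per-SNP minor-allele counts for every individual in a design.

    ``counts`` is a float array aligned with ``HybridDesign.individuals``;
    entries are 0/1/2 or ``nan`` for missing.
    """

    snp_id: str
    alleles: tuple[str, str]  # (minor, major) labels
    minor_allele: str
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        ok = np.isnan(self.counts) | np.isin(self.counts, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = self.counts[~ok][0]
            raise PedigreeError(f"SNP {self.snp_id}: invalid genotype count {bad}")


class HybridDesign:
    """Validated container for pedigree structure, roles and genotypes.

    Builds index structures used throughout the package: parent index arrays,
    founder mask, topological generation levels (founders first) and
    per-family member lists. Raises :class:`PedigreeError` on structural
    problems (unresolved or sex-inconsistent parents, cycles, duplicate ids).
    """

    def __init__(self, individuals: list[Individual], genotypes: list[GenotypeVector] | None = None):
        self.individuals = list(individuals)
        self.genotypes = list(genotypes) if genotypes else []
        self._build_indexes()
        for g in self.genotypes:
            if len(g.counts) != self.n_individuals:
                raise PedigreeError(
                    f"SNP {g.snp_id}: {len(g.counts)} genotypes for {self.n_individuals} individuals"
                )

    # -- construction ---------------------------------------------------

    def _build_indexes(self) -> None:
        n = len(self.individuals)
        self._index: dict[tuple[str, str], int] = {}
        for i, ind in enumerate(self.individuals):
            if ind.key in self._index:
                raise PedigreeError(f"duplicate individual id {ind.key}")
            self._index[ind.key] = i

        self.father_idx = np.full(n, -1, dtype=np.int64)
        self.mother_idx = np.full(n, -1, dtype=np.int64)
        for i, ind in enumerate(self.individuals):
            if ind.is_founder:
                continue
            for attr, pid, want_sex in (
                ("father_idx", ind.father_id, SEX_MALE),
                ("mother_idx", ind.mother_id, SEX_FEMALE),
            ):
                key = (ind.family_id, pid)
                if key not in self._index:
                    raise PedigreeError(
                        f"individual {ind.key}: parent {pid!r} not found in family {ind.family_id}"
                    )
                j = self._index[key]
                psex = self.individuals[j].sex
                if psex not in (want_sex, SEX_UNKNOWN):
                    raise PedigreeError(
                        f"individual {ind.key}: parent {pid!r} has sex {psex}, expected {want_sex}"
                    )
                getattr(self, attr)[i] = j

        self.founder_mask = self.father_idx < 0

        # generation levels by longest path from a founder; cycle detection
        level = np.full(n, -1, dtype=np.int64)
        level[self.founder_mask] = 0
        pending = [i for i in range(n) if level[i] < 0]
        while pending:
            progressed = False
            nxt = []
            for i in pending:
                fa, mo = self.father_idx[i], self.mother_idx[i]
                if level[fa] >= 0 and level[mo] >= 0:
                    level[i] = 1 + max(level[fa], level[mo])
                    progressed = True
                else:
                    nxt.append(i)
            if not progressed:
                bad = self.individuals[nxt[0]]
                raise PedigreeError(f"cyclic pedigree involving {bad.key}")
            pending = nxt
        self.generation = level
        self.levels = [np.flatnonzero(level == g) for g in range(int(level.max()) + 1)] if n else []

        self.families: dict[str, np.ndarray] = {}
        fids: dict[str, list[int]] = {}
        for i, ind in enumerate(self.individuals):
            fids.setdefault(ind.family_id, []).append(i)
        self.families = {fid: np.asarray(ix, dtype=np.int64) for fid, ix in fids.items()}

        self.roles = np.asarray([ind.role for ind in self.individuals], dtype=object)
        self.affection = np.asarray([ind.affection for ind in self.individuals], dtype=object)
        self.sexes = np.asarray([ind.sex for ind in self.individuals], dtype=object)

    # -- access ---------------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def snp_ids(self) -> list[str]:
        return [g.snp_id for g in self.genotypes]

    def snp_index(self, snp_id: str) -> int:
        for i, g in enumerate(self.genotypes):
            if g.snp_id == snp_id:
                return i
        raise KeyError(f"unknown SNP {snp_id!r}")

    def index_of(self, family_id: str, person_id: str) -> int:
        return self._index[(family_id, person_id)]

    def children_of(self, i: int) -> np.ndarray:
        return np.flatnonzero((self.father_idx == i) | (self.mother_idx == i))

    def genotype_matrix(self) -> np.ndarray:
        """(n_snps, n_individuals) float matrix of minor-allele counts."""
        if not self.genotypes:
            return np.empty((0, self.n_individuals))
        return np.vstack([g.counts for g in self.genotypes])


@dataclass
class KinshipMatrix:
    """Pairwise kinship coefficients, stored as per-family dense blocks.

    phi_ij is the probability that one allele drawn at random from each of i
    and j is identical by descent. Individuals in different families have
    phi = 0 and are not stored.
    """

    ids: list[tuple[str, str]]
    blocks: dict[str, tuple[np.ndarray, np.ndarray]]  # fid -> (indices, phi block)

    def full(self) -> np.ndarray:
        n = len(self.ids)
        phi = np.zeros((n, n))
        for idx, block in self.blocks.values():
            phi[np.ix_(idx, idx)] = block
        return phi

    def phi_pair(self, i: int, j: int) -> float:
        fid_i = self.ids[i][0]
        if fid_i != self.ids[j][0]:
            return 0.0
        idx, block = self.blocks[fid_i]
        pos = {g: k for k, g in enumerate(idx)}
        return float(block[pos[i], pos[j]])


def kinship_matrix(design: HybridDesign) -> KinshipMatrix:
    """Recursive kinship coefficients for every individual in the design.

    Founders are assumed non-inbred and mutually unrelated. For i processed
    after all of its ancestors:

        phi(i, i) = 1/2 (1 + phi(father_i, mother_i))
        phi(i, j) = 1/2 (phi(father_i, j) + phi(mother_i, j))   (j processed earlier)

    Processing in topological order guarantees j is never a descendant of i
    when the second rule is applied.
    """
    blocks: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for fid, members in design.families.items():
        m = len(members)
        local = {g: k for k, g in enumerate(members)}
        block = np.zeros((m, m))
        fam_order = members[np.argsort(design.generation[members], kind="stable")]
        done: list[int] = []
        for i in fam_order:
            li = local[i]
            fa, mo = design.father_idx[i], design.mother_idx[i]
            if fa < 0:
                block[li, li] = 0.5
            else:
                block[li, li] = 0.5 * (1.0 + block[local[fa], local[mo]])
                for j in done:
                    lj = local[j]
                    v = 0.5 * (block[local[fa], lj] + block[local[mo], lj])
                    block[li, lj] = block[lj, li] = v
            done.append(i)
        blocks[fid] = (members, block)
    ids = [ind.key for ind in design.individuals]
    return KinshipMatrix(ids=ids, blocks=blocks)


# -- validation ---------------------------------------------------------


@dataclass(frozen=True)
class Finding:
    """A validation finding; data, not an exception."""

    kind: str  # mendelian | role_conflict | empty_genotypes
    family_id: str
    person_id: str
    snp_id: str | None
    message: str


def _transmission_range(g: float) -> tuple[int, int]:
    # range of minor-allele doses a parent with count g can transmit
    if np.isnan(g):
        return (0, 1)
    if g == 0:
        return (0, 0)
    if g == 2:
        return (1, 1)
    return (0, 1)


def validate(design: HybridDesign) -> list[Finding]:
    """Report Mendelian inconsistencies, role conflicts and empty genotypes.

    Mendelian checks use each parent's non-missing genotype to bound the
    child's possible minor-allele count; missing parents contribute the full
    range. Nothing is auto-fixed.
    """
    findings: list[Finding] = []
    G = design.genotype_matrix()
    for i, ind in enumerate(design.individuals):
        if ind.role == ROLE_CONTROL and ind.affection == AFF_AFFECTED:
            findings.append(
                Finding("role_conflict", ind.family_id, ind.person_id, None,
                        "control is marked affected")
            )
        if ind.role == ROLE_CASE and ind.affection == AFF_UNAFFECTED:
            findings.append(
                Finding("role_conflict", ind.family_id, ind.person_id, None,
                        "independent case is marked unaffected")
            )
        if design.genotypes and np.isnan(G[:, i]).all():
            findings.append(
                Finding("empty_genotypes", ind.family_id, ind.person_id, None,
                        "no non-missing genotypes")
            )
    for s, gv in enumerate(design.genotypes):
        for i, ind in enumerate(design.individuals):
            if ind.is_founder or np.isnan(G[s, i]):
                continue
            lo_f, hi_f = _transmission_range(G[s, design.father_idx[i]])
            lo_m, hi_m = _transmission_range(G[s, design.mother_idx[i]])
            if not (lo_f + lo_m <= G[s, i] <= hi_f + hi_m):
                findings.append(
                    Finding("mendelian", ind.family_id, ind.person_id, gv.snp_id,
                            f"child count {int(G[s, i])} impossible given parents")
                )
    return findings


# -- PED/MAP I/O --------------------------------------------------------

_SEX_IN = {"1": SEX_MALE, "2": SEX_FEMALE}
_SEX_OUT = {SEX_MALE: "1", SEX_FEMALE: "2", SEX_UNKNOWN: "0"}
_AFF_IN = {"2": AFF_AFFECTED, "1": AFF_UNAFFECTED, "0": AFF_UNKNOWN, "-9": AFF_UNKNOWN}
_AFF_OUT = {AFF_AFFECTED: "2", AFF_UNAFFECTED: "1", AFF_UNKNOWN: "0"}


def read_roles(path: str | Path) -> dict[tuple[str, str], str]:
    """Read a roles sidecar TSV with columns family_id, person_id, role."""
    roles: dict[tuple[str, str], str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            fields = line.split()
            if not fields or fields[0].startswith("#"):
                continue
            if fields == ["family_id", "person_id", "role"]:
                continue
            if len(fields) != 3:
                raise PedigreeError("expected 3 columns in roles file", str(path), ln)
            fid, pid, role = fields
            if role not in _ROLES:
                raise PedigreeError(f"unknown role {role!r}", str(path), ln)
            roles[(fid, pid)] = role
    return roles


def _default_role(family_rows: int, affection: str) -> str:
    if family_rows > 1:
        return ROLE_FAMILY
    return ROLE_CASE if affection == AFF_AFFECTED else ROLE_CONTROL


def read_ped(
    ped_path: str | Path,
    map_path: str | Path,
    roles: str | Path | dict[tuple[str, str], str] | None = None,
) -> HybridDesign:
    """Read a LINKAGE/PLINK text PED + MAP pair into a :class:`HybridDesign`.

    Parameters
    ----------
    ped_path, map_path
        Whitespace-delimited PED (FID IID PAT MAT SEX PHENO + two allele
        columns per SNP) and its MAP (SNP ids in column order; MAP lines may
        have 3 or 4 columns, the SNP id is the second).
    roles
        Sidecar TSV path or ``{(fid, pid): role}`` mapping. Unlisted samples
        get the default: members of multi-person families are
        ``family_member``; singletons are ``independent_case`` if affected,
        else ``control``.

    The minor allele of each SNP is estimated from control genotypes (all
    samples if there are no typed controls), ties broken lexicographically;
    allele "0" is missing.
    """
    snp_ids: list[str] = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 2:
                raise PedigreeError("MAP line needs at least 2 columns", str(map_path), ln)
            snp_ids.append(fields[1])

    role_map: dict[tuple[str, str], str]
    if roles is None:
        role_map = {}
    elif isinstance(roles, (str, Path)):
        role_map = read_roles(roles)
    else:
        role_map = dict(roles)

    rows: list[tuple] = []
    fam_sizes: dict[str, int] = {}
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * len(snp_ids):
                raise PedigreeError(
                    f"expected {6 + 2 * len(snp_ids)} columns, got {len(fields)}",
                    str(ped_path), ln,
                )
            fid, pid, pat, mat, sex, pheno = fields[:6]
            alleles = fields[6:]
            rows.append((ln, fid, pid, pat, mat, sex, pheno, alleles))
            fam_sizes[fid] = fam_sizes.get(fid, 0) + 1

    individuals: list[Individual] = []
    allele_data: list[list[tuple[str, str]]] = []
    for ln, fid, pid, pat, mat, sex, pheno, alleles in rows:
        affection = _AFF_IN.get(pheno, AFF_UNKNOWN)
        role = role_map.get((fid, pid), _default_role(fam_sizes[fid], affection))
        try:
            individuals.append(
                Individual(
                    person_id=pid,
                    family_id=fid,
                    father_id=None if pat == "0" else pat,
                    mother_id=None if mat == "0" else mat,
                    sex=_SEX_IN.get(sex, SEX_UNKNOWN),
                    affection=affection,
                    role=role,
                )
            )
        except PedigreeError as e:
            raise PedigreeError(str(e), str(ped_path), ln) from None
        allele_data.append([(alleles[2 * s], alleles[2 * s + 1]) for s in range(len(snp_ids))])

    # minor allele from controls (fallback: everyone)
    genotypes: list[GenotypeVector] = []
    control_rows = [i for i, ind in enumerate(individuals) if ind.role == ROLE_CONTROL]
    for s, snp in enumerate(snp_ids):
        counter: dict[str, int] = {}
        source = control_rows if control_rows else range(len(individuals))
        for i in source:
            for a in allele_data[i][s]:
                if a != "0":
                    counter[a] = counter.get(a, 0) + 1
        observed = set()
        for i in range(len(individuals)):
            observed.update(a for a in allele_data[i][s] if a != "0")
        if not observed:
            observed = {"0"}
        if not counter:  # source entirely missing at this SNP: count everyone
            for i in range(len(individuals)):
                for a in allele_data[i][s]:
                    if a != "0":
                        counter[a] = counter.get(a, 0) + 1
        if len(observed) > 2:
            raise PedigreeError(f"SNP {snp} has more than two alleles", str(ped_path))
        minor = min(sorted(observed), key=lambda a: (counter.get(a, 0), a))
        major = next((a for a in sorted(observed) if a != minor), minor)
        counts = np.full(len(individuals), np.nan)
        for i in range(len(individuals)):
            a1, a2 = allele_data[i][s]
            if a1 == "0" or a2 == "0":
                continue
            counts[i] = (a1 == minor) + (a2 == minor)
        genotypes.append(
            GenotypeVector(snp_id=snp, alleles=(minor, major), minor_allele=minor, counts=counts)
        )

    try:
        return HybridDesign(individuals, genotypes)
    except PedigreeError as e:
        raise PedigreeError(str(e), str(ped_path)) from None


def write_ped(
    design: HybridDesign,
    ped_path: str | Path,
    map_path: str | Path,
    roles_path: str | Path | None = None,
) -> None:
    """Write a design back to PED + MAP (+ optional roles TSV)."""
    with open(map_path, "w") as fh:
        for g in design.genotypes:
            fh.write(f"1 {g.snp_id} 0 0\n")
    with open(ped_path, "w") as fh:
        for i, ind in enumerate(design.individuals):
            row = [
                ind.family_id,
                ind.person_id,
                ind.father_id or "0",
                ind.mother_id or "0",
                _SEX_OUT[ind.sex],
                _AFF_OUT[ind.affection],
            ]
            for g in design.genotypes:
                minor, major = g.alleles
                c = g.counts[i]
                if np.isnan(c):
                    row += ["0", "0"]
                elif c == 2:
                    row += [minor, minor]
                elif c == 1:
                    row += [minor, major]
                else:
                    row += [major, major]
            fh.write(" ".join(row) + "\n")
    if roles_path is not None:
        with open(roles_path, "w") as fh:
            fh.write("family_id\tperson_id\trole\n")
            for ind in design.individuals:
                fh.write(f"{ind.family_id}\t{ind.person_id}\t{ind.role}\n")
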