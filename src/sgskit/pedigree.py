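"""Pedigree data model, validation, and meiosis counting.

A pedigree is a directed parent->child graph over individuals with case
(affected) and genotyped flags.  The family-power criterion used to select
extended families for shared-segment analysis is the number of meioses
(parent->child transmissions) in the minimal sub-pedigree connecting a set of
cases: families with fewer than 15 meioses between genotyped cases lack power
for segment sharing statistics.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Iterable

__all__ = [
    "Individual",
    "Pedigree",
    "CaseSubset",
    "PedigreeError",
    "read_pedigree",
    "read_pedigrees",
    "write_pedigree",
    "count_meioses",
    "eligible_family",
]

MALE, FEMALE, UNKNOWN = "male", "female", "unknown"

_SEX_CODES = {"1": MALE, "2": FEMALE, "0": UNKNOWN, "-9": UNKNOWN}
_SEX_OUT = {MALE: "1", FEMALE: "2", UNKNOWN: "0"}


class PedigreeError(ValueError):
    """Structural or reference error in a pedigree."""


@dataclass(frozen=True)
class Individual:
    """One pedigree member.

    A founder has both parent ids equal to ``None``; a non-founder must have
    both parents present in the same pedigree.
    """

    id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: str = UNKNOWN
    is_case: bool = False
    is_genotyped: bool = False

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None

    def __post_init__(self):
        if (self.father_id is None) != (self.mother_id is None):
            raise PedigreeError(
                f"individual {self.id!r}: both parents must be given or both missing"
            )
        if self.sex not in (MALE, FEMALE, UNKNOWN):
            raise PedigreeError(f"individual {self.id!r}: bad sex {self.sex!r}")


class Pedigree:
    """A validated single-family pedigree."""

    def __init__(self, family_id: str, individuals: Iterable[Individual]):
        self.family_id = str(family_id)
        self.individuals: dict[str, Individual] = {}
        for ind in individuals:
            if ind.id in self.individuals:
                raise PedigreeError(f"duplicate individual id {ind.id!r}")
            self.individuals[ind.id] = ind
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        if not self.individuals:
            raise PedigreeError(f"family {self.family_id}: empty pedigree")
        for ind in self.individuals.values():
            for pid, role, want in (
                (ind.father_id, "father", MALE),
                (ind.mother_id, "mother", FEMALE),
            ):
                if pid is None:
                    continue
                if pid == ind.id:
                    raise PedigreeError(
                        f"individual {ind.id!r} lists itself as {role}"
                    )
                parent = self.individuals.get(pid)
                if parent is None:
                    raise PedigreeError(
                        f"individual {ind.id!r}: missing {role} record {pid!r}"
                    )
                # parental-sex check skipped when sex unknown (ancestors)
                if parent.sex not in (want, UNKNOWN):
                    raise PedigreeError(
                        f"individual {ind.id!r}: {role} {pid!r} has sex {parent.sex}"
                    )
        if not any(i.is_founder for i in self.individuals.values()):
            raise PedigreeError(f"family {self.family_id}: no founder")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}  # 0 visiting, 1 done

        for start in self.individuals:
            if start in state:
                continue
            stack = [(start, iter(self._parent_ids(start)))]
            state[start] = 0
            while stack:
                node, parents = stack[-1]
                nxt = next(parents, None)
                if nxt is None:
                    state[node] = 1
                    stack.pop()
                    continue
                if state.get(nxt) == 0:
                    raise PedigreeError(
                        f"ancestry cycle detected at individual {nxt!r}"
                    )
                if nxt not in state:
                    state[nxt] = 0
                    stack.append((nxt, iter(self._parent_ids(nxt))))

    def _parent_ids(self, iid: str) -> list[str]:
        ind = self.individuals[iid]
        return [p for p in (ind.father_id, ind.mother_id) if p is not None]

    # -- views --------------------------------------------------------------
    @property
    def founders(self) -> list[Individual]:
        return [i for i in self.individuals.values() if i.is_founder]

    @property
    def cases(self) -> list[Individual]:
        return [i for i in self.individuals.values() if i.is_case]

    @property
    def genotyped_cases(self) -> list[Individual]:
        return [i for i in self.individuals.values() if i.is_case and i.is_genotyped]

    def couples(self) -> set[tuple[str, str]]:
        """All (father, mother) pairs that appear as parents."""
        return {
            (i.father_id, i.mother_id)
            for i in self.individuals.values()
            if not i.is_founder
        }

    def children_of(self, couple: tuple[str, str]) -> list[str]:
        f, m = couple
        return [
            i.id
            for i in self.individuals.values()
            if i.father_id == f and i.mother_id == m
        ]

    def with_genotyped(self, ids: Iterable[str]) -> "Pedigree":
        """Return a copy with ``is_genotyped`` set exactly on ``ids``."""
        ids = set(ids)
        missing = ids - self.individuals.keys()
        if missing:
            raise PedigreeError(f"unknown individuals marked genotyped: {sorted(missing)}")
        return Pedigree(
            self.family_id,
            [replace(i, is_genotyped=i.id in ids) for i in self.individuals.values()],
        )

    def __len__(self) -> int:
        return len(self.individuals)

    def __repr__(self) -> str:
        return (
            f"Pedigree({self.family_id!r}, n={len(self)}, "
            f"founders={len(self.founders)}, cases={len(self.cases)})"
        )


@dataclass
class CaseSubset:
    """A set of genotyped cases analyzed together for allelic sharing."""

    family_id: str
    member_ids: frozenset[str]
    n_meioses: int | None = None

    def __post_init__(self):
        self.member_ids = frozenset(self.member_ids)
        if self.n_meioses is not None and len(self.member_ids) >= 2:
            if self.n_meioses < len(self.member_ids) - 1:
                raise PedigreeError(
                    "n_meioses below the minimum for the subset size"
                )

    @property
    def size(self) -> int:
        return len(self.member_ids)


# -- file I/O ---------------------------------------------------------------

def _parse_rows(path) -> list[list[str]]:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            fields = line.split()
            if not fields or fields[0].startswith("#"):
                continue
            if len(fields) < 6:
                raise PedigreeError(f"{path}:{ln}: expected >= 6 columns")
            rows.append(fields[:6])
    return rows


def _row_to_individual(fid, iid, pat, mat, sex, pheno) -> Individual:
    father = None if pat == "0" else pat
    mother = None if mat == "0" else mat
    return Individual(
        id=iid,
        father_id=father,
        mother_id=mother,
        sex=_SEX_CODES.get(sex, UNKNOWN),
        is_case=(pheno == "2"),
    )


def read_pedigrees(path, dialect: str = "linkage") -> dict[str, Pedigree]:
    """Read all families from a LINKAGE pre-makeped / PLINK ``.fam`` file.

    Columns: FID IID PAT MAT SEX PHENO; ``0`` codes a missing parent;
    phenotype ``2`` = case, ``1`` = control, ``0``/``-9`` = unknown.  The two
    dialects share this 6-column layout (``linkage`` files may carry trailing
    marker columns, which are ignored here).
    """
    if dialect not in ("linkage", "plink_fam"):
        raise ValueError(f"unknown pedigree dialect {dialect!r}")
    by_family: dict[str, list[Individual]] = {}
    for fid, iid, pat, mat, sex, pheno in _parse_rows(path):
        by_family.setdefault(fid, []).append(
            _row_to_individual(fid, iid, pat, mat, sex, pheno)
        )
    return {fid: Pedigree(fid, inds) for fid, inds in by_family.items()}


def read_pedigree(path, dialect: str = "linkage", family_id: str | None = None) -> Pedigree:
    """Read a single family; error if the file holds several and none is named."""
    peds = read_pedigrees(path, dialect=dialect)
    if family_id is not None:
        try:
            return peds[family_id]
        except KeyError:
            raise PedigreeError(f"family {family_id!r} not in {path}") from None
    if len(peds) != 1:
        raise PedigreeError(
            f"{path} holds {len(peds)} families; pass family_id to choose one"
        )
    return next(iter(peds.values()))


def write_pedigree(ped: Pedigree, path, phenotype_missing: str = "1") -> None:
    """Write LINKAGE/.fam text (controls coded ``1`` by default)."""
    with open(path, "w") as fh:
        for ind in ped.individuals.values():
            fh.write(
                " ".join(
                    [
                        ped.family_id,
                        ind.id,
                        ind.father_id or "0",
                        ind.mother_id or "0",
                        _SEX_OUT[ind.sex],
                        "2" if ind.is_case else phenotype_missing,
                    ]
                )
                + "\n"
            )


# -- meiosis counting -------------------------------------------------------

def _paths_to_couple(ped: Pedigree, iid: str, couple: tuple[str, str],
                     _memo=None) -> list[frozenset]:
    """All edge sets of descent paths from ``couple`` down to ``iid``.

    Edges are (couple, child) pairs; each corresponds to one meiosis in the
    connecting tree (one transmission from the couple to the child).  An
    individual who is a member of the couple has the empty path.
    """
    if _memo is None:
        _memo = {}
    if iid in _memo:
        return _memo[iid]
    out: list[frozenset] = []
    if iid in couple:
        out.append(frozenset())
    ind = ped.individuals[iid]
    if not ind.is_founder:
        own = (ind.father_id, ind.mother_id)
        edge = (own, iid)
        if own == couple:
            out.append(frozenset([edge]))
        else:
            for parent in own:
                for sub in _paths_to_couple(ped, parent, couple, _memo):
                    out.append(sub | {edge})
    # de-duplicate edge sets arising from loops
    out = list(dict.fromkeys(out))
    _memo[iid] = out
    return out


def count_meioses(ped: Pedigree, cases: Iterable[str],
                  max_combinations: int = 200_000) -> int:
    """Number of meioses in the minimal sub-pedigree connecting ``cases``.

    The count is the number of parent->child transmission edges in the union,
    over a common-ancestor couple, of the descent paths linking every case.
    On multiply-connected pedigrees the minimum over admissible ancestor
    couples (and over alternative descent paths) is returned.
    """
    cases = sorted(set(cases))
    if len(cases) < 2:
        raise ValueError("need at least two cases to count meioses")
    for c in cases:
        if c not in ped.individuals:
            raise PedigreeError(f"case {c!r} not in family {ped.family_id}")

    best: int | None = None
    for couple in sorted(ped.couples()):
        memo: dict = {}
        per_case = [_paths_to_couple(ped, c, couple, memo) for c in cases]
        if any(not p for p in per_case):
            continue  # couple is not an ancestor of every case
        n_comb = 1
        for p in per_case:
            n_comb *= len(p)
        if n_comb <= max_combinations:
            for combo in itertools.product(*per_case):
                union = frozenset().union(*combo)
                if best is None or len(union) < best:
                    best = len(union)
        else:
            # greedy fallback for pathological loop counts: grow the union
            # case by case, always picking the path overlapping it most
            union: set = set()
            for paths in sorted(per_case, key=len):
                pick = min(paths, key=lambda p: len(p - union))
                union |= pick
            if best is None or len(union) < best:
                best = len(union)
    if best is None:
        raise PedigreeError(
            f"cases {cases} are not connected by any ancestor couple in "
            f"family {ped.family_id}"
        )
    return best


def eligible_family(
    ped: Pedigree,
    fsir_p: float,
    min_cases_dna: int = 3,
    max_fsir_p: float = 0.05,
    min_meioses: int = 15,
) -> bool:
    """Family selection rule: significant familial excess (p < 0.05), at
    least ``min_cases_dna`` genotyped cases, and at least ``min_meioses``
    meioses between the genotyped cases."""
    if not 0.0 <= fsir_p <= 1.0:
        raise ValueError("fsir_p must be a probability")
    if fsir_p >= max_fsir_p:
        return False
    gcases = [i.id for i in ped.genotyped_cases]
    if len(gcases) < min_cases_dna:
        return False
    return count_meioses(ped, gcases) >= min_meioses
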