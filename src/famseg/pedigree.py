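"""Pedigree (PED) parsing, validation, and family queries.

The 6-column PED dialect is used throughout: family, individual, father,
mother, sex (1=male, 2=female, 0=unknown), phenotype (2=affected,
1=unaffected, 0 or -9=unknown). Individuals referenced only as parents are
materialized as unsequenced, unknown-status placeholders so that pedigrees
with unsequenced connector individuals remain well-formed. No assumptions
are made about the genotype or phenotype of individuals who were not
sequenced: they simply impose no segregation constraint downstream.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import IO, Iterable, Optional, Union

import networkx as nx


class PedigreeError(ValueError):
    """Raised for malformed or internally inconsistent pedigrees."""


class Sex(enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Status(enum.Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


_SEX_CODES = {"1": Sex.MALE, "2": Sex.FEMALE, "0": Sex.UNKNOWN}
_SEX_TO_CODE = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
# -9 and 0 both mean unknown; dialects differ and the distinction carries
# no information for segregation analysis.
_STATUS_CODES = {"2": Status.AFFECTED, "1": Status.UNAFFECTED,
                 "0": Status.UNKNOWN, "-9": Status.UNKNOWN}
_STATUS_TO_CODE = {Status.AFFECTED: "2", Status.UNAFFECTED: "1", Status.UNKNOWN: "0"}


@dataclass
class Individual:
    individual_id: str
    family_id: str
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    sex: Sex = Sex.UNKNOWN
    status: Status = Status.UNKNOWN
    sequenced: bool = False

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


@dataclass
class Family:
    family_id: str
    members: dict[str, Individual] = field(default_factory=dict)

    def add(self, ind: Individual) -> None:
        if ind.individual_id in self.members:
            raise PedigreeError(
                f"duplicate individual {ind.individual_id!r} in family {self.family_id!r}"
            )
        self.members[ind.individual_id] = ind

    @property
    def affected(self) -> list[Individual]:
        return [m for m in self.members.values() if m.status is Status.AFFECTED]

    @property
    def sequenced_members(self) -> list[Individual]:
        return [m for m in self.members.values() if m.sequenced]

    def parents_of(self, individual_id: str) -> tuple[Optional[Individual], Optional[Individual]]:
        """(father, mother) of an individual; None for absent links."""
        ind = self.members[individual_id]
        father = self.members.get(ind.father_id) if ind.father_id else None
        mother = self.members.get(ind.mother_id) if ind.mother_id else None
        return father, mother

    def parent_graph(self) -> nx.DiGraph:
        """Directed graph with edges parent -> child."""
        g = nx.DiGraph()
        g.add_nodes_from(self.members)
        for ind in self.members.values():
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None and pid in self.members:
                    g.add_edge(pid, ind.individual_id)
        return g


def _parse_row(fields: list[str], lineno: int) -> Individual:
    fam, iid, fa, mo, sex, pheno = fields[:6]
    if sex not in _SEX_CODES:
        raise PedigreeError(f"line {lineno}: bad sex code {sex!r}")
    if pheno not in _STATUS_CODES:
        raise PedigreeError(f"line {lineno}: bad phenotype code {pheno!r}")
    return Individual(
        individual_id=iid,
        family_id=fam,
        father_id=None if fa == "0" else fa,
        mother_id=None if mo == "0" else mo,
        sex=_SEX_CODES[sex],
        status=_STATUS_CODES[pheno],
    )


def parse_ped(stream: Union[IO[str], Iterable[str], str]) -> list[Family]:
    """Parse a 6-column PED stream into a list of families.

    Accepts an open text stream, an iterable of lines, or a string of PED
    text. Comment lines starting with ``#`` and blank lines are skipped.
    Rows with fewer than six whitespace-delimited columns raise
    :class:`PedigreeError` naming the line number, as do duplicate
    (family, individual) rows. Parents referenced but not listed as rows
    are added as placeholder members with unknown sex/status, except that
    their sex is inferred from the slot (father=male, mother=female).

    Families are returned sorted by family ID; the result is insensitive
    to input row order.
    """
    if isinstance(stream, str):
        stream = stream.splitlines()
    families: dict[str, Family] = {}
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 6:
            raise PedigreeError(
                f"line {lineno}: expected >=6 columns, got {len(fields)}"
            )
        ind = _parse_row(fields, lineno)
        fam = families.setdefault(ind.family_id, Family(ind.family_id))
        if ind.individual_id in fam.members:
            raise PedigreeError(
                f"line {lineno}: duplicate individual {ind.individual_id!r} "
                f"in family {ind.family_id!r}"
            )
        fam.add(ind)
    for fam in families.values():
        _materialize_placeholder_parents(fam)
    return [families[fid] for fid in sorted(families)]


def _materialize_placeholder_parents(fam: Family) -> None:
    for ind in list(fam.members.values()):
        for pid, sex in ((ind.father_id, Sex.MALE), (ind.mother_id, Sex.FEMALE)):
            if pid is not None and pid not in fam.members:
                fam.add(Individual(individual_id=pid, family_id=fam.family_id, sex=sex))


def write_ped(families: list[Family], sink: IO[str]) -> None:
    """Write families back to canonical 6-column PED (absent parents as "0")."""
    for fam in sorted(families, key=lambda f: f.family_id):
        for iid in sorted(fam.members):
            ind = fam.members[iid]
            sink.write("\t".join([
                fam.family_id,
                ind.individual_id,
                ind.father_id or "0",
                ind.mother_id or "0",
                _SEX_TO_CODE[ind.sex],
                _STATUS_TO_CODE[ind.status],
            ]) + "\n")


@dataclass
class Issue:
    severity: str  # "warning" | "error"
    individual_id: Optional[str]
    message: str


def validate_family(fam: Family, vcf_samples: set[str]) -> list[Issue]:
    """Validate one family against the VCF sample set.

    Side effect: sets ``sequenced`` on each member according to whether its
    ID appears in ``vcf_samples``. Members absent from the VCF are not an
    error — they become unsequenced and impose no constraint downstream.
    Non-fatal inconsistencies (parent sex mismatch) are returned as issues;
    cyclic parentage is fatal and raises :class:`PedigreeError`.
    """
    g = fam.parent_graph()
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise PedigreeError(
            f"family {fam.family_id!r}: cyclic parentage {cycle}"
        )
    issues: list[Issue] = []
    for ind in fam.members.values():
        ind.sequenced = ind.individual_id in vcf_samples
        if not ind.sequenced:
            issues.append(Issue("warning", ind.individual_id,
                                "not in VCF; treated as unsequenced"))
    for ind in fam.members.values():
        father, mother = fam.parents_of(ind.individual_id)
        if father is not None and father.sex is Sex.FEMALE:
            issues.append(Issue("error", ind.individual_id,
                                f"father {father.individual_id!r} has sex=female"))
        if mother is not None and mother.sex is Sex.MALE:
            issues.append(Issue("error", ind.individual_id,
                                f"mother {mother.individual_id!r} has sex=male"))
    if not fam.affected:
        issues.append(Issue("warning", None,
                            "no affected member; family will yield no hits"))
    return issues
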