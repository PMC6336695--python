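"""Pedigree reading, validation, and peeling-order construction.

Pedigrees come in as classic 6-column linkage-format PED files
(family, individual, father, mother, sex, phenotype) with ``0`` parent ids
marking founders, sex coded 1=male / 2=female / 0=unknown, and phenotype
coded 1=unaffected / 2=affected / 0 or -9=unknown.  Probands are not a PED
column; they are flagged through a sidecar list because ascertainment
information lives outside the genotype file.

The module also derives the *peeling order* used by the exact pedigree
likelihood: a sequence of nuclear families such that each processed unit
touches the unprocessed remainder through exactly one pivot individual.
Marriage loops (e.g. first-cousin matings) are detected at parse time and
only rejected when a peeling order is requested; small looped pedigrees are
handled downstream by full enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .errors import PedParseError, PedValidationError, PedigreeLoopError

__all__ = [
    "Sex",
    "Affection",
    "PedigreeMember",
    "Pedigree",
    "NuclearUnit",
    "read_ped",
    "write_ped",
    "founders",
    "peeling_order",
]


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Affection(str, Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


_SEX_FROM_CODE = {"1": Sex.MALE, "2": Sex.FEMALE, "0": Sex.UNKNOWN}
_CODE_FROM_SEX = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
_AFF_FROM_CODE = {
    "1": Affection.UNAFFECTED,
    "2": Affection.AFFECTED,
    "0": Affection.UNKNOWN,
    "-9": Affection.UNKNOWN,
}
_CODE_FROM_AFF = {
    Affection.UNAFFECTED: "1",
    Affection.AFFECTED: "2",
    Affection.UNKNOWN: "0",
}


@dataclass(frozen=True)
class PedigreeMember:
    """One individual of a family.

    ``father_id``/``mother_id`` are ``None`` for founders; the two are always
    both present or both absent.
    """

    family_id: str
    individual_id: str
    father_id: str | None
    mother_id: str | None
    sex: Sex = Sex.UNKNOWN
    affection: Affection = Affection.UNKNOWN
    is_proband: bool = False

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None

    def __post_init__(self) -> None:
        if (self.father_id is None) != (self.mother_id is None):
            raise PedValidationError(
                f"{self.family_id}/{self.individual_id}: exactly one parent given; "
                "founders must have both parents missing"
            )


@dataclass(frozen=True)
class NuclearUnit:
    """A father-mother couple with their children; ``pivot`` connects the unit
    to the rest of the pedigree (``None`` for the final unit of a component)."""

    father_id: str
    mother_id: str
    children: tuple[str, ...]
    pivot: str | None

    @property
    def member_ids(self) -> tuple[str, ...]:
        return (self.father_id, self.mother_id) + self.children


class Pedigree:
    """A validated family graph with ordered members."""

    def __init__(self, family_id: str, members: Sequence[PedigreeMember]):
        self.family_id = family_id
        self.members: list[PedigreeMember] = list(members)
        self._by_id = {m.individual_id: m for m in self.members}
        self._validate()
        self.loops_present = self._detect_loops()

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self._by_id

    def member(self, individual_id: str) -> PedigreeMember:
        return self._by_id[individual_id]

    @property
    def member_ids(self) -> list[str]:
        return [m.individual_id for m in self.members]

    @property
    def probands(self) -> list[PedigreeMember]:
        return [m for m in self.members if m.is_proband]

    @property
    def affected(self) -> list[PedigreeMember]:
        return [m for m in self.members if m.affection is Affection.AFFECTED]

    def founders(self) -> list[PedigreeMember]:
        return [m for m in self.members if m.is_founder]

    def nonfounders(self) -> list[PedigreeMember]:
        return [m for m in self.members if not m.is_founder]

    def children_of(self, individual_id: str) -> list[PedigreeMember]:
        return [
            m
            for m in self.members
            if individual_id in (m.father_id, m.mother_id)
        ]

    def couples(self) -> dict[tuple[str, str], list[str]]:
        """(father_id, mother_id) -> child ids, in member order."""
        out: dict[tuple[str, str], list[str]] = {}
        for m in self.members:
            if not m.is_founder:
                out.setdefault((m.father_id, m.mother_id), []).append(
                    m.individual_id
                )
        return out

    def with_probands(self, proband_ids: Iterable[str]) -> "Pedigree":
        wanted = set(proband_ids)
        unknown = wanted - set(self._by_id)
        if unknown:
            raise PedValidationError(
                f"family {self.family_id}: unknown proband ids {sorted(unknown)}"
            )
        members = [
            replace(m, is_proband=(m.individual_id in wanted)) for m in self.members
        ]
        return Pedigree(self.family_id, members)

    # -- validation ---------------------------------------------------------

    def _validate(self) -> None:
        if len(self._by_id) != len(self.members):
            seen, dups = set(), set()
            for m in self.members:
                (dups if m.individual_id in seen else seen).add(m.individual_id)
            raise PedValidationError(
                f"family {self.family_id}: duplicate individual ids {sorted(dups)}"
            )
        father_roles: set[str] = set()
        mother_roles: set[str] = set()
        for m in self.members:
            if m.individual_id in (m.father_id, m.mother_id):
                raise PedValidationError(
                    f"family {self.family_id}: {m.individual_id} listed as its own parent"
                )
            for pid, role in ((m.father_id, "father"), (m.mother_id, "mother")):
                if pid is None:
                    continue
                parent = self._by_id.get(pid)
                if parent is None:
                    raise PedValidationError(
                        f"family {self.family_id}: {m.individual_id} references "
                        f"unresolved {role} id {pid!r}"
                    )
                want = Sex.MALE if role == "father" else Sex.FEMALE
                if parent.sex not in (want, Sex.UNKNOWN):
                    raise PedValidationError(
                        f"family {self.family_id}: {pid} has sex {parent.sex.value} "
                        f"but is listed as {role} of {m.individual_id}"
                    )
                (father_roles if role == "father" else mother_roles).add(pid)
        both = father_roles & mother_roles
        if both:
            raise PedValidationError(
                f"family {self.family_id}: individuals appear as both father and "
                f"mother: {sorted(both)}"
            )
        dg = nx.DiGraph()
        dg.add_nodes_from(self._by_id)
        for m in self.members:
            for pid in (m.father_id, m.mother_id):
                if pid is not None:
                    dg.add_edge(pid, m.individual_id)
        if not nx.is_directed_acyclic_graph(dg):
            raise PedValidationError(
                f"family {self.family_id}: cyclic ancestry detected"
            )

    def _detect_loops(self) -> bool:
        # Marriage-node graph: individuals plus one node per couple; a cycle in
        # the undirected graph means a pedigree loop (e.g. consanguinity).
        g = nx.Graph()
        g.add_nodes_from(self._by_id)
        for (fid, mid), children in self.couples().items():
            cnode = ("couple", fid, mid)
            g.add_edge(fid, cnode)
            g.add_edge(mid, cnode)
            for c in children:
                g.add_edge(cnode, c)
        return len(nx.cycle_basis(g)) > 0


def founders(p: Pedigree) -> list[PedigreeMember]:
    """Members with both parents missing (the complement of non-founders)."""
    return p.founders()


def peeling_order(p: Pedigree) -> list[NuclearUnit]:
    """Order the nuclear families of ``p`` for likelihood peeling.

    Each returned unit shares exactly one individual (its pivot) with the
    not-yet-processed remainder; the last unit of each connected component has
    ``pivot=None`` and is summed out entirely.  Raises
    :class:`PedigreeLoopError` when the pedigree contains marriage loops.
    """
    if p.loops_present:
        raise PedigreeLoopError(
            f"family {p.family_id}: loop pedigree; use enumeration fallback"
        )
    remaining = [
        (fid, mid, tuple(children)) for (fid, mid), children in p.couples().items()
    ]
    order: list[NuclearUnit] = []
    while remaining:
        membership: dict[str, int] = {}
        for unit in remaining:
            for ind in (unit[0], unit[1], *unit[2]):
                membership[ind] = membership.get(ind, 0) + 1
        chosen = None
        for i, unit in enumerate(remaining):
            shared = [
                ind
                for ind in dict.fromkeys((unit[0], unit[1], *unit[2]))
                if membership[ind] > 1
            ]
            if len(shared) <= 1:
                chosen = (i, unit, shared[0] if shared else None)
                break
        if chosen is None:  # pragma: no cover - guarded by loops_present
            raise PedigreeLoopError(
                f"family {p.family_id}: no peelable nuclear unit; loop pedigree"
            )
        i, (fid, mid, children), pivot = chosen
        del remaining[i]
        order.append(NuclearUnit(fid, mid, children, pivot))
    return order


# -- PED I/O ----------------------------------------------------------------


def read_ped(
    path: str | Path,
    probands: Iterable[tuple[str, str]] | Iterable[str] | None = None,
) -> list[Pedigree]:
    """Parse a whitespace-delimited 6+ column linkage PED file.

    Returns one :class:`Pedigree` per distinct family id, preserving member
    order.  ``probands`` may be given as ``(family_id, individual_id)`` pairs
    or bare individual ids (matched in any family).
    """
    path = Path(path)
    rows: dict[str, list[PedigreeMember]] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise PedParseError(
                    f"{path.name}:{lineno}: expected >=6 columns, got {len(fields)}"
                )
            fam, ind, fa, mo, sex_code, pheno_code = fields[:6]
            if sex_code not in _SEX_FROM_CODE:
                raise PedParseError(
                    f"{path.name}:{lineno}: bad sex code {sex_code!r}"
                )
            if pheno_code not in _AFF_FROM_CODE:
                raise PedParseError(
                    f"{path.name}:{lineno}: bad phenotype code {pheno_code!r}"
                )
            try:
                member = PedigreeMember(
                    family_id=fam,
                    individual_id=ind,
                    father_id=None if fa == "0" else fa,
                    mother_id=None if mo == "0" else mo,
                    sex=_SEX_FROM_CODE[sex_code],
                    affection=_AFF_FROM_CODE[pheno_code],
                )
            except PedValidationError as exc:
                raise PedParseError(f"{path.name}:{lineno}: {exc}") from exc
            rows.setdefault(fam, []).append(member)
    pedigrees = [Pedigree(fam, members) for fam, members in rows.items()]
    if probands is not None:
        by_family: dict[str, set[str]] = {}
        loose: set[str] = set()
        for item in probands:
            if isinstance(item, str):
                loose.add(item)
            else:
                fam, ind = item
                by_family.setdefault(fam, set()).add(ind)
        pedigrees = [
            ped.with_probands(
                by_family.get(ped.family_id, set())
                | {i for i in loose if i in ped}
            )
            for ped in pedigrees
        ]
    return pedigrees


def write_ped(pedigrees: Iterable[Pedigree], path: str | Path) -> Path:
    """Write pedigrees as canonical tab-delimited 6-column PED."""
    path = Path(path)
    with path.open("w") as fh:
        for ped in pedigrees:
            for m in ped.members:
                fh.write(
                    "\t".join(
                        [
                            m.family_id,
                            m.individual_id,
                            m.father_id or "0",
                            m.mother_id or "0",
                            _CODE_FROM_SEX[m.sex],
                            _CODE_FROM_AFF[m.affection],
                        ]
                    )
                    + "\n"
                )
    return path
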