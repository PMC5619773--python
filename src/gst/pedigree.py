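"""Pedigree parsing and family structure.

The family configuration decides which indicator equations apply
downstream: when both parents are genotyped (Condition 1) only the
offspring contribute to the pattern frequency (C = V - 2); otherwise
(Condition 2) every genotyped member is treated as an offspring (C = V).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

log = logging.getLogger(__name__)

ROLE_FATHER = "father"
ROLE_MOTHER = "mother"
ROLE_OFFSPRING = "offspring"


@dataclass(frozen=True)
class FamilyMember:
    """One pedigree member.

    ``index_v`` is the 1-based member index: the father is v = 1 and the
    mother v = 2 when both are genotyped, offspring follow in file order.
    ``disease_state`` is 0 for unaffected, 1 for affected. Members with
    ``has_data = False`` stay in the structure (they define roles) but
    never contribute genotypes.
    """

    member_id: str
    index_v: int
    role: str
    disease_state: int
    has_data: bool

    @property
    def affected(self) -> bool:
        return self.disease_state == 1


@dataclass
class FamilyStructure:
    """Ordered family roster with the derived analysis constants."""

    members: list[FamilyMember] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [m.member_id for m in self.members]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate member_id in pedigree")
        if sum(1 for m in self.members if m.role == ROLE_FATHER) > 1:
            raise ValueError("more than one father in pedigree")
        if sum(1 for m in self.members if m.role == ROLE_MOTHER) > 1:
            raise ValueError("more than one mother in pedigree")
        if not any(m.affected for m in self.members):
            raise ValueError("pedigree contains no affected member; analysis is vacuous")

    @property
    def by_id(self) -> dict[str, FamilyMember]:
        return {m.member_id: m for m in self.members}

    @property
    def father(self) -> FamilyMember | None:
        return next((m for m in self.members if m.role == ROLE_FATHER), None)

    @property
    def mother(self) -> FamilyMember | None:
        return next((m for m in self.members if m.role == ROLE_MOTHER), None)

    @property
    def data_members(self) -> list[FamilyMember]:
        """Members with genotype data, in roster order."""
        return [m for m in self.members if m.has_data]

    @property
    def V(self) -> int:
        """Number of members with genotype data."""
        return len(self.data_members)

    @property
    def condition(self) -> int:
        """1 when both parents are genotyped, else 2."""
        f, m = self.father, self.mother
        return 1 if (f is not None and f.has_data and m is not None and m.has_data) else 2

    @property
    def C(self) -> int:
        """Count of members contributing to the pattern frequency."""
        return self.V - 2 if self.condition == 1 else self.V

    def contributing_members(self) -> list[FamilyMember]:
        """Members whose indicators are summed into LF_j."""
        if self.condition == 1:
            return [m for m in self.data_members if m.role == ROLE_OFFSPRING]
        return self.data_members


def _parse_affection(raw: list[str]) -> list[int]:
    # PED convention uses 1/2 (2 = affected); a column is read as the
    # disease state S in {0,1} only when it contains a 0 and no 2.
    vals = [int(float(x)) for x in raw]
    if any(v == 0 for v in vals) and all(v < 2 for v in vals):
        return vals
    return [1 if v == 2 else 0 for v in vals]


def read_pedigree(path: str) -> FamilyStructure:
    """Read a PED-like pedigree file into a :class:`FamilyStructure`.

    Accepts whitespace- or tab-delimited rows with columns
    ``member_id father_id mother_id sex affection [data_flag]``; a leading
    family-id column (classic 6-column PED plus a data flag) is detected
    and dropped. Lines starting with ``#`` and an optional header row are
    ignored. Affection is PED-coded (1 = unaffected, 2 = affected) when
    any value ≥ 2 appears, otherwise 0/1. ``data_flag = 0`` keeps the
    member but marks them as having no genotype data.
    """
    rows: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rows.append(line.split())
    if not rows:
        raise ValueError(f"empty pedigree file: {path}")
    # header detection: first row whose affection column is not numeric
    def _numeric(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    ncol = len(rows[0])
    if ncol < 5:
        raise ValueError("pedigree needs at least member_id, father_id, mother_id, sex, affection")
    if not _numeric(rows[0][-1]) or not _numeric(rows[0][-2]):
        rows = rows[1:]
        if not rows:
            raise ValueError(f"pedigree file has only a header: {path}")

    # 7+ columns => leading family id (ignored; single-family tool)
    width = len(rows[0])
    parsed = []
    for r in rows:
        if len(r) != width:
            raise ValueError(f"ragged pedigree row: {r}")
        r = r[1:] if width >= 7 else r
        member_id, father_id, mother_id = r[0], r[1], r[2]
        affection = r[4]
        data_flag = r[5] if len(r) >= 6 else "1"
        parsed.append((member_id, father_id, mother_id, affection, data_flag))

    ids = [p[0] for p in parsed]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate member_id in pedigree")

    affections = _parse_affection([p[3] for p in parsed])

    father_ids = {p[1] for p in parsed if p[1] not in ("0", ".", "")}
    mother_ids = {p[2] for p in parsed if p[2] not in ("0", ".", "")}
    if len(father_ids) > 1 or len(mother_ids) > 1 or len(father_ids | mother_ids) > 2:
        raise ValueError("more than two parents referenced in pedigree")

    members: list[FamilyMember] = []
    # parents first (father v=1, mother v=2), then offspring in file order
    order: list[tuple[str, str]] = []
    for mid in ids:
        if mid in father_ids:
            order.append((mid, ROLE_FATHER))
    for mid in ids:
        if mid in mother_ids:
            order.append((mid, ROLE_MOTHER))
    for mid in ids:
        if mid not in father_ids and mid not in mother_ids:
            order.append((mid, ROLE_OFFSPRING))

    aff_by_id = dict(zip(ids, affections))
    data_by_id = {p[0]: p[4] not in ("0",) for p in parsed}
    for v, (mid, role) in enumerate(order, start=1):
        members.append(FamilyMember(
            member_id=mid, index_v=v, role=role,
            disease_state=aff_by_id[mid], has_data=data_by_id[mid],
        ))
    fam = FamilyStructure(members)
    log.info("pedigree: V=%d condition=%d C=%d", fam.V, fam.condition, fam.C)
    return fam
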