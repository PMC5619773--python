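"""Per-site segregation indicators and the pattern frequency LF_j.

Each data-bearing member receives an indicator I(SNV_jv) at each site j:
0 when the member's genotype is consistent with a causative variant
segregating with disease, 1 when inconsistent (0.5 for a partially
consistent affected member without parental data). The pattern frequency
LF_j is the sum of the contributing members' indicators; LF_j = 0 marks a
site where patients and unaffected members separate perfectly.

Two family configurations apply:

* Condition 1 — both parents genotyped. Offspring are scored against the
  reference allele and both parents' genotypes; only offspring contribute
  (C = V - 2).
* Condition 2 — at most one parent genotyped. Everyone is scored as an
  offspring (C = V): an unaffected member is consistent when homozygous
  reference; an affected member is consistent when carrying the modal
  affected genotype MSNV_j, provided that modal genotype differs from the
  reference.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field

from gst.pedigree import FamilyStructure, ROLE_OFFSPRING
from gst.variants import GenotypeCall, SiteRecord, SiteTable

log = logging.getLogger(__name__)

MISSING_POLICY_ONE = "one"    # missing genotype scores I = 1
MISSING_POLICY_SKIP = "skip"  # missing genotype drops the member at that site


def determine_condition(family: FamilyStructure) -> int:
    """Return 1 when both parents carry genotype data, else 2."""
    return family.condition


def _parent_calls(site: SiteRecord, family: FamilyStructure):
    unaff, aff = [], []
    for parent in (family.father, family.mother):
        if parent is None or not parent.has_data:
            continue
        call = site.genotypes.get(parent.member_id, GenotypeCall.miss())
        (aff if parent.affected else unaff).append(call)
    return unaff, aff


def indicator_condition1(site: SiteRecord, family: FamilyStructure,
                         missing_policy: str = MISSING_POLICY_ONE) -> dict[str, float | None]:
    """Indicators for each genotyped offspring under Condition 1.

    An unaffected offspring is consistent (I = 0) when the reference,
    every unaffected parent and the offspring share the same genotype and
    that genotype differs from every affected parent's. An affected
    offspring is consistent when every unaffected parent is homozygous
    reference, the offspring is not, and the offspring matches every
    affected parent. When no parent of the required disease state exists
    the corresponding clause is dropped. Any missing genotype in the
    comparison forces I = 1 (or removes the member under ``skip``).
    """
    if family.condition != 1:
        raise ValueError("indicator_condition1 requires both parents genotyped")
    unaff_par, aff_par = _parent_calls(site, family)
    ref_hom = GenotypeCall.hom_ref(site.ref_allele)
    out: dict[str, float | None] = {}
    parents_missing = any(c.missing for c in unaff_par + aff_par)
    for member in family.data_members:
        if member.role != ROLE_OFFSPRING:
            continue
        g = site.genotypes.get(member.member_id, GenotypeCall.miss())
        if g.missing:
            out[member.member_id] = None if missing_policy == MISSING_POLICY_SKIP else 1.0
            continue
        if parents_missing:
            out[member.member_id] = 1.0
            continue
        if member.affected:
            ok = (all(c == ref_hom for c in unaff_par)
                  and g != ref_hom
                  and all(c == g for c in aff_par))
        else:
            ok = (all(c == ref_hom for c in unaff_par)
                  and g == ref_hom
                  and all(c != ref_hom for c in aff_par))
        out[member.member_id] = 0.0 if ok else 1.0
    return out


def modal_patient_genotype(site: SiteRecord, family: FamilyStructure) -> GenotypeCall:
    """The most common genotype among affected members at a site.

    Missing calls are excluded from the count; ties break by the
    allele-sorted genotype string. If every affected call is missing a
    missing-call sentinel is returned and downstream indicators assign
    I = 1 to affected members at the site.
    """
    counts: dict[GenotypeCall, int] = {}
    for member in family.data_members:
        if not member.affected:
            continue
        call = site.genotypes.get(member.member_id, GenotypeCall.miss())
        if call.missing:
            continue
        counts[call] = counts.get(call, 0) + 1
    if not counts:
        return GenotypeCall.miss()
    return min(counts, key=lambda c: (-counts[c], str(c)))


def indicator_condition2(site: SiteRecord, family: FamilyStructure,
                         msnv: GenotypeCall | None = None,
                         missing_policy: str = MISSING_POLICY_ONE) -> dict[str, float | None]:
    """Indicators for every genotyped member under Condition 2.

    Unaffected: I = 0 iff homozygous reference. Affected, with the modal
    affected genotype ``msnv``: I = 0 iff msnv differs from the reference
    and the member carries msnv; I = 0.5 iff msnv differs from the
    reference and the member carries some other non-reference genotype;
    I = 1 otherwise (including when msnv itself is homozygous reference).
    """
    if msnv is None:
        msnv = modal_patient_genotype(site, family)
    ref_hom = GenotypeCall.hom_ref(site.ref_allele)
    out: dict[str, float | None] = {}
    for member in family.data_members:
        g = site.genotypes.get(member.member_id, GenotypeCall.miss())
        if g.missing:
            out[member.member_id] = None if missing_policy == MISSING_POLICY_SKIP else 1.0
            continue
        if not member.affected:
            out[member.member_id] = 0.0 if g == ref_hom else 1.0
            continue
        if msnv.missing or msnv == ref_hom:
            out[member.member_id] = 1.0
        elif g == msnv:
            out[member.member_id] = 0.0
        elif g != ref_hom:
            out[member.member_id] = 0.5
        else:
            out[member.member_id] = 1.0
    return out


def pattern_frequency(indicators: dict[str, float | None]) -> tuple[float, int]:
    """Sum indicator values into LF_j.

    Returns ``(lf, c_local)`` where ``c_local`` counts the members that
    actually contributed (smaller than C only under the ``skip`` missing
    policy). Raises on values outside {0, 0.5, 1}.
    """
    lf = 0.0
    c_local = 0
    for v in indicators.values():
        if v is None:
            continue
        if v not in (0.0, 0.5, 1.0):
            raise ValueError(f"indicator value outside {{0, 0.5, 1}}: {v}")
        lf += v
        c_local += 1
    return lf, c_local


@dataclass
class IndicatorMatrix:
    """Per-site, per-member indicators with the derived LF_j values.

    ``values[chrom]`` is a list (aligned with the SiteTable's records) of
    per-member indicator dicts; ``lf`` and ``c_local`` are the per-site
    pattern frequency and contributing-member count.
    """

    condition: int
    contributing_count: int
    values: dict[str, list[dict[str, float | None]]] = field(default_factory=dict)
    lf: dict[str, list[float]] = field(default_factory=dict)
    c_local: dict[str, list[int]] = field(default_factory=dict)
    msnv: dict[str, list[GenotypeCall]] = field(default_factory=dict)


def build_indicator_matrix(table: SiteTable, family: FamilyStructure,
                           missing_policy: str = MISSING_POLICY_ONE) -> IndicatorMatrix:
    """Compute indicators and LF_j for every site in the table."""
    condition = family.condition
    matrix = IndicatorMatrix(condition=condition, contributing_count=family.C)
    for chrom in table.chromosomes():
        vals, lfs, cs, modes = [], [], [], []
        for rec in table.sites[chrom]:
            if condition == 1:
                ind = indicator_condition1(rec, family, missing_policy)
                modes.append(GenotypeCall.miss())
            else:
                m = modal_patient_genotype(rec, family)
                ind = indicator_condition2(rec, family, m, missing_policy)
                modes.append(m)
            lf, c_local = pattern_frequency(ind)
            vals.append(ind)
            lfs.append(lf)
            cs.append(c_local)
        matrix.values[chrom] = vals
        matrix.lf[chrom] = lfs
        matrix.c_local[chrom] = cs
        matrix.msnv[chrom] = modes
    return matrix


def dump_indicator_tsv(table: SiteTable, matrix: IndicatorMatrix, path: str) -> None:
    """Audit dump of the full indicator matrix (gzipped when path ends .gz)."""
    opener = gzip.open if path.endswith(".gz") else open
    members = table.member_ids
    with opener(path, "wt") as out:
        out.write("chrom\tpos\tref\t" + "\t".join(f"I_{m}" for m in members) + "\tLF\n")
        for chrom in table.chromosomes():
            for rec, ind, lf in zip(table.sites[chrom], matrix.values[chrom], matrix.lf[chrom]):
                cells = ["NA" if ind.get(m) is None else f"{ind.get(m, 1.0):g}" for m in members]
                out.write(f"{chrom}\t{rec.locus}\t{rec.ref_allele}\t" + "\t".join(cells) + f"\t{lf:g}\n")
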