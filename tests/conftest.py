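import pytest

from gst.pedigree import (
    ROLE_FATHER,
    ROLE_MOTHER,
    ROLE_OFFSPRING,
    FamilyMember,
    FamilyStructure,
)
from gst.variants import GenotypeCall, SiteRecord


def make_member(mid, v, role, affected, has_data=True):
    return FamilyMember(member_id=mid, index_v=v, role=role,
                        disease_state=1 if affected else 0, has_data=has_data)


@pytest.fixture
def quartet():
    """Unaffected father, affected mother, two affected daughters —
    both parents genotyped, so Condition 1 with C = 2."""
    return FamilyStructure([
        make_member("F", 1, ROLE_FATHER, affected=False),
        make_member("M", 2, ROLE_MOTHER, affected=True),
        make_member("D1", 3, ROLE_OFFSPRING, affected=True),
        make_member("D2", 4, ROLE_OFFSPRING, affected=True),
    ])


@pytest.fixture
def siblings7():
    """Seven genotyped members, no genotyped parents — Condition 2, C = 7."""
    members = []
    for k in range(1, 8):
        members.append(make_member(f"M{k}", k, ROLE_OFFSPRING, affected=(k <= 2)))
    return FamilyStructure(members)


def site(ref, calls, chrom="chr1", locus=100):
    """Build a SiteRecord from {member_id: 'A/G' | None} (None = missing)."""
    rec = SiteRecord(chromosome=chrom, locus=locus, ref_allele=ref)
    for mid, gt in calls.items():
        if gt is None:
            rec.genotypes[mid] = GenotypeCall.miss()
        else:
            rec.genotypes[mid] = GenotypeCall(alleles=tuple(gt.split("/")))
    return rec


@pytest.fixture
def write_ped(tmp_path):
    def _write(rows, name="fam.ped", header=True):
        path = tmp_path / name
        lines = []
        if header:
            lines.append("# member_id father_id mother_id sex affection data_flag")
        for r in rows:
            lines.append("\t".join(str(x) for x in r))
        path.write_text("\n".join(lines) + "\n")
        return str(path)
    return _write


def write_simple_vcf(path, samples, records):
    """records: (chrom, pos, ref, alts, [gt strings like '0/1'])."""
    with open(path, "w") as out:
        out.write("##fileformat=VCFv4.2\n")
        out.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = sorted({r[0] for r in records})
        for c in chroms:
            out.write(f"##contig=<ID={c}>\n")
        out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                  + "\t".join(samples) + "\n")
        for chrom, pos, ref, alts, gts in sorted(records):
            out.write(f"{chrom}\t{pos}\t.\t{ref}\t{','.join(alts) or '.'}\t.\tPASS\t.\tGT\t"
                      + "\t".join(gts) + "\n")
    return str(path)
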