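"""Genotype containers and VCF / genotype-table input.

Per-member variant lists are outer-joined on (chromosome, position,
reference allele): a site absent from one member's VCF means no variant
was called there, so that member receives the homozygous-reference call.
Genotypes are compared as unordered allele multisets — phase is ignored
and zygosity matters (A/G differs from G/G).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from cyvcf2 import VCF

log = logging.getLogger(__name__)

MISSING_ALLELE = "."


@dataclass(frozen=True)
class GenotypeCall:
    """A diploid genotype as a sorted allele tuple, or a missing call."""

    alleles: tuple[str, ...] = ()
    missing: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "alleles", tuple(sorted(self.alleles)))
        if not self.missing and len(self.alleles) != 2:
            raise ValueError(f"diploid call needs 2 alleles, got {self.alleles}")

    @classmethod
    def hom_ref(cls, ref: str) -> "GenotypeCall":
        return cls(alleles=(ref, ref))

    @classmethod
    def miss(cls) -> "GenotypeCall":
        return cls(alleles=(), missing=True)

    def is_hom(self, allele: str) -> bool:
        return not self.missing and all(a == allele for a in self.alleles)

    def __str__(self) -> str:
        return "./." if self.missing else "/".join(self.alleles)


@dataclass
class SiteRecord:
    """One genotyped site: chromosome, 1-based locus, reference allele
    and the per-member calls (one entry per data-bearing member)."""

    chromosome: str
    locus: int
    ref_allele: str
    genotypes: dict[str, GenotypeCall] = field(default_factory=dict)
    alt_alleles: tuple[str, ...] = ()
    site_index_j: int = 0


@dataclass
class SiteTable:
    """Ordered site records grouped per chromosome."""

    sites: dict[str, list[SiteRecord]] = field(default_factory=dict)
    member_ids: list[str] = field(default_factory=list)
    dropped: list[tuple[str, int, str]] = field(default_factory=list)

    def chromosomes(self) -> list[str]:
        return sorted(self.sites, key=_chrom_key)

    def all_records(self) -> list[SiteRecord]:
        return [rec for chrom in self.chromosomes() for rec in self.sites[chrom]]

    @property
    def n_sites(self) -> int:
        return sum(len(v) for v in self.sites.values())


def _chrom_key(chrom: str):
    body = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return (0, int(body)) if body.isdigit() else (1, body)


def _normalize_chrom(chrom: str, want_prefix: bool) -> str:
    has = chrom.lower().startswith("chr")
    if want_prefix and not has:
        return "chr" + chrom
    if not want_prefix and has:
        return chrom[3:]
    return chrom


def _call_from_gt(gt_indices, ref: str, alts: list[str]) -> GenotypeCall:
    # cyvcf2 genotype rows are [allele1, allele2, phased]; -1 marks '.'
    idx = [i for i in gt_indices[:-1]]
    if any(i < 0 for i in idx) or len(idx) < 2:
        return GenotypeCall.miss()
    alleles = [ref if i == 0 else alts[i - 1] for i in idx[:2]]
    return GenotypeCall(alleles=tuple(alleles))


def read_family_vcf(paths, family) -> SiteTable:
    """Merge one multi-sample VCF or several per-member VCFs into a
    position-aligned :class:`SiteTable`.

    Sites are joined on (chromosome, locus, reference allele); a member
    with no record at a merged site is assigned the homozygous-reference
    call, and ``./.`` genotypes become missing calls. Records whose REF
    conflicts across files at the same position are dropped and logged.
    Chromosome names are normalized to the dialect (``chr1`` vs ``1``) of
    the first input.
    """
    if isinstance(paths, str):
        paths = [paths]
    data_ids = [m.member_id for m in family.data_members]
    want_prefix: bool | None = None

    # (chrom, pos) -> (ref, alts(set), {member: call})
    merged: dict[tuple[str, int], tuple[str, set, dict]] = {}
    dropped: list[tuple[str, int, str]] = []
    seen_samples: set[str] = set()

    for path in paths:
        vcf = VCF(path)
        samples = list(vcf.samples)
        keep = [s for s in samples if s in data_ids]
        for s in samples:
            if s not in data_ids:
                log.warning("VCF sample %r not a data-bearing pedigree member; ignored", s)
        seen_samples.update(keep)
        sample_pos = {s: samples.index(s) for s in keep}
        for var in vcf:
            chrom = var.CHROM
            if want_prefix is None:
                want_prefix = chrom.lower().startswith("chr")
            chrom = _normalize_chrom(chrom, want_prefix)
            pos = var.POS
            ref = var.REF
            alts = [a for a in (var.ALT or [])]
            key = (chrom, pos)
            if key in merged and merged[key][0] != ref:
                dropped.append((chrom, pos, f"conflicting REF {merged[key][0]} vs {ref}"))
                log.warning("dropping %s:%d: conflicting REF alleles", chrom, pos)
                merged[key] = (merged[key][0], merged[key][1], None)  # poison
                continue
            entry = merged.setdefault(key, (ref, set(), {}))
            if entry[2] is None:
                continue
            entry[1].update(alts)
            gts = var.genotypes
            for s, spos in sample_pos.items():
                call = _call_from_gt(gts[spos], ref, alts)
                prev = entry[2].get(s)
                if prev is not None and prev != call and not call.is_hom(ref):
                    log.warning("duplicate call for %s at %s:%d; keeping first", s, chrom, pos)
                    continue
                if prev is None or prev.is_hom(ref):
                    entry[2][s] = call
        vcf.close()

    missing_members = [m for m in data_ids if m not in seen_samples]
    if missing_members:
        raise ValueError(f"pedigree members without VCF samples: {missing_members}")

    table = SiteTable(member_ids=data_ids)
    for (chrom, pos), (ref, _alts, calls) in merged.items():
        if calls is None:
            continue
        rec = SiteRecord(chromosome=chrom, locus=pos, ref_allele=ref,
                         alt_alleles=tuple(sorted(_alts)))
        for mid in data_ids:
            rec.genotypes[mid] = calls.get(mid, GenotypeCall.hom_ref(ref))
        table.sites.setdefault(chrom, []).append(rec)

    for chrom, recs in table.sites.items():
        recs.sort(key=lambda r: r.locus)
        # deduplicate identical loci (possible only if poisoning missed)
        for j, rec in enumerate(recs, start=1):
            rec.site_index_j = j
    table.dropped = dropped
    return table


def read_genotype_table(path: str, family) -> SiteTable:
    """Read a plain TSV genotype table as an alternate input format.

    Columns: ``chrom  pos  ref  <member1>  <member2> ...`` with genotypes
    written as ``A/G`` (phase separator ``|`` accepted) or ``./.`` for
    missing. Useful for pre-made SNV tables that never passed through a
    VCF.
    """
    data_ids = [m.member_id for m in family.data_members]
    table = SiteTable(member_ids=data_ids)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["chrom", "pos", "ref"]:
            raise ValueError("genotype table must start with columns chrom, pos, ref")
        cols = header[3:]
        missing = [m for m in data_ids if m not in cols]
        if missing:
            raise ValueError(f"genotype table lacks members: {missing}")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ValueError(f"malformed genotype table line {lineno}")
            chrom, pos, ref = parts[0], int(parts[1]), parts[2]
            rec = SiteRecord(chromosome=chrom, locus=pos, ref_allele=ref)
            for mid, tok in zip(cols, parts[3:]):
                if mid not in data_ids:
                    continue
                if tok in (".", "./.", ".|."):
                    rec.genotypes[mid] = GenotypeCall.miss()
                else:
                    alleles = tok.replace("|", "/").split("/")
                    rec.genotypes[mid] = GenotypeCall(alleles=tuple(alleles))
            table.sites.setdefault(chrom, []).append(rec)
    for recs in table.sites.values():
        recs.sort(key=lambda r: r.locus)
        for j, rec in enumerate(recs, start=1):
            rec.site_index_j = j
    return table


def write_vcf(table: SiteTable, path: str, sample_ids: list[str] | None = None,
              contig_lengths: dict[str, int] | None = None) -> None:
    """Write a SiteTable as an uncompressed multi-sample VCF 4.2 file."""
    samples = sample_ids or table.member_ids
    with open(path, "w") as out:
        out.write("##fileformat=VCFv4.2\n")
        out.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in table.chromosomes():
            length = (contig_lengths or {}).get(chrom)
            if length:
                out.write(f"##contig=<ID={chrom},length={length}>\n")
            else:
                out.write(f"##contig=<ID={chrom}>\n")
        out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                  + "\t".join(samples) + "\n")
        for chrom in table.chromosomes():
            for rec in table.sites[chrom]:
                alts = set(rec.alt_alleles)
                for call in rec.genotypes.values():
                    if not call.missing:
                        alts.update(a for a in call.alleles if a != rec.ref_allele)
                alt_list = sorted(alts) or ["."]
                allele_index = {rec.ref_allele: 0}
                for k, a in enumerate(alt_list, start=1):
                    if a != ".":
                        allele_index[a] = k
                gt_strs = []
                for mid in samples:
                    call = rec.genotypes.get(mid, GenotypeCall.hom_ref(rec.ref_allele))
                    if call.missing:
                        gt_strs.append("./.")
                    else:
                        gt_strs.append("/".join(str(allele_index[a]) for a in call.alleles))
                out.write(f"{rec.chromosome}\t{rec.locus}\t.\t{rec.ref_allele}\t"
                          f"{','.join(alt_list)}\t.\tPASS\t.\tGT\t" + "\t".join(gt_strs) + "\n")


def write_audit_tsv(table: SiteTable, path: str) -> None:
    """Write the dropped-site audit log as a TSV."""
    with open(path, "w") as out:
        out.write("chrom\tpos\treason\n")
        for chrom, pos, reason in table.dropped:
            out.write(f"{chrom}\t{pos}\t{reason}\n")
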