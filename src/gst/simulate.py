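"""Synthetic family generator with planted causal clusters.

Emulates the data regime the scan is designed for: a small family whose
members share most of their exome (shared background variants regardless
of affection status), plus a cluster of patient-specific SNVs planted in
the coding sequence of a designated causal gene — affected members carry
an identical non-reference genotype there and unaffected members are
homozygous reference, so each causal site has pattern frequency LF = 0
before noise. Genotyping error and missing-call noise are applied on
top at configurable rates. Output is standard PED/VCF/GFF3 plus a truth
file, so the simulator doubles as a fixture generator.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np

from gst.genemodels import write_gff3
from gst.pedigree import FamilyStructure, read_pedigree
from gst.variants import GenotypeCall, SiteRecord, SiteTable, write_vcf

log = logging.getLogger(__name__)

#: roster entries: (member_id, father_id, mother_id, sex, affected, has_data)
DEFAULT_ROSTER = [
    ("M1", "0", "0", 1, 1, True),
    ("M2", "0", "0", 2, 1, True),
    ("M3", "0", "0", 1, 0, True),
    ("M4", "0", "0", 2, 0, True),
    ("M5", "0", "0", 1, 0, True),
    ("M6", "0", "0", 2, 0, True),
    ("M7", "0", "0", 1, 0, True),
]


@dataclass
class SimulationConfig:
    """Study conditions for one simulated family.

    Defaults emulate a seven-member family with genotype data for all
    seven and no genotyped parents (Condition 2, C = 7, half-width
    n = 19 by the sample-size formula). The causal cluster holds
    2·19 + 1 = 39 patient-specific SNVs in a 50 kb CDS so at least one
    full window fits inside it.
    """

    roster: list[tuple] = field(default_factory=lambda: list(DEFAULT_ROSTER))
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 60_000_000, "chr2": 60_000_000})
    sites_per_chrom: int = 260
    shared_variant_rate: float = 0.35
    private_variant_rate: float = 0.05
    genotyping_error_rate: float = 0.0
    missing_call_rate: float = 0.0
    causal_gene: str = "GENE_CAUSAL"
    causal_chrom: str = "chr1"
    causal_start: int = 30_000_000
    causal_span: int = 50_000
    causal_cluster_size: int = 39
    decoy_genes_per_chrom: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.shared_variant_rate, self.private_variant_rate,
                     self.genotyping_error_rate, self.missing_call_rate):
            if not 0 <= rate < 1:
                raise ValueError("rates must lie in [0, 1)")
        if self.causal_chrom not in self.chrom_lengths:
            raise ValueError(f"causal gene chromosome {self.causal_chrom} not in genome")
        if self.causal_start + self.causal_span > self.chrom_lengths[self.causal_chrom]:
            raise ValueError("causal gene extends past its chromosome")


@dataclass
class TruthSet:
    """What was planted: the causal gene and its site loci."""

    causal_gene: str
    causal_chrom: str
    causal_loci: list[int]
    expected_lf: float = 0.0

    def to_json(self, path: str) -> None:
        with open(path, "w") as out:
            json.dump(self.__dict__, out, indent=1)


_ALT = {"A": "G", "C": "T", "G": "A", "T": "C"}


def _random_genotype(rng, ref: str, alt: str, exclude: GenotypeCall) -> GenotypeCall:
    options = [GenotypeCall((ref, ref)), GenotypeCall((ref, alt)), GenotypeCall((alt, alt))]
    options = [g for g in options if g != exclude]
    return options[rng.integers(len(options))]


def simulate_family(config: SimulationConfig, out_dir: str) -> tuple[str, str, str, TruthSet]:
    """Generate pedigree, multi-sample VCF, GFF3 and truth files.

    Returns ``(ped_path, vcf_path, gff_path, truth)``. Background sites
    are either shared heterozygous in every member (rate
    ``shared_variant_rate``), a private variant in one random member
    (rate ``private_variant_rate``) or homozygous reference everywhere;
    causal sites are identically non-reference in all affected members
    and homozygous reference in the unaffected. Error and missing noise
    are applied afterwards. Deterministic for a fixed seed.
    """
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    members = [r[0] for r in config.roster if r[5]]
    affected = {r[0] for r in config.roster if r[4]}
    if not affected:
        raise ValueError("roster has no affected member")

    table = SiteTable(member_ids=members)
    causal_loci: list[int] = []
    genes: list[dict] = []

    for chrom, length in config.chrom_lengths.items():
        n_bg = config.sites_per_chrom
        loci = set()
        if chrom == config.causal_chrom:
            cluster = np.sort(rng.choice(
                np.arange(config.causal_start, config.causal_start + config.causal_span),
                size=config.causal_cluster_size, replace=False))
            causal_loci = [int(x) for x in cluster]
            loci.update(causal_loci)
            n_bg = max(0, n_bg - config.causal_cluster_size)
        causal_set = set(causal_loci) if chrom == config.causal_chrom else set()
        # background loci stay outside the cluster interval so the planted
        # pattern is contiguous in marker space
        lo = config.causal_start
        hi = config.causal_start + config.causal_span
        while len(loci) < n_bg + len(causal_set):
            pos = int(rng.integers(1, length))
            if causal_set and lo <= pos <= hi:
                continue
            loci.add(pos)

        for pos in sorted(loci):
            ref = "ACGT"[rng.integers(4)]
            alt = _ALT[ref]
            rec = SiteRecord(chromosome=chrom, locus=pos, ref_allele=ref,
                             alt_alleles=(alt,))
            hom_ref = GenotypeCall.hom_ref(ref)
            het = GenotypeCall((ref, alt))
            if pos in causal_set:
                for mid in members:
                    rec.genotypes[mid] = het if mid in affected else hom_ref
            else:
                u = rng.random()
                if u < config.shared_variant_rate:
                    for mid in members:
                        rec.genotypes[mid] = het
                elif u < config.shared_variant_rate + config.private_variant_rate:
                    carrier = members[rng.integers(len(members))]
                    for mid in members:
                        rec.genotypes[mid] = het if mid == carrier else hom_ref
                else:
                    for mid in members:
                        rec.genotypes[mid] = hom_ref
            # noise
            for mid in members:
                if config.genotyping_error_rate and rng.random() < config.genotyping_error_rate:
                    rec.genotypes[mid] = _random_genotype(rng, ref, alt, rec.genotypes[mid])
                if config.missing_call_rate and rng.random() < config.missing_call_rate:
                    rec.genotypes[mid] = GenotypeCall.miss()
            table.sites.setdefault(chrom, []).append(rec)

        # decoy gene models over random site ranges
        chrom_sites = sorted(loci)
        for d in range(config.decoy_genes_per_chrom):
            if len(chrom_sites) < 4:
                break
            a = int(rng.integers(0, len(chrom_sites) - 3))
            b = min(len(chrom_sites) - 1, a + int(rng.integers(2, 10)))
            genes.append({
                "name": f"GENE_{chrom}_{d}", "chrom": chrom, "strand": "+",
                "cds": [(chrom_sites[a] - 10, chrom_sites[b] + 10)],
            })

    genes.append({
        "name": config.causal_gene, "chrom": config.causal_chrom, "strand": "+",
        "cds": [(config.causal_start - 10, config.causal_start + config.causal_span + 10)],
    })

    for recs in table.sites.values():
        for j, rec in enumerate(recs, start=1):
            rec.site_index_j = j

    ped_path = os.path.join(out_dir, "family.ped")
    vcf_path = os.path.join(out_dir, "family.vcf")
    gff_path = os.path.join(out_dir, "genes.gff3")
    with open(ped_path, "w") as out:
        out.write("# member_id father_id mother_id sex affection data_flag\n")
        for mid, fid, moid, sex, aff, has_data in config.roster:
            out.write(f"{mid}\t{fid}\t{moid}\t{sex}\t{2 if aff else 1}\t{1 if has_data else 0}\n")
    write_vcf(table, vcf_path, contig_lengths=config.chrom_lengths)
    write_gff3(genes, gff_path)

    truth = TruthSet(causal_gene=config.causal_gene, causal_chrom=config.causal_chrom,
                     causal_loci=causal_loci)
    truth.to_json(os.path.join(out_dir, "truth.json"))
    return ped_path, vcf_path, gff_path, truth


def recovery_experiment(config: SimulationConfig, out_dir: str,
                        window_n: int | None = None, t: float = 1.0,
                        alpha: float = 0.05):
    """Simulate, run the full pipeline through the file readers, and
    return ``(rank, report)`` where ``rank`` is the causal gene's 1-based
    position in the gene-level report (None when absent)."""
    from gst.pipeline import run_pipeline

    ped, vcf, gff, truth = simulate_family(config, out_dir)
    result_dir = os.path.join(out_dir, "gst_out")
    outputs = run_pipeline(vcf_paths=[vcf], ped_path=ped, gff_path=gff,
                           out_dir=result_dir, window_n=window_n, t=t,
                           alpha=alpha, make_plot=False)
    report = outputs["report"]
    hit = report.index[report["gene"] == truth.causal_gene]
    rank = int(report.loc[hit[0], "rank"]) if len(hit) else None
    return rank, report
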