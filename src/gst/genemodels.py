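"""Gene-model loading and CDS / splice-site classification.

Candidate sites must fall in coding sequence or a splice site. Splice
sites are taken as the two intronic bases flanking each internal CDS
boundary (the canonical donor/acceptor dinucleotides); the extent is
configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gffutils
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

REGION_CDS = "CDS"
REGION_SPLICE = "splice_site"
REGION_OTHER = "other"


@dataclass
class GeneModelIndex:
    """Interval index over CDS regions and splice-site positions.

    ``cds`` maps chromosome -> IntervalTree of [start, end+1) intervals
    tagged with gene names; ``splice`` maps chromosome -> {position:
    set(gene names)}. Coordinates are 1-based inclusive throughout.
    """

    cds: dict[str, IntervalTree] = field(default_factory=dict)
    splice: dict[str, dict[int, set]] = field(default_factory=dict)
    genes: set = field(default_factory=set)


def _gene_name(db, feature) -> str | None:
    for key in ("gene_name", "gene_id", "gene", "Name"):
        if key in feature.attributes:
            return feature.attributes[key][0]
    try:
        for parent in db.parents(feature, featuretype="gene"):
            for key in ("Name", "gene_name", "gene_id", "ID"):
                if key in parent.attributes:
                    return parent.attributes[key][0]
    except Exception:
        pass
    return None


def _transcript_id(feature) -> str | None:
    for key in ("transcript_id", "Parent"):
        if key in feature.attributes:
            return feature.attributes[key][0]
    return None


def load_gene_models(path: str, splice_bp: int = 2) -> GeneModelIndex:
    """Build a :class:`GeneModelIndex` from a GFF3 or GTF file.

    CDS intervals are indexed per chromosome; splice sites are derived
    as the ``splice_bp`` intronic bases on each side of every internal
    CDS boundary within a transcript. CDS features lacking a gene
    identifier are grouped under their transcript id with a warning.
    """
    db = gffutils.create_db(
        path, ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    index = GeneModelIndex()
    # transcript id -> (chrom, gene, [(start, end)])
    transcripts: dict[str, tuple[str, str, list[tuple[int, int]]]] = {}
    n_cds = 0
    for feat in db.features_of_type("CDS"):
        n_cds += 1
        gene = _gene_name(db, feat)
        tid = _transcript_id(feat) or f"tx_{feat.seqid}_{feat.start}"
        if gene is None:
            log.warning("CDS without gene id at %s:%d; grouped under %s", feat.seqid, feat.start, tid)
            gene = tid
        index.genes.add(gene)
        tree = index.cds.setdefault(feat.seqid, IntervalTree())
        tree.addi(feat.start, feat.end + 1, gene)
        key = f"{tid}|{gene}"
        entry = transcripts.setdefault(key, (feat.seqid, gene, []))
        entry[2].append((feat.start, feat.end))
    if n_cds == 0:
        raise ValueError(f"gene-model file {path} contains no CDS features")

    for chrom, gene, exons in transcripts.values():
        exons.sort()
        sites = index.splice.setdefault(chrom, {})
        for (s1, e1), (s2, _e2) in zip(exons, exons[1:]):
            if s2 <= e1 + 1:
                continue  # abutting or overlapping segments: no intron
            for pos in range(e1 + 1, min(e1 + splice_bp, s2 - 1) + 1):
                sites.setdefault(pos, set()).add(gene)
            for pos in range(max(s2 - splice_bp, e1 + 1), s2):
                sites.setdefault(pos, set()).add(gene)
    return index


def classify_site(chromosome: str, locus: int, index: GeneModelIndex) -> tuple[str, str | None]:
    """Classify a position as CDS, splice_site or other.

    CDS takes precedence over splice_site when overlapping transcripts
    disagree; among multiple hits the lexicographically first gene name
    is returned for determinism.
    """
    tree = index.cds.get(chromosome)
    if tree is not None:
        hits = tree[locus]
        if hits:
            return REGION_CDS, min(iv.data for iv in hits)
    genes = index.splice.get(chromosome, {}).get(locus)
    if genes:
        return REGION_SPLICE, min(genes)
    return REGION_OTHER, None


def write_gff3(genes: list[dict], path: str) -> None:
    """Write a minimal GFF3 gene model file.

    Each entry: ``{"name", "chrom", "strand", "cds": [(start, end), ...]}``
    with 1-based inclusive CDS coordinates.
    """
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for g in genes:
            cds = sorted(g["cds"])
            gstart, gend = cds[0][0], cds[-1][1]
            strand = g.get("strand", "+")
            gid = g["name"]
            out.write(f"{g['chrom']}\tgst\tgene\t{gstart}\t{gend}\t.\t{strand}\t.\t"
                      f"ID=gene:{gid};Name={gid}\n")
            out.write(f"{g['chrom']}\tgst\tmRNA\t{gstart}\t{gend}\t.\t{strand}\t.\t"
                      f"ID=tx:{gid};Parent=gene:{gid}\n")
            for s, e in cds:
                out.write(f"{g['chrom']}\tgst\tCDS\t{s}\t{e}\t.\t{strand}\t0\t"
                          f"Parent=tx:{gid};gene_name={gid}\n")
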