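"""End-to-end orchestration: read → indicators → scan → select → report."""

from __future__ import annotations

import hashlib
import json
import logging
import os

from gst._version import __version__
from gst.genemodels import classify_site, load_gene_models
from gst.indicators import MISSING_POLICY_ONE, build_indicator_matrix, dump_indicator_tsv
from gst.pedigree import read_pedigree
from gst.report import build_report, grouped_phenotype_view, manhattan_plot, plot_table
from gst.variants import read_family_vcf, read_genotype_table, write_audit_tsv
from gst.windows import WindowConfig, scan_chromosome, select_candidates, window_size

log = logging.getLogger(__name__)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _fmt(df, float_cols):
    out = df.copy()
    for col in float_cols:
        if col in out.columns:
            out[col] = out[col].map(lambda x: f"{x:.6f}")
    return out


def run_pipeline(vcf_paths=None, ped_path=None, gff_path=None, out_dir="gst_out",
                 genotype_table=None, window_n=None, t: float = 1.0,
                 alpha: float = 0.05, E: float = 0.05, z: float = 1.645,
                 test: str = "z", splice_bp: int = 2,
                 missing_policy: str = MISSING_POLICY_ONE,
                 gene_annotation=None, variant_annotation=None,
                 fdr: bool = False, make_plot: bool = True, seed: int | None = None):
    """Run the full scan and write the report files.

    Returns a dict with the in-memory ``report``, ``detail``, ``windows``
    (list of WindowResult) and the resolved ``manifest``. The half-width
    defaults to the sample-size formula applied to the family's
    contributing-member count C; pass ``window_n`` to override.
    """
    if ped_path is None:
        raise ValueError("pedigree file is required")
    family = read_pedigree(ped_path)
    if genotype_table is not None:
        table = read_genotype_table(genotype_table, family)
    elif vcf_paths:
        table = read_family_vcf(vcf_paths, family)
    else:
        raise ValueError("provide VCF input or a genotype table")
    index = load_gene_models(gff_path, splice_bp=splice_bp)

    n = window_n if window_n is not None else window_size(family.C, z=z, E=E)
    config = WindowConfig(n=n, t=t, alpha=alpha, E=E, z=z, test=test)

    os.makedirs(out_dir, exist_ok=True)
    manifest = {
        "tool_version": __version__,
        "n": n, "t": t, "alpha": alpha, "E": E, "z": z, "test": test,
        "condition": family.condition, "C": family.C, "V": family.V,
        "missing_policy": missing_policy, "splice_bp": splice_bp,
        "seed": seed,
        "inputs": {os.path.basename(p): _sha256(p)
                   for p in ([*(vcf_paths or [])] +
                             [x for x in (ped_path, gff_path, genotype_table) if x])},
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)

    matrix = build_indicator_matrix(table, family, missing_policy)
    results = []
    for chrom in table.chromosomes():
        loci = [r.locus for r in table.sites[chrom]]
        c_local = matrix.c_local[chrom] if missing_policy == "skip" else None
        results.extend(scan_chromosome(
            chrom, loci, matrix.lf[chrom], config,
            c_local=c_local, C=family.C, indicators=matrix.values[chrom]))

    if fdr and results:
        from statsmodels.stats.multitest import multipletests
        import math
        rej, qvals, _, _ = multipletests([r.pvalue for r in results], alpha=alpha,
                                         method="fdr_bh")
        for r, q in zip(results, qvals):
            r.pvalue = float(q)
            r.score = -(math.log(r.weight) + math.log(max(q, 1e-300)))

    candidates = select_candidates(results, lambda c, l: classify_site(c, l, index),
                                   alpha=alpha)
    report, detail = build_report(candidates, index, gene_annotation, variant_annotation)

    float_cols = ["score", "pr", "pvalue"]
    _fmt(report, float_cols).to_csv(os.path.join(out_dir, "report.tsv"), sep="\t", index=False)
    _fmt(detail, float_cols).to_csv(os.path.join(out_dir, "report_detail.tsv"), sep="\t", index=False)
    _fmt(grouped_phenotype_view(report), float_cols).to_csv(
        os.path.join(out_dir, "report_by_phenotype.tsv"), sep="\t", index=False)

    windows_path = os.path.join(out_dir, "windows.tsv")
    with open(windows_path, "w") as out:
        out.write("chrom\tcenter_pos\tPR\tpvalue\tspan_bp\tweight\tscore\tcenter_LF\n")
        for r in results:
            out.write(f"{r.chromosome}\t{r.center_locus}\t{r.pr:.6f}\t{r.pvalue:.6g}\t"
                      f"{r.span_bp}\t{r.weight:.6f}\t{r.score:.6f}\t{r.center_lf:g}\n")

    write_audit_tsv(table, os.path.join(out_dir, "audit_dropped_sites.tsv"))
    dump_indicator_tsv(table, matrix, os.path.join(out_dir, "indicators.tsv.gz"))

    ptable = plot_table(results, candidates)
    ptable.to_csv(os.path.join(out_dir, "plot.tsv"), sep="\t", index=False)
    if make_plot and not ptable.empty:
        manhattan_plot(ptable, candidates, index, os.path.join(out_dir, "plot.png"),
                       threshold=config.score_threshold)

    return {"report": report, "detail": detail, "windows": results,
            "candidates": candidates, "manifest": manifest, "table": table,
            "matrix": matrix, "index": index}
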