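"""Candidate report assembly and genome-wide plot.

Candidate windows are joined to gene models and optional annotation
tables (gene description, phenotype, SIFT and PolyPhen-2 scores supplied
as TSVs) and emitted as a ranked report: one row per gene carrying its
best-scoring SNV, with every supporting SNV in a detail table. A
Manhattan-style plot of the trimmed score (negative scores clipped to
zero) over the autosomes accompanies the report.
"""

from __future__ import annotations

import logging

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from gst.genemodels import GeneModelIndex, classify_site
from gst.variants import _chrom_key
from gst.windows import WindowResult

log = logging.getLogger(__name__)

_SEX_CHROMS = {"x", "y", "chrx", "chry"}


def _load_annotation(path: str | None, value_cols: list[str]) -> pd.DataFrame | None:
    if path is None:
        return None
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in value_cols if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table {path} lacks columns {missing}")
    return df


def build_report(candidates: list[WindowResult], index: GeneModelIndex,
                 gene_annotation: str | None = None,
                 variant_annotation: str | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the ranked candidate-gene report.

    ``gene_annotation`` is an optional TSV with columns
    ``gene, description, phenotype``; ``variant_annotation`` an optional
    TSV with ``chrom, pos, sift, polyphen2``. Returns
    ``(report, detail)``: the report holds one row per gene (its
    best-scoring SNV), the detail table every supporting candidate SNV.
    Rows sort by descending score with phenotype-annotated genes first
    among ties; ranks are assigned after sorting.
    """
    rows = []
    for r in candidates:
        region, gene = classify_site(r.chromosome, r.center_locus, index)
        rows.append({
            "chromosome": r.chromosome, "locus": r.center_locus,
            "gene": gene if gene is not None else "",
            "score": r.score, "region": region,
            "pr": r.pr, "pvalue": r.pvalue, "span_bp": r.span_bp,
        })
    detail = pd.DataFrame(rows, columns=["chromosome", "locus", "gene", "score",
                                         "region", "pr", "pvalue", "span_bp"])

    gene_df = _load_annotation(gene_annotation, ["gene"])
    var_df = _load_annotation(variant_annotation, ["chrom", "pos"])

    if not detail.empty:
        detail = detail.sort_values(
            ["score", "chromosome", "locus"], ascending=[False, True, True],
        ).reset_index(drop=True)
        report = (detail.sort_values("score", ascending=False)
                  .groupby("gene", as_index=False, sort=False).first())
    else:
        report = detail.copy()

    for df in (report, detail):
        df["description"] = ""
        df["phenotype"] = ""
        df["sift"] = ""
        df["polyphen2"] = ""

    if gene_df is not None and not report.empty:
        ann = gene_df.set_index("gene")
        for df in (report, detail):
            for col in ("description", "phenotype"):
                if col in ann.columns:
                    mapped = df["gene"].map(ann[col])
                    unmatched = df.loc[mapped.isna() & (df["gene"] != ""), "gene"]
                    for g in unmatched.unique():
                        log.warning("no annotation row for gene %s; left empty", g)
                    df[col] = mapped.fillna("")
    if var_df is not None and not detail.empty:
        var_df = var_df.copy()
        var_df["pos"] = var_df["pos"].astype(int)
        key = var_df.set_index(["chrom", "pos"])
        for df in (report, detail):
            idx = pd.MultiIndex.from_frame(df[["chromosome", "locus"]])
            for col in ("sift", "polyphen2"):
                if col in key.columns:
                    df[col] = key[col].reindex(idx).fillna("").to_numpy()

    if not report.empty:
        # primary order by score; phenotype presence breaks exact ties
        report = report.sort_values(
            by=["score", "phenotype", "chromosome", "locus"],
            ascending=[False, False, True, True],
            key=lambda s: s.ne("") if s.name == "phenotype" else s,
        ).reset_index(drop=True)
        report.insert(0, "rank", range(1, len(report) + 1))
    else:
        report.insert(0, "rank", pd.Series(dtype=int))
    cols = ["rank", "chromosome", "locus", "gene", "score", "region",
            "description", "phenotype", "sift", "polyphen2"]
    return report[cols], detail


def grouped_phenotype_view(report: pd.DataFrame) -> pd.DataFrame:
    """Secondary view: phenotype-annotated genes first, then the rest,
    score-sorted inside each block."""
    if report.empty:
        return report.copy()
    has_pheno = report["phenotype"].ne("")
    top = report[has_pheno]
    bottom = report[~has_pheno]
    return pd.concat([top, bottom]).reset_index(drop=True)


def plot_table(results: list[WindowResult], candidates: list[WindowResult],
               index: GeneModelIndex | None = None,
               include_sex_chromosomes: bool = False) -> pd.DataFrame:
    """Per-site table for the genome-wide plot.

    Columns: chromosome, position, score, trimmed_score (= max(score, 0)).
    X and Y chromosomes are excluded by default.
    """
    rows = [
        {"chromosome": r.chromosome, "position": r.center_locus,
         "score": r.score, "trimmed_score": max(r.score, 0.0)}
        for r in results
        if include_sex_chromosomes or r.chromosome.lower() not in _SEX_CHROMS
    ]
    return pd.DataFrame(rows, columns=["chromosome", "position", "score", "trimmed_score"])


def manhattan_plot(table: pd.DataFrame, candidates: list[WindowResult],
                   index: GeneModelIndex | None, out_path: str,
                   threshold: float | None = None) -> None:
    """Manhattan-style plot of trimmed scores, chromosomes alternating
    red and blue, candidate genes labeled at their peaks."""
    fig, ax = plt.subplots(figsize=(12, 4))
    offset = 0
    ticks, labels = [], []
    chroms = sorted(table["chromosome"].unique(), key=_chrom_key)
    for k, chrom in enumerate(chroms):
        sub = table[table["chromosome"] == chrom]
        color = "red" if k % 2 == 0 else "blue"
        ax.scatter(sub["position"] + offset, sub["trimmed_score"], s=3, color=color)
        ticks.append(offset + (sub["position"].min() + sub["position"].max()) / 2)
        labels.append(chrom.replace("chr", ""))
        span = int(sub["position"].max())
        for c in candidates:
            if c.chromosome != chrom:
                continue
            gene = None
            if index is not None:
                _, gene = classify_site(c.chromosome, c.center_locus, index)
            ax.annotate(gene or f"{chrom}:{c.center_locus}",
                        (c.center_locus + offset, max(c.score, 0.0)),
                        fontsize=7, rotation=45)
        offset += span + 1
    if threshold is not None:
        ax.axhline(threshold, color="grey", linestyle="--", linewidth=0.8)
    ax.set_xticks(ticks)
    ax.set_xticklabels(labels, fontsize=7)
    ax.set_xlabel("chromosome")
    ax.set_ylabel("trimmed score")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
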