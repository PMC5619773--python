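"""Sliding-window proportion test and scoring.

A window of 2n+1 consecutive markers is centered on each eligible site
of a chromosome. The window proportion PR = Σ LF_j / (C·(2n+1)) is tested
one-tailed against the null PR ≥ 0.5 with a normal approximation; the
p-value is multiplied by a weight proportional to the window's physical
span (tight clusters of consistent sites score higher) and the score is
the negative natural log of that product:

    Score = −ln( w · p ),   w = span_bp / (t · 10⁶)

Sites are selected as candidates when Score exceeds −ln(α) (2.996 at
α = 0.05), the center site segregates perfectly (LF = 0), and the site
falls in coding sequence or a splice site.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom, norm

log = logging.getLogger(__name__)

TEST_Z = "z"          # plain normal approximation (default)
TEST_Z_CC = "z-cc"    # normal approximation with continuity correction
TEST_EXACT = "exact"  # exact binomial (integer success counts only)


@dataclass
class WindowConfig:
    """Scan parameters.

    n       markers on each side of the window center (half-width)
    t       span tuning parameter, in Mb (weight = span / (t·10⁶))
    alpha   selection significance level
    E       margin of error in the window-size formula
    z       one-sided normal critical value matching alpha = 0.05
    test    proportion-test flavor: z, z-cc or exact
    """

    n: int = 19
    t: float = 1.0
    alpha: float = 0.05
    E: float = 0.05
    z: float = 1.645
    test: str = TEST_Z
    per_member: bool = False

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("window half-width n must be >= 1")
        if self.t <= 0:
            raise ValueError("tuning parameter t must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.E < 0.5:
            raise ValueError("margin of error E must lie in (0, 0.5)")

    @property
    def score_threshold(self) -> float:
        return -math.log(self.alpha)


@dataclass
class WindowResult:
    """Statistics for one window center."""

    chromosome: str
    center_site_index: int      # 1-based index within the chromosome
    center_locus: int
    pr: float
    pvalue: float
    span_bp: int
    weight: float
    score: float
    center_lf: float
    per_member_pr: dict[str, float] | None = None


def window_size(C: int, z: float = 1.645, E: float = 0.05) -> int:
    """Half-width n from the proportion-test sample-size formula.

    n = round( (((z·0.5)² / (C·E²)) − 1) / 2 ), half-up, floored at 1,
    so that the 2n+1 markers in a window provide the sample size a
    proportion test with margin of error E needs once each of the C
    contributing members adds one trial per marker.
    """
    if C <= 0:
        raise ValueError("contributing-member count C must be positive")
    raw = (((z * 0.5) ** 2 / (C * E * E)) - 1.0) / 2.0
    return max(1, int(math.floor(raw + 0.5)))


def window_proportion(lf, i: int, n: int, C: float) -> float:
    """PR for the window centered at 1-based site index ``i``.

    PR = Σ_{j=i−n..i+n} LF_j / (C·(2n+1)); the window must fit inside
    the chromosome. The scan itself restricts centers further, to
    i = n+1 .. U−n−1.
    """
    U = len(lf)
    if i - n < 1 or i + n > U:
        raise ValueError(f"window at center {i} exceeds chromosome bounds (U={U}, n={n})")
    total = float(sum(lf[i - n - 1:i + n]))
    return total / (C * (2 * n + 1))


def proportion_pvalue(pr: float, m: float, test: str = TEST_Z) -> float:
    """One-tailed p-value for H0: PR ≥ 0.5 against PR < 0.5.

    ``m`` is the effective number of trials, C·(2n+1). The default is the
    lower-tail normal approximation without continuity correction; z-cc
    adds the correction and exact uses the binomial CDF (requires an
    integer success count, i.e. Condition 1 data).
    """
    if m <= 0:
        raise ValueError("effective trial count must be positive")
    se = math.sqrt(0.25 / m)
    if test == TEST_Z:
        return float(norm.cdf((pr - 0.5) / se))
    if test == TEST_Z_CC:
        return float(norm.cdf((pr - 0.5 + 0.5 / m) / se))
    if test == TEST_EXACT:
        successes = pr * m
        k = round(successes)
        if abs(successes - k) > 1e-9:
            raise ValueError("exact test needs an integer success count")
        return float(binom.cdf(k, int(round(m)), 0.5))
    raise ValueError(f"unknown test {test!r}")


def window_weight(span_bp: int, t: float = 1.0) -> float:
    """Span weight w = span_bp / (t·10⁶); tighter windows weigh less."""
    if span_bp <= 0:
        raise ValueError("window span must be positive")
    if t <= 0:
        raise ValueError("tuning parameter t must be positive")
    return span_bp / (t * 1e6)


def score(pvalue: float, weight: float) -> float:
    """Score = −ln(weight · pvalue); may be negative when w·p > 1."""
    if pvalue <= 0 or pvalue >= 1 or weight <= 0:
        raise ValueError("score requires p in (0,1) and weight > 0")
    return -(math.log(weight) + math.log(pvalue))


def scan_chromosome(chrom: str, loci, lf, config: WindowConfig,
                    c_local=None, C: float | None = None,
                    indicators=None) -> list[WindowResult]:
    """Slide the window along one chromosome.

    ``loci`` and ``lf`` are position-aligned arrays for the chromosome's
    sites; centers run over 1-based indices n+1 .. U−n−1 (the first and
    last n sites are unscored and a chromosome needs at least 2n+2 sites
    to produce any window). ``c_local`` gives per-site contributing
    counts when the skip missing policy reduced them; otherwise the
    denominator is C·(2n+1).
    """
    n = config.n
    loci = np.asarray(loci, dtype=np.int64)
    lf = np.asarray(lf, dtype=np.float64)
    U = len(lf)
    if U < 2 * n + 2:
        log.warning("chromosome %s has %d sites < 2n+2 = %d; skipped", chrom, U, 2 * n + 2)
        return []
    if C is None:
        raise ValueError("C (contributing-member count) is required")
    if c_local is None:
        c_arr = np.full(U, float(C))
    else:
        c_arr = np.asarray(c_local, dtype=np.float64)

    width = 2 * n + 1
    csum_lf = np.concatenate(([0.0], np.cumsum(lf)))
    csum_c = np.concatenate(([0.0], np.cumsum(c_arr)))
    # 0-based centers n .. U-n-2  <=>  1-based n+1 .. U-n-1
    centers = np.arange(n, U - n - 1)
    lo, hi = centers - n, centers + n
    win_lf = csum_lf[hi + 1] - csum_lf[lo]
    denom = csum_c[hi + 1] - csum_c[lo]
    denom = np.where(denom > 0, denom, np.nan)
    pr = win_lf / denom
    z = (pr - 0.5) / np.sqrt(0.25 / denom)
    if config.test == TEST_Z_CC:
        z = (pr - 0.5 + 0.5 / denom) / np.sqrt(0.25 / denom)
    if config.test in (TEST_Z, TEST_Z_CC):
        pvals = norm.cdf(z)
    else:
        pvals = np.array([proportion_pvalue(p, m, config.test) for p, m in zip(pr, denom)])
    pvals = np.clip(pvals, 1e-300, 1.0)  # keep the log finite at extreme z
    spans = loci[hi] - loci[lo]
    weights = spans / (config.t * 1e6)
    scores = -(np.log(weights) + np.log(pvals))

    member_ids = None
    if config.per_member and indicators is not None:
        member_ids = sorted({mid for ind in indicators for mid in ind})
        imat = np.array([[1.0 if ind.get(mid) is None else ind.get(mid, 1.0)
                          for mid in member_ids] for ind in indicators])
        csum_i = np.vstack([np.zeros(len(member_ids)), np.cumsum(imat, axis=0)])

    results = []
    for k, c0 in enumerate(centers):
        per_member = None
        if member_ids is not None:
            sums = csum_i[hi[k] + 1] - csum_i[lo[k]]
            per_member = {mid: float(s / width) for mid, s in zip(member_ids, sums)}
        results.append(WindowResult(
            chromosome=chrom,
            center_site_index=int(c0) + 1,
            center_locus=int(loci[c0]),
            pr=float(pr[k]),
            pvalue=float(pvals[k]),
            span_bp=int(spans[k]),
            weight=float(weights[k]),
            score=float(scores[k]),
            center_lf=float(lf[c0]),
            per_member_pr=per_member,
        ))
    return results


def select_candidates(results: list[WindowResult], regions, alpha: float = 0.05) -> list[WindowResult]:
    """Filter windows to candidate sites.

    Keeps windows whose score exceeds −ln(alpha), whose center site has
    LF = 0, and whose center locus classifies as CDS or splice_site in
    ``regions`` (a callable (chrom, locus) -> (region_class, gene)).
    Sorted by descending score.
    """
    threshold = -math.log(alpha)
    kept = []
    for r in results:
        if r.score <= threshold or r.center_lf != 0.0:
            continue
        region, _gene = regions(r.chromosome, r.center_locus)
        if region in ("CDS", "splice_site"):
            kept.append(r)
    kept.sort(key=lambda r: (-r.score, r.chromosome, r.center_locus))
    return kept
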