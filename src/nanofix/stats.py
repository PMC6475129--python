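"""Enrichment/depletion statistics and sampling-effort correlation.

Taxonomic composition of each filtered dataset is compared against the PU
baseline with pairwise two-sided Fisher exact tests (one 2x2 table per
taxonomic group x dataset: group vs rest, dataset vs PU), Bonferroni
corrected for the full grid of comparisons (9 groups x 6 datasets = 54 by
default) at a 5% family-wise type-I error.

The two-sided p-value follows the conventional point-probability rule: the
sum, over all tables sharing the observed margins, of hypergeometric
probabilities no larger than the observed table's (ties admitted within
1e-7 relative tolerance).  Small tables (total n <= ``exact_limit``) are
evaluated by exact integer enumeration; larger tables go through
``scipy.stats.fisher_exact``, which implements the same rule in floating
point.

Spearman rank correlation (mid-ranks for ties) quantifies how pathway
completeness tracks sequencing effort; only the coefficient is part of the
core contract, the t-approximation p-value is available behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

ALPHA = 0.05
TIE_REL_TOL = 1e-7
EXACT_LIMIT = 1000  # largest table total evaluated by integer enumeration


def _validate_table(table) -> tuple[int, int, int, int]:
    flat = [table[0][0], table[0][1], table[1][0], table[1][1]]
    out = []
    for v in flat:
        iv = int(v)
        if iv != v or iv < 0:
            raise ValueError(f"table entries must be non-negative integers, got {v}")
        out.append(iv)
    if sum(out) == 0:
        raise ValueError("table has no positive margin")
    return tuple(out)  # type: ignore[return-value]


def odds_ratio(table) -> float:
    """Sample odds ratio (a*d)/(b*c); division by zero yields +infinity."""
    a, b, c, d = _validate_table(table)
    if b * c == 0:
        return math.inf
    return (a * d) / (b * c)


def fisher_exact_2x2(table, exact_limit: int = EXACT_LIMIT) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 table.

    Returns ``(odds_ratio, p)``.  The p-value is the conditional
    hypergeometric two-sided probability under fixed margins (see module
    docstring for the tie rule and the exact/float split).
    """
    a, b, c, d = _validate_table(table)
    n = a + b + c + d
    if n > exact_limit:
        _, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        return odds_ratio(table), min(1.0, float(p))
    r1, r2, c1 = a + b, c + d, a + c
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return odds_ratio(table), 1.0  # degenerate margin: only one table
    amin, amax = max(0, c1 - r2), min(r1, c1)
    # Integer hypergeometric numerators over the common denominator C(n, c1):
    # exact comparisons, no floating-point ties possible.
    numerators = [math.comb(r1, x) * math.comb(r2, c1 - x) for x in range(amin, amax + 1)]
    observed = numerators[a - amin]
    p = sum(v for v in numerators if v <= observed) / math.comb(n, c1)
    return odds_ratio(table), min(1.0, p)


@dataclass(frozen=True, slots=True)
class EnrichmentResult:
    dataset: str
    group: str
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_raw: float
    p_adj: float
    verdict: str  # enriched | depleted | ns

    def __post_init__(self) -> None:
        if self.verdict not in ("enriched", "depleted", "ns"):
            raise ValueError(f"unknown verdict {self.verdict!r}")
        if self.verdict != "ns" and not self.p_adj < ALPHA:
            raise ValueError("significant verdict with p_adj >= alpha")


def run_enrichment(
    counts: Mapping[tuple[str, str], int],
    pu_counts: Mapping[str, int],
    groups: Sequence[str] | None = None,
    datasets: Sequence[str] | None = None,
    alpha: float = ALPHA,
) -> list[EnrichmentResult]:
    """Fisher enrichment/depletion of each group in each dataset vs PU.

    ``counts`` maps (group, dataset) to sequence counts; ``pu_counts`` maps
    group to its PU count.  The Bonferroni factor is the number of tests,
    ``len(groups) * len(datasets)`` (54 under the default 9x6 design).
    """
    if groups is None:
        groups = sorted(pu_counts)
    if datasets is None:
        datasets = sorted({ds for _, ds in counts})
    missing = [g for g in groups if g not in pu_counts]
    if missing:
        raise ValueError(f"group(s) missing from PU counts: {', '.join(missing)}")
    n_tests = len(groups) * len(datasets)
    pu_total = sum(pu_counts[g] for g in groups)
    totals = {ds: sum(counts.get((g, ds), 0) for g in groups) for ds in datasets}
    results = []
    for ds in datasets:
        for g in groups:
            a = counts.get((g, ds), 0)
            b = totals[ds] - a
            c = pu_counts[g]
            d = pu_total - c
            table = ((a, b), (c, d))
            oratio, p = fisher_exact_2x2(table)
            p_adj = min(1.0, p * n_tests)
            if p_adj < alpha:
                verdict = "enriched" if oratio > 1 else "depleted"
            else:
                verdict = "ns"
            results.append(EnrichmentResult(ds, g, table, oratio, p, p_adj, verdict))
    return results


def write_enrichment(results: Sequence[EnrichmentResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("dataset\tgroup\tcount\ttotal\tpu_count\tpu_total"
                 "\todds_ratio\tp_raw\tp_adj\tverdict\n")
        for r in results:
            (a, b), (c, d) = r.table
            orstr = "inf" if math.isinf(r.odds_ratio) else f"{r.odds_ratio:.4g}"
            fh.write(f"{r.dataset}\t{r.group}\t{a}\t{a + b}\t{c}\t{c + d}"
                     f"\t{orstr}\t{r.p_raw:.6g}\t{r.p_adj:.6g}\t{r.verdict}\n")


def spearman(x: Sequence[float], y: Sequence[float], return_p: bool = False):
    """Spearman rank correlation (mid-ranks for ties).

    Returns rho, or ``(rho, p)`` with the t-approximation p-value when
    ``return_p`` is set.  Constant input has no defined rank correlation and
    yields NaN rather than raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("spearman requires two equal-length vectors, n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return (math.nan, math.nan) if return_p else math.nan
    rho, p = sps.spearmanr(x, y)
    return (float(rho), float(p)) if return_p else float(rho)


@dataclass(frozen=True, slots=True)
class EffortMetrics:
    """Sequencing-effort covariates for one (site, depth) key, with each
    covariate normalised to the maximum across sites (so the best-sampled
    site scores 1.0 on each axis)."""

    key: tuple[str, str]
    n_reads: int
    n_hq_reads: int
    n_predicted_genes: int
    avg_read_cov_per_protein: float
    normalized_effort: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.normalized_effort <= 1.0 + 1e-12):
            raise ValueError("normalized_effort outside [0, 1]")


def normalize_effort(
    raw: Mapping[tuple[str, str], tuple[int, int, int, float]]
) -> dict[tuple[str, str], EffortMetrics]:
    """Build :class:`EffortMetrics` from raw per-site covariates.

    ``raw`` maps (site, depth) to (n_reads, n_hq_reads, n_predicted_genes,
    avg_read_cov_per_protein).  The scalar ``normalized_effort`` is the mean
    of n_predicted_genes and avg coverage, each divided by its cross-site
    maximum (the two indicators reported alongside the completeness matrix).
    """
    if not raw:
        return {}
    max_genes = max(v[2] for v in raw.values()) or 1
    max_cov = max(v[3] for v in raw.values()) or 1.0
    out = {}
    for key, (reads, hq, genes, cov) in raw.items():
        eff = 0.5 * (genes / max_genes + cov / max_cov)
        out[key] = EffortMetrics(key, reads, hq, genes, cov, eff)
    return out


def write_effort(metrics: Mapping[tuple[str, str], EffortMetrics], path) -> None:
    with open(path, "w") as fh:
        fh.write("site_id\tdepth\tn_reads\tn_hq_reads\tn_predicted_genes"
                 "\tavg_read_cov_per_protein\tnormalized_effort\n")
        for key in sorted(metrics):
            m = metrics[key]
            fh.write(f"{key[0]}\t{key[1]}\t{m.n_reads}\t{m.n_hq_reads}"
                     f"\t{m.n_predicted_genes}\t{m.avg_read_cov_per_protein:.4f}"
                     f"\t{m.normalized_effort:.4f}\n")
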