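"""Enrichment statistics: Fisher's exact 2x2 tests, genomic region filters
and hypergeometric gene-set over-representation.

The 2x2 layout throughout is

    a = in category & flagged        b = in category & not flagged
    c = not in category & flagged    d = not in category & not flagged

with the universe equal to all analyzed genes.  The reported odds ratio is
the sample (cross-product) odds ratio a*d / (b*c); the conditional maximum
likelihood odds ratio and an exact conditional CI are also computed for
transparency, alongside the asymptotic Woolf (log-OR) interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _cmle_odds_ratio

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable",
    "EnrichmentResult",
    "build_contingency",
    "fisher_exact_2x2",
    "region_filter",
    "read_gmt",
    "ora_gene_sets",
    "gene_importance_counts",
]


@dataclass(frozen=True)
class ContingencyTable:
    a: int  # in category & flagged
    b: int  # in category & not flagged
    c: int  # out of category & flagged
    d: int  # out of category & not flagged

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def universe(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass
class EnrichmentResult:
    table: ContingencyTable
    odds_ratio: float  # sample (cross-product) OR, Haldane-corrected if any zero cell
    ci_low: float  # Woolf 95% CI on the (possibly corrected) cells
    ci_high: float
    p: float  # two-sided Fisher exact p (minimum-likelihood rule)
    odds_ratio_cmle: float  # conditional MLE OR
    ci_low_exact: float  # exact conditional 95% CI
    ci_high_exact: float


def build_contingency(flagged, category, universe) -> ContingencyTable:
    """Cross-tabulate category membership against a flagged gene list.

    Members of ``flagged``/``category`` outside the universe are dropped
    (with a logged count), mirroring the usual restriction of curated gene
    sets to genes actually measured on the platform.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    flagged, category = set(flagged), set(category)
    out_f = len(flagged - universe)
    out_c = len(category - universe)
    if out_f or out_c:
        logger.info(
            "build_contingency: dropped %d flagged / %d category genes "
            "outside the universe", out_f, out_c,
        )
    flagged &= universe
    category &= universe
    a = len(flagged & category)
    b = len(category) - a
    c = len(flagged) - a
    d = len(universe) - a - b - c
    return ContingencyTable(a, b, c, d)


def fisher_exact_2x2(table: ContingencyTable) -> EnrichmentResult:
    """Two-sided Fisher's exact test with odds ratios and 95% CIs.

    The two-sided p-value follows the minimum-likelihood rule: the sum of
    hypergeometric probabilities of all tables (margins fixed) whose point
    probability does not exceed that of the observed table.  When any cell
    is zero, the Haldane-Anscombe +0.5 correction is applied to all cells
    for the sample odds ratio and its Woolf interval.
    """
    arr = table.as_array()
    _, p = stats.fisher_exact(arr, alternative="two-sided")
    cells = arr.astype(float)
    if (cells == 0).any():
        cells = cells + 0.5
    a, b = cells[0]
    c, d = cells[1]
    or_sample = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ci_low = float(np.exp(np.log(or_sample) - 1.96 * se))
    ci_high = float(np.exp(np.log(or_sample) + 1.96 * se))
    res = _cmle_odds_ratio(arr, kind="conditional")
    ci = res.confidence_interval(0.95)
    return EnrichmentResult(
        table=table,
        odds_ratio=float(or_sample),
        ci_low=ci_low,
        ci_high=ci_high,
        p=float(min(p, 1.0)),
        odds_ratio_cmle=float(res.statistic),
        ci_low_exact=float(ci.low),
        ci_high_exact=float(ci.high),
    )


def region_filter(
    annotation: pd.DataFrame, chrom: str, start: int, end: int
) -> set[str]:
    """Genes whose [start, end] span overlaps a genomic interval.

    Coordinates are 1-based inclusive on both sides; a gene touching the
    query boundary counts as overlapping.  An unknown chromosome yields an
    empty set with a warning.
    """
    if start > end:
        raise ValueError("region start must be <= end")
    on_chrom = annotation["chrom"] == chrom
    if not on_chrom.any():
        logger.warning("region_filter: no genes on chromosome %r", chrom)
        return set()
    hits = on_chrom & (annotation["start"] <= end) & (annotation["end"] >= start)
    return set(annotation.index[hits])


def read_gmt(path) -> dict[str, set[str]]:
    """Parse a GMT file (name, description, member genes per line)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT parse error at line {lineno}: < 3 fields")
            name, members = fields[0], {g for g in fields[2:] if g}
            if name in sets:
                raise ValueError(f"duplicate gene-set name {name!r} (line {lineno})")
            if not members:
                raise ValueError(f"gene set {name!r} has no members (line {lineno})")
            sets[name] = members
    return sets


def ora_gene_sets(
    flagged, universe, gene_sets: dict[str, set[str]], alpha: float = 0.05
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation per gene set.

    For a set with K members in the universe of N genes, n flagged genes
    and overlap a, p = P(X >= a) with X ~ Hypergeometric(N, K, n).
    P-values are reported unadjusted and a set is called significant when
    p < alpha (an exploratory convention; no multiplicity correction).
    Sets with no member in the universe are skipped with a warning.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    flagged = set(flagged) & universe
    N, n = len(universe), len(flagged)
    rows = []
    for name, members in gene_sets.items():
        K = len(members & universe)
        if K == 0:
            logger.warning("gene set %r has no members in the universe; skipped", name)
            continue
        a = len(members & flagged)
        p = float(stats.hypergeom.sf(a - 1, N, K, n))
        expected = K * n / N
        rows.append(
            {
                "set": name,
                "overlap": a,
                "set_size": K,
                "expected": expected,
                "enrichment": a / expected if expected > 0 else np.nan,
                "p": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows, columns=["set", "overlap", "set_size", "expected", "enrichment", "p"])
    out = out.sort_values("p", kind="stable").reset_index(drop=True)
    out["significant"] = out["p"] < alpha
    return out


def gene_importance_counts(
    ora: pd.DataFrame, gene_sets: dict[str, set[str]], flagged
) -> pd.Series:
    """Per flagged gene: number of significant sets containing it.

    This is the quantity behind word-cloud summaries where a gene's
    prominence reflects how many enriched terms it appears in.
    """
    flagged = set(flagged)
    sig = ora.loc[ora["significant"], "set"]
    counts: dict[str, int] = {g: 0 for g in flagged}
    for name in sig:
        for g in gene_sets.get(name, ()) :
            if g in flagged:
                counts[g] += 1
    s = pd.Series(counts, name="n_significant_sets").sort_values(ascending=False)
    s.index.name = "gene_id"
    return s
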