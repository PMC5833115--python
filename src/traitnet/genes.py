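"""Gene presence vs growth phenotypes, and gene co-occurrence within trait communities.

Works on a binary species table holding both gene-presence columns and
growth columns.  The gene-growth association is a chi-square test on the full
2x2 presence x growth table (the reported "same"/"different" counts are
summaries of that table); gene co-occurrence within versus between gene
groups is an equal-proportions test on counts pooled over species x pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations, product

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .associations import bh_adjust

log = logging.getLogger("traitnet")

#: gene groups used in the yeast carbon analysis
CONTAINS_GALACTOSE_GENES = ("GAL1", "GAL7", "GAL10", "LAC12", "MEL1")
GLUCOSIDE_GENES = ("MAL11", "MAL13", "MAL6", "IMA/MAL", "IMA5", "SUC2")


def collapse_gene_group(table: pd.DataFrame, members, name: str) -> pd.DataFrame:
    """Collapse closely related paralog columns into one presence column (any-of)."""
    members = [m for m in members if m in table.columns]
    if not members:
        raise ValueError("no member columns present to collapse")
    out = table.drop(columns=members).copy()
    out[name] = table[members].max(axis=1).astype(int)
    return out


@dataclass
class GeneGrowthResult:
    gene: str
    carbon: str
    same: int        # gene present and growth
    different: int   # gene absent & growth + gene present & no growth
    chi2: float
    p: float
    q: float = float("nan")


def gene_growth_chi2(
    table: pd.DataFrame, gene: str, carbon: str, correction: bool = False
) -> GeneGrowthResult | None:
    """Chi-square association of one gene-presence column with one growth column.

    Returns ``None`` (with a log note) when either column is constant, since
    the test is undefined there.
    """
    g = table[gene].astype(int).to_numpy()
    c = table[carbon].astype(int).to_numpy()
    if len(np.unique(g)) < 2 or len(np.unique(c)) < 2:
        log.info("constant column in (%s, %s); test skipped", gene, carbon)
        return None
    tab = np.array([
        [int(((g == 1) & (c == 1)).sum()), int(((g == 1) & (c == 0)).sum())],
        [int(((g == 0) & (c == 1)).sum()), int(((g == 0) & (c == 0)).sum())],
    ])
    chi2, p, _, _ = chi2_contingency(tab, correction=correction)
    return GeneGrowthResult(
        gene=gene, carbon=carbon,
        same=int(tab[0, 0]), different=int(tab[0, 1] + tab[1, 0]),
        chi2=float(chi2), p=float(p),
    )


def gene_growth_scan(
    table: pd.DataFrame, gene_cols, carbon_cols, correction: bool = False
) -> pd.DataFrame:
    """All gene x carbon chi-square tests, BH-adjusted across the scan."""
    rows = []
    for gene, carbon in product(gene_cols, carbon_cols):
        res = gene_growth_chi2(table, gene, carbon, correction=correction)
        if res is not None:
            rows.append(res)
    df = pd.DataFrame([r.__dict__ for r in rows])
    if len(df):
        df["q"] = bh_adjust(df["p"].to_numpy())
    return df


@dataclass
class CoOccurrenceResult:
    within_freq: float
    between_freq: float
    within_events: int
    within_total: int
    between_events: int
    between_total: int
    chi2: float
    p: float


def co_occurrence_test(
    table: pd.DataFrame, group1, group2, yates: bool = True, pooled: bool = True
) -> CoOccurrenceResult:
    """Do genes of the same group co-occur more often than cross-group genes?

    A co-occurrence event is both genes of a pair present in a species.
    Within-pairs are all unordered pairs inside group1 plus inside group2;
    between-pairs all cross-group pairs.  By default events are pooled over
    species x pairs and compared with an equal-proportions chi-square (Yates
    continuity-corrected); ``pooled=False`` averages per-pair frequencies
    instead (diagnostic only, the test still uses pooled counts).
    """
    group1, group2 = list(group1), list(group2)
    if not group1 or not group2:
        raise ValueError("both gene groups must be non-empty")
    if set(group1) & set(group2):
        raise ValueError("gene groups must be disjoint")
    x = table[group1 + group2].astype(int)
    n = len(x)

    def pair_events(pairs):
        ev = sum(int((x[a] & x[b]).sum()) for a, b in pairs)
        return ev, n * len(pairs)

    within_pairs = list(combinations(group1, 2)) + list(combinations(group2, 2))
    between_pairs = list(product(group1, group2))
    w_ev, w_tot = pair_events(within_pairs)
    b_ev, b_tot = pair_events(between_pairs)
    if pooled:
        w_freq, b_freq = w_ev / w_tot, b_ev / b_tot
    else:
        w_freq = float(np.mean([(x[a] & x[b]).mean() for a, b in within_pairs]))
        b_freq = float(np.mean([(x[a] & x[b]).mean() for a, b in between_pairs]))
    tab = np.array([[w_ev, w_tot - w_ev], [b_ev, b_tot - b_ev]])
    chi2, p, _, _ = chi2_contingency(tab, correction=yates)
    return CoOccurrenceResult(
        within_freq=w_freq, between_freq=b_freq,
        within_events=w_ev, within_total=w_tot,
        between_events=b_ev, between_total=b_tot,
        chi2=float(chi2), p=float(p),
    )
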