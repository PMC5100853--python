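"""Gene-list handling and one-tailed Fisher overlap statistics.

Overlap of two gene lists within a declared universe is summarized as a
2x2 contingency table with the sample (cross-product) odds ratio and the
one-tailed enrichment p-value (hypergeometric upper tail). A
conditional-MLE odds ratio is also reported for reference.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import hypergeom
from scipy.stats.contingency import odds_ratio as _cmle_odds_ratio

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneList:
    name: str
    members: frozenset[str]
    universe_name: str = ""

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class OverlapResult:
    a: int  # |A n B|
    b: int  # |A| - a
    c: int  # |B| - a
    d: int  # N - a - b - c
    odds_ratio: float
    odds_ratio_cmle: float
    p_one_tailed: float

    @property
    def universe_size(self) -> int:
        return self.a + self.b + self.c + self.d


def read_gene_list(path: str | Path, name: str = "") -> GeneList:
    """One identifier per line, or the first column of a TSV; whitespace-stripped."""
    members = set()
    with open(path) as fh:
        for line in fh:
            token = line.strip().split("\t")[0].strip()
            if token:
                members.add(token)
    return GeneList(name=name or Path(path).stem, members=frozenset(members))


def build_target_set(
    target_table: pd.DataFrame, mirna_list: Sequence[str], name: str = "mirna_targets"
) -> GeneList:
    """Genes with >= 1 conserved ORF or 3'UTR site for any listed miRNA.

    Only miRNAs present in the table contribute; absent ones are logged and
    skipped. ``target_table`` needs columns gene_id, mirna_family,
    site_region (ORF / 3UTR) and a conserved flag.
    """
    required = {"gene_id", "mirna_family", "site_region", "conserved"}
    missing = required - set(target_table.columns)
    if missing:
        raise ValueError(f"target table lacks columns {sorted(missing)}")
    families = set(target_table["mirna_family"])
    absent = [m for m in mirna_list if m not in families]
    if absent:
        logger.info("%d miRNAs absent from the target table: %s", len(absent), absent[:10])
    present = [m for m in mirna_list if m in families]
    mask = (
        target_table["mirna_family"].isin(present)
        & target_table["conserved"].astype(bool)
        & target_table["site_region"].isin(["ORF", "3UTR"])
    )
    genes = frozenset(g.strip() for g in target_table.loc[mask, "gene_id"].astype(str))
    return GeneList(name=name, members=genes)


def fisher_overlap_counts(
    universe_size: int, size_a: int, size_b: int, overlap: int, cmle: bool = True
) -> OverlapResult:
    """Overlap statistics from pre-tabulated counts.

    a = overlap, b = |A| - a, c = |B| - a, d = N - a - b - c; sample odds
    ratio (a*d)/(b*c) (inf when b*c = 0); p = P[X >= a] for
    X ~ Hypergeometric(N, |A|, |B|). The conditional-MLE odds ratio needs
    iterative root-finding; pass ``cmle=False`` to skip it in bulk use.
    """
    a = overlap
    b = size_a - a
    c = size_b - a
    d = universe_size - a - b - c
    if min(a, b, c) < 0 or d < 0:
        raise ValueError(
            f"inconsistent 2x2 inputs: N={universe_size}, |A|={size_a}, |B|={size_b}, a={a}"
        )
    odds = math.inf if b * c == 0 else (a * d) / (b * c)
    p = float(hypergeom.sf(a - 1, universe_size, size_a, size_b))
    cmle_val = (
        float(_cmle_odds_ratio([[a, b], [c, d]], kind="conditional").statistic)
        if cmle
        else math.nan
    )
    return OverlapResult(
        a=a, b=b, c=c, d=d, odds_ratio=odds, odds_ratio_cmle=cmle_val, p_one_tailed=p
    )


def fisher_overlap(
    universe_size: int, list_a: GeneList | Iterable[str], list_b: GeneList | Iterable[str]
) -> OverlapResult:
    """Overlap statistics from explicit gene lists within a universe of given size."""
    members_a = set(list_a.members if isinstance(list_a, GeneList) else list_a)
    members_b = set(list_b.members if isinstance(list_b, GeneList) else list_b)
    if max(len(members_a), len(members_b)) > universe_size:
        raise ValueError("list larger than universe")
    return fisher_overlap_counts(
        universe_size, len(members_a), len(members_b), len(members_a & members_b)
    )


def overlap_report(
    comparisons: Sequence[tuple[str, int, GeneList, GeneList]],
) -> pd.DataFrame:
    """Tabular report of several overlap tests (dataset sizes, overlap, p, OR)."""
    rows = []
    for name, universe_size, list_a, list_b in comparisons:
        res = fisher_overlap(universe_size, list_a, list_b)
        rows.append(
            {
                "comparison": name,
                "universe": universe_size,
                "list_a": list_a.name,
                "n_a": len(list_a),
                "list_b": list_b.name,
                "n_b": len(list_b),
                "overlap": res.a,
                "p_value": res.p_one_tailed,
                "odds_ratio": res.odds_ratio,
            }
        )
    columns = [
        "comparison", "universe", "list_a", "n_a", "list_b", "n_b",
        "overlap", "p_value", "odds_ratio",
    ]
    return pd.DataFrame(rows, columns=columns)
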