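"""Sample-set aggregation, expression-profile clustering, and selection filters.

A "sample set" is one genotype x timepoint cell averaged over its three
replicates, giving six columns (wt/mut x three timepoints). Canonical
miRNAs passing an RPM >= 10 filter are clustered into k=5 expression
classes (A-E) by agglomerative hierarchical clustering of log2(RPM + 1)
wild-type profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .synthetic import GENOTYPES, TIMEPOINTS

SAMPLE_SETS = tuple(f"{g}.{t}" for g in GENOTYPES for t in TIMEPOINTS)
WT_SETS = tuple(f"wt.{t}" for t in TIMEPOINTS)
EMBRYO_TIMEPOINTS = ("F0_2h", "F2_4h")


def sample_set_means(rpm_matrix: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Per-feature arithmetic mean RPM over the replicates of each sample set.

    Requires the complete 2 x 3 x 3 design; a missing replicate is an error.
    """
    cols = {}
    for g in GENOTYPES:
        for t in TIMEPOINTS:
            libs = design.index[(design["genotype"] == g) & (design["timepoint"] == t)]
            if len(libs) != 3:
                raise ValueError(f"incomplete design: {g}.{t} has {len(libs)} replicates, need 3")
            cols[f"{g}.{t}"] = rpm_matrix[libs].mean(axis=1)
    return pd.DataFrame(cols, index=rpm_matrix.index)[list(SAMPLE_SETS)]


def select_canonical_for_clustering(
    sample_sets: pd.DataFrame, min_rpm: float = 10.0
) -> pd.Index:
    """Features whose mean RPM reaches ``min_rpm`` (inclusive) in >= 1 sample set."""
    keep = (sample_sets >= min_rpm).any(axis=1)
    return sample_sets.index[keep]


@dataclass
class ClassAssignment:
    labels: pd.Series  # mirna_id -> class label
    k: int
    columns_used: tuple[str, ...]

    def members(self, label: str) -> list[str]:
        return list(self.labels.index[self.labels == label])


def cluster_classes(
    sample_sets: pd.DataFrame,
    k: int = 5,
    wildtype_only: bool = True,
    method: str = "complete",
    metric: str = "euclidean",
) -> ClassAssignment:
    """Hierarchical clustering of log2(mean RPM + 1) profiles into k classes.

    By default clusters on the three wild-type sample sets (classes are
    defined by the wild-type developmental profile; mutant behaviour is
    then summarized per class). The tree is cut at k clusters, which are
    relabeled A, B, ... by ascending wild-type maternal (UF) abundance,
    with ties broken by descending zygotic gain (F2_4h / UF ratio).
    """
    cols = list(WT_SETS) if wildtype_only else list(SAMPLE_SETS)
    x = np.log2(sample_sets[cols].to_numpy(dtype=float) + 1.0)
    n = x.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of features ({n})")
    if k == n:
        raw = np.arange(1, n + 1)
    else:
        z = linkage(x, method=method, metric=metric)
        raw = fcluster(z, t=k, criterion="maxclust")

    uf = np.log2(sample_sets["wt.UF0_2h"].to_numpy(dtype=float) + 1.0)
    late = np.log2(sample_sets["wt.F2_4h"].to_numpy(dtype=float) + 1.0)
    order_keys = []
    for c in np.unique(raw):
        members = raw == c
        order_keys.append((float(uf[members].mean()), -float((late - uf)[members].mean()), c))
    order_keys.sort()
    alphabet = [chr(ord("A") + i) for i in range(len(order_keys))]
    relabel = {c: alphabet[i] for i, (_, _, c) in enumerate(order_keys)}
    labels = pd.Series([relabel[c] for c in raw], index=sample_sets.index, name="class")
    return ClassAssignment(labels=labels, k=k, columns_used=tuple(cols))


def class_summary(assignment: ClassAssignment, sample_sets: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean RPM per class per sample set (both genotypes)."""
    joined = sample_sets.join(assignment.labels)
    out = joined.groupby("class").mean()
    out.index.name = "class"
    return out


def select_downregulated_mirnas(
    de_by_timepoint: Mapping[str, pd.DataFrame],
    canonical_sets: pd.DataFrame,
    fdr_max: float = 0.05,
    min_rpm: float = 10.0,
) -> list[str]:
    """Canonical miRNAs significantly reduced in the mutant.

    Union over the supplied per-timepoint contrasts of features with
    FDR <= ``fdr_max`` and negative log fold-change (mutant below wild
    type), intersected with the canonical RPM >= ``min_rpm`` in >= 1
    sample set filter.
    """
    hits: set[str] = set()
    for de in de_by_timepoint.values():
        sig = de.index[(de["FDR"] <= fdr_max) & (de["logFC"] < 0)]
        hits.update(sig)
    expressed = set(select_canonical_for_clustering(canonical_sets, min_rpm=min_rpm))
    return sorted(hits & expressed)


def _proportions(part: pd.DataFrame, total: pd.DataFrame) -> pd.DataFrame:
    with np.errstate(divide="ignore", invalid="ignore"):
        p = part / total
    return p.fillna(0.0)


def select_noncanonical_subset(
    canonical: pd.DataFrame,
    noncanonical: pd.DataFrame,
    nta: pd.DataFrame,
    min_total: float = 10.0,
    min_share: float = 0.5,
    min_shift: float = 0.2,
) -> pd.DataFrame:
    """Highly expressed, dynamic noncanonical miRNAs.

    Criteria (all on sample-set RPM matrices with identical indexes):
      1. canonical + noncanonical + NTA total >= ``min_total`` in >= 1 set;
      2. noncanonical share of the total >= ``min_share`` in >= 1 set;
      3. the wild-type noncanonical share changes by >= ``min_shift``
         between unfertilized eggs and either embryo timepoint.

    Returns a per-criterion pass/fail table with a ``selected`` column.
    """
    total = canonical + noncanonical + nta
    share = _proportions(noncanonical, total)
    c1 = (total >= min_total).any(axis=1)
    c2 = (share >= min_share).any(axis=1)
    shifts = pd.concat(
        [(share["wt.UF0_2h"] - share[f"wt.{t}"]).abs() for t in EMBRYO_TIMEPOINTS], axis=1
    )
    c3 = (shifts >= min_shift).any(axis=1)
    return pd.DataFrame(
        {"c1_total": c1, "c2_share": c2, "c3_shift": c3, "selected": c1 & c2 & c3}
    )


def select_nta_subset(
    canonical: pd.DataFrame,
    noncanonical: pd.DataFrame,
    nta: pd.DataFrame,
    min_total: float = 10.0,
    min_share: float = 0.2,
    min_sets: int = 2,
    min_shift_uf: float = 0.1,
    min_shift_mut: float = 0.2,
) -> pd.DataFrame:
    """Highly expressed, dynamic NTA miRNAs.

    Criteria: (1) total >= ``min_total`` in >= 1 set; (2) NTA share >=
    ``min_share`` in >= ``min_sets`` sets; (3) the NTA share differs by >=
    ``min_shift_uf`` between wild-type eggs and embryos, or by >=
    ``min_shift_mut`` between wild-type and mutant embryos.
    """
    total = canonical + noncanonical + nta
    share = _proportions(nta, total)
    c1 = (total >= min_total).any(axis=1)
    c2 = (share >= min_share).sum(axis=1) >= min_sets
    shift_uf = pd.concat(
        [(share["wt.UF0_2h"] - share[f"wt.{t}"]).abs() for t in EMBRYO_TIMEPOINTS], axis=1
    ).max(axis=1)
    shift_mut = pd.concat(
        [(share[f"wt.{t}"] - share[f"mut.{t}"]).abs() for t in EMBRYO_TIMEPOINTS], axis=1
    ).max(axis=1)
    c3 = (shift_uf >= min_shift_uf) | (shift_mut >= min_shift_mut)
    return pd.DataFrame(
        {"c1_total": c1, "c2_share": c2, "c3_shift": c3, "selected": c1 & c2 & c3}
    )
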