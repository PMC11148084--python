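"""Fuzzy membership-function scoring and tolerance grading.

Each genotype's STI for each trait is rescaled across genotypes to the unit
interval by the fuzzy membership function

    Xi = (X - Xmin) / (Xmax - Xmin)

where Xmin/Xmax are the minimum/maximum STI for that trait over all
genotypes, so per trait at least one genotype scores 0 and one scores 1.
The genotype's composite tolerance score is the arithmetic mean of its MFVs
over the selected traits (mean MFV, in [0, 1]; higher = more tolerant).

Genotypes are then graded by agglomerative hierarchical clustering of the
scalar mean-MFV values with furthest-neighbour (complete) linkage and
Euclidean distance, cut at k clusters.  Clusters ranked by descending mean
of mean MFV receive grades HST, ST, MST, SS, HSS when k = 5 (G1..Gk
otherwise).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .errors import DegenerateInputError, ValidationError
from .indices import apply_undefined_policy
from .traits import GRADE_LABELS, normalize_traits

logger = logging.getLogger(__name__)


def membership_function(x: float, x_min: float, x_max: float) -> float:
    """Min-max membership value (X - Xmin)/(Xmax - Xmin), in [0, 1]."""
    if x_max <= x_min:
        raise DegenerateInputError(
            f"membership function undefined: x_max ({x_max}) <= x_min ({x_min})")
    if x < x_min or x > x_max:
        raise ValidationError(f"x={x} outside [{x_min}, {x_max}]")
    return (x - x_min) / (x_max - x_min)


@dataclass
class MFVTable:
    """Per-genotype, per-trait membership values with the trait extremes used."""

    table: pd.DataFrame          # columns: genotype, trait, sti, mfv
    extremes: pd.DataFrame       # columns: trait, x_min, x_max

    def pivot(self) -> pd.DataFrame:
        """Genotype x trait matrix of MFVs."""
        return self.table.pivot(index="genotype", columns="trait", values="mfv")


def build_mfv_table(index_table: pd.DataFrame, traits=None,
                    undefined_policy: str = "drop",
                    degenerate_trait: str = "fail") -> MFVTable:
    """Membership values of trait STIs across genotypes at one concentration.

    ``index_table`` must contain a single stress concentration (the chosen
    screening dose).  ``degenerate_trait`` controls traits whose STI is
    constant across genotypes: ``"fail"`` (default) or ``"drop"`` with a
    warning.
    """
    table = apply_undefined_policy(index_table, undefined_policy)
    concs = table["concentration"].unique()
    if len(concs) != 1:
        raise ValidationError(
            f"MFV requires a single screening concentration, got {sorted(concs)}")
    if traits is not None:
        traits = normalize_traits(traits)
        table = table[table["trait"].isin(traits)]
        if set(table["trait"].unique()) != set(traits):
            missing = set(traits) - set(table["trait"].unique())
            raise ValidationError(f"traits absent from index table: {sorted(missing)}")
    if degenerate_trait not in ("fail", "drop"):
        raise ValueError(f"degenerate_trait must be 'fail' or 'drop'")

    rows, extremes = [], []
    for trait, sub in table.groupby("trait", sort=True):
        x = sub["sti"].to_numpy(float)
        x_min, x_max = float(x.min()), float(x.max())
        if x_max <= x_min:
            if degenerate_trait == "fail":
                raise DegenerateInputError(
                    f"trait {trait}: all genotypes share STI={x_min}; "
                    "membership function is undefined")
            logger.warning("dropping degenerate trait %s (constant STI %.4g)",
                           trait, x_min)
            continue
        mfv = (x - x_min) / (x_max - x_min)
        rows.extend(zip(sub["genotype"], [trait] * len(sub), x, mfv))
        extremes.append((trait, x_min, x_max))

    if not rows:
        raise DegenerateInputError("no non-degenerate traits left for MFV")
    out = pd.DataFrame(rows, columns=["genotype", "trait", "sti", "mfv"])
    return MFVTable(table=out,
                    extremes=pd.DataFrame(extremes, columns=["trait", "x_min", "x_max"]))


def mean_mfv(mfv_table: MFVTable, traits=None) -> pd.Series:
    """Arithmetic mean MFV per genotype over the selected traits."""
    table = mfv_table.table
    if traits is not None:
        traits = normalize_traits(traits)
        table = table[table["trait"].isin(traits)]
    else:
        traits = tuple(sorted(table["trait"].unique()))
    counts = table.groupby("genotype")["trait"].count()
    incomplete = counts[counts != len(traits)]
    if not incomplete.empty:
        raise ValidationError(
            f"genotypes missing trait MFVs: {sorted(incomplete.index)[:5]}")
    out = table.groupby("genotype")["mfv"].mean().rename("mean_mfv")
    return out


@dataclass
class ToleranceReport:
    """Grading result: one row per genotype plus the merge tree."""

    table: pd.DataFrame          # columns: genotype, mean_mfv, cluster_id, grade
    linkage: np.ndarray          # scipy condensed linkage matrix
    k: int

    @property
    def grade_counts(self) -> dict[str, int]:
        counts = self.table["grade"].value_counts().to_dict()
        order = GRADE_LABELS if self.k == 5 else [f"G{i}" for i in range(1, self.k + 1)]
        return {g: int(counts.get(g, 0)) for g in order}


def cluster_grades(mean_mfv_values: pd.Series, k: int = 5) -> ToleranceReport:
    """Grade genotypes by complete-linkage clustering of their mean MFV.

    Clusters are cut at ``k`` and ranked by descending within-cluster mean of
    mean MFV; with k = 5 the ranked clusters are labelled HST, ST, MST, SS,
    HSS (most to least tolerant).
    """
    if k < 2:
        raise ValidationError(f"cluster count must be >= 2, got {k}")
    values = mean_mfv_values.sort_index()
    n = len(values)
    if n < k:
        raise ValidationError(f"{n} genotypes cannot form {k} clusters")

    z = hierarchy.linkage(values.to_numpy(float).reshape(-1, 1),
                          method="complete", metric="euclidean")
    cluster_raw = hierarchy.fcluster(z, t=k, criterion="maxclust")

    means = pd.Series(values.to_numpy(), index=cluster_raw).groupby(level=0).mean()
    order = means.sort_values(ascending=False).index  # rank 0 = most tolerant
    labels = GRADE_LABELS if k == 5 else tuple(f"G{i}" for i in range(1, k + 1))
    rank_of = {raw: rank for rank, raw in enumerate(order)}

    table = pd.DataFrame({
        "genotype": values.index,
        "mean_mfv": values.to_numpy(),
        "cluster_id": [rank_of[c] + 1 for c in cluster_raw],
        "grade": [labels[rank_of[c]] for c in cluster_raw],
    }).reset_index(drop=True)
    report = ToleranceReport(table=table, linkage=z, k=k)
    logger.info("graded %d genotypes: %s", n, report.grade_counts)
    return report


def evaluate_tolerance(index_table: pd.DataFrame, traits=None, k: int = 5,
                       undefined_policy: str = "drop",
                       degenerate_trait: str = "fail") -> tuple[MFVTable, pd.Series, ToleranceReport]:
    """MFV table, mean MFV and graded report in one call."""
    mfv = build_mfv_table(index_table, traits, undefined_policy, degenerate_trait)
    scores = mean_mfv(mfv)
    return mfv, scores, cluster_grades(scores, k)


def linkage_to_newick(linkage: np.ndarray, labels) -> str:
    """Render the merge tree as a newick string (branch lengths = merge heights)."""
    tree = hierarchy.to_tree(linkage)

    def walk(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"
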