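"""Odor-set descriptor handling and virtual-screening statistics.

Docking scores are in kcal mol⁻¹ with the convention that more negative
means stronger predicted binding; every ranking here therefore orders
scores ascending ("more-negative-first"). AUC is the Mann–Whitney
probability that a random positive outranks a random negative, with ties
counted ½.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve
from statsmodels.stats.multitest import multipletests

from .errors import AnalysisError, FormatError

REQUIRED_ODOR_COLUMNS = ("id", "score", "mol_weight", "volume", "logP", "chem_class")
DESCRIPTORS = ("mol_weight", "volume", "logP")

CHEM_CLASSES = (
    "alcohol", "ketone", "acid", "ester", "aldehyde", "ether", "aromatic", "other",
)


@dataclass(frozen=True)
class OdorRecord:
    """One odorant: docking score plus physicochemical descriptors."""

    id: str
    score: float        # kcal mol⁻¹, more negative = stronger
    mol_weight: float   # g mol⁻¹
    volume: float       # Å³
    logP: float
    chem_class: str = "other"


def validate_odor_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_ODOR_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"odor table missing columns: {missing}")
    table = table.copy()
    table["id"] = table["id"].astype(str)
    if table["id"].duplicated().any():
        dups = table.loc[table["id"].duplicated(), "id"].tolist()
        raise FormatError(f"duplicate odor ids: {dups}")
    for col in ("score", "mol_weight", "volume", "logP"):
        try:
            table[col] = pd.to_numeric(table[col], errors="raise")
        except (ValueError, TypeError) as exc:
            raise FormatError(f"non-numeric value in column {col!r}") from exc
    if (table["volume"] <= 0).any() or (table["mol_weight"] <= 0).any():
        raise FormatError("volume and mol_weight must be positive")
    return table.reset_index(drop=True)


def load_odor_table(path) -> pd.DataFrame:
    """Read and validate a delimited odor-score table."""
    table = pd.read_csv(path, sep=None, engine="python", comment="#")
    return validate_odor_table(table)


def records_from_table(table: pd.DataFrame) -> List[OdorRecord]:
    return [
        OdorRecord(
            id=row["id"], score=float(row["score"]),
            mol_weight=float(row["mol_weight"]), volume=float(row["volume"]),
            logP=float(row["logP"]), chem_class=str(row["chem_class"]),
        )
        for _, row in table.iterrows()
    ]


def top_fraction_subset(
    table: pd.DataFrame,
    descriptor: str,
    fraction: float = 1.0 / 3.0,
    direction: str = "descending",
) -> List[str]:
    """Ids of the ⌊n·fraction⌋ records ranked by a descriptor.

    ``descending`` ranks large values first (the "large odors" subsets);
    ties break deterministically by id. n = 132 with fraction 1/3 yields
    44 ids. Returned in rank order, so subsets nest as the fraction grows.
    """
    if descriptor not in DESCRIPTORS:
        raise AnalysisError(f"descriptor must be one of {DESCRIPTORS}")
    if not 0 < fraction <= 1:
        raise AnalysisError("fraction must be in (0, 1]")
    if len(table) == 0:
        raise AnalysisError("empty odor table")
    ascending = direction == "ascending"
    ranked = table.sort_values(
        [descriptor, "id"], ascending=[ascending, True], kind="mergesort"
    )
    k = int(np.floor(len(table) * fraction))
    return ranked["id"].head(k).tolist()


@dataclass
class RocResult:
    """ROC points (FPR, TPR) from (0,0) to (1,1) and the tie-aware AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_positive: int
    n_negative: int


def roc_auc(
    table: pd.DataFrame,
    positive_ids: Iterable[str],
    score_orientation: str = "more_negative_first",
) -> RocResult:
    """Screening performance of the score ranking against a positive set.

    AUC is computed from the Mann–Whitney rank formula (ties ½); curve
    points come from the thresholded ranking.
    """
    positives = set(str(p) for p in positive_ids)
    labels = table["id"].astype(str).isin(positives).to_numpy()
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise AnalysisError("both classes must be nonempty for a ROC curve")
    scores = table["score"].to_numpy(dtype=float)
    if score_orientation == "more_negative_first":
        strength = -scores
    elif score_orientation == "higher_first":
        strength = scores
    else:
        raise AnalysisError(f"unknown score orientation {score_orientation!r}")
    ranks = stats.rankdata(strength)  # average ranks handle ties as ½
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    fpr, tpr, _ = roc_curve(labels.astype(int), strength)
    return RocResult(fpr=fpr, tpr=tpr, auc=float(auc),
                     n_positive=n_pos, n_negative=n_neg)


@dataclass
class TrendResult:
    """Binned score response along a descriptor plus a rank correlation."""

    bin_mean_descriptor: np.ndarray
    bin_mean_score: np.ndarray
    bin_counts: np.ndarray
    spearman_rho: float
    spearman_p: float


def descriptor_trend(
    table: pd.DataFrame, descriptor: str, n_bins: int = 6
) -> TrendResult:
    """Equal-count binned mean scores over a descriptor plus Spearman ρ.

    When either variable is constant the rank correlation is reported as
    0 (no monotone association resolvable under total ties).
    """
    if descriptor not in DESCRIPTORS:
        raise AnalysisError(f"descriptor must be one of {DESCRIPTORS}")
    if n_bins < 2:
        raise AnalysisError("n_bins must be >= 2")
    if n_bins > len(table):
        raise AnalysisError("more bins than records")
    ranked = table.sort_values([descriptor, "id"], kind="mergesort")
    chunks = np.array_split(np.arange(len(ranked)), n_bins)
    mean_desc = np.array(
        [ranked[descriptor].to_numpy()[c].mean() for c in chunks]
    )
    mean_score = np.array([ranked["score"].to_numpy()[c].mean() for c in chunks])
    counts = np.array([len(c) for c in chunks])
    x = table[descriptor].to_numpy(dtype=float)
    y = table["score"].to_numpy(dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        rho, p = 0.0, 1.0
    else:
        rho, p = stats.spearmanr(x, y)
    return TrendResult(
        bin_mean_descriptor=mean_desc, bin_mean_score=mean_score,
        bin_counts=counts, spearman_rho=float(rho), spearman_p=float(p),
    )


@dataclass
class ClassSelectivityResult:
    """Per-class score summaries and BH-adjusted pairwise rank-sum tests."""

    summary: pd.DataFrame    # class, n, mean, median
    pairwise: pd.DataFrame   # class_a, class_b, statistic, p, p_adj, significant
    excluded: List[str]      # singleton classes dropped with a warning
    alpha: float

    @property
    def any_significant(self) -> bool:
        return bool(self.pairwise["significant"].any())


def class_selectivity(
    table: pd.DataFrame, alpha: float = 0.05
) -> ClassSelectivityResult:
    """Does the score distribution differ between chemical classes?

    Two-sided Wilcoxon rank-sum per class pair with Benjamini–Hochberg
    adjustment across pairs. Classes with fewer than 2 members are
    excluded with a warning.
    """
    groups: Dict[str, np.ndarray] = {}
    excluded: List[str] = []
    for cls, sub in table.groupby("chem_class"):
        if len(sub) < 2:
            excluded.append(str(cls))
            continue
        groups[str(cls)] = sub["score"].to_numpy(dtype=float)
    if excluded:
        warnings.warn(f"singleton classes excluded: {excluded}", stacklevel=2)
    if len(groups) < 2:
        raise AnalysisError("need at least 2 classes with >= 2 members")
    summary = pd.DataFrame(
        [
            {"chem_class": c, "n": len(v), "mean_score": v.mean(),
             "median_score": float(np.median(v))}
            for c, v in sorted(groups.items())
        ]
    )
    names = sorted(groups)
    rows = []
    for a_i in range(len(names)):
        for b_i in range(a_i + 1, len(names)):
            a, b = names[a_i], names[b_i]
            res = stats.ranksums(groups[a], groups[b])
            rows.append(
                {"class_a": a, "class_b": b,
                 "statistic": float(res.statistic), "p": float(res.pvalue)}
            )
    pairwise = pd.DataFrame(rows)
    reject, p_adj, _, _ = multipletests(
        pairwise["p"].to_numpy(), alpha=alpha, method="fdr_bh"
    )
    pairwise["p_adj"] = p_adj
    pairwise["significant"] = reject
    return ClassSelectivityResult(
        summary=summary, pairwise=pairwise, excluded=excluded, alpha=alpha
    )
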