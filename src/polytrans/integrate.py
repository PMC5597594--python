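"""Gene classification and cross-dataset summaries.

Combines total-mRNA DE, ribosome-association DE, polysome-profile
flags, ribosome-load changes and CLIP target tiers into a per-gene
class table, Venn counts, tier crosstabs, high-expression windows and
rank-sum shift tests.
"""

from __future__ import annotations

import math
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CLASSES",
    "classify_genes",
    "venn_counts",
    "percent",
    "crosstab_targets",
    "expression_window",
    "genes_in_window",
    "window_shift_test",
]

CLASSES = ("neither", "abundance_only", "translation_only", "both")


def percent(part: int, whole: int) -> int:
    """Nearest-integer percentage, half away from zero."""
    if whole == 0:
        raise ValueError("cannot take a percentage of an empty set")
    return int(math.floor(100.0 * part / whole + 0.5))


def _flag(df: Optional[pd.DataFrame], column: str, universe: pd.Index, threshold=None):
    if df is None:
        return pd.Series(pd.NA, index=universe, dtype="boolean")
    series = df[column].reindex(universe)
    if threshold is not None:
        series = series < threshold
    return series.fillna(False).astype("boolean")


def classify_genes(
    total_de: pd.DataFrame,
    ribo_de: pd.DataFrame,
    profile: Optional[pd.DataFrame] = None,
    riboload_result: Optional[pd.DataFrame] = None,
    padj_threshold: float = 0.01,
) -> tuple[pd.DataFrame, dict]:
    """Per-gene classification from the two primary significance flags.

    The gene universe is the index of ``total_de`` (genes detected in
    the total-mRNA matrix).  ``abundance_change`` and ``ribo_change``
    are padj < threshold on the respective DE tables and drive the
    four-way class; profile and ribosome-load flags are carried as
    extra columns.  Returns (table, Venn summary dict).
    """
    universe = total_de.index
    unmatched = len(set(ribo_de.index) - set(universe))

    out = pd.DataFrame(index=universe)
    out["abundance_change"] = _flag(total_de, "padj", universe, padj_threshold)
    out["ribo_change"] = _flag(ribo_de, "padj", universe, padj_threshold)
    if profile is not None:
        for col in ("changed_any", "changed_mono", "changed_light", "changed_heavy"):
            out[col] = _flag(profile, col, universe)
    if riboload_result is not None:
        out["riboload_change"] = (
            riboload_result["changed"].reindex(universe).fillna(False).astype("boolean")
        )

    a = out["abundance_change"].fillna(False).to_numpy(bool)
    r = out["ribo_change"].fillna(False).to_numpy(bool)
    cls = np.where(a & r, "both", np.where(a, "abundance_only",
                   np.where(r, "translation_only", "neither")))
    out["class"] = cls
    summary = venn_counts(out)
    if unmatched:
        summary["unmatched_ids"] = unmatched
    return out, summary


def venn_counts(gene_class: pd.DataFrame) -> dict:
    """Venn arithmetic over the abundance and translation sets."""
    cls = gene_class["class"]
    n_both = int((cls == "both").sum())
    n_a_only = int((cls == "abundance_only").sum())
    n_t_only = int((cls == "translation_only").sum())
    n_abundance = n_a_only + n_both
    n_translation = n_t_only + n_both
    summary = {
        "n_genes": int(len(gene_class)),
        "abundance": n_abundance,
        "translation": n_translation,
        "both": n_both,
        "abundance_only": n_a_only,
        "translation_only": n_t_only,
        "neither": int((cls == "neither").sum()),
    }
    if n_abundance:
        summary["pct_abundance_without_translation"] = percent(n_a_only, n_abundance)
    if n_translation:
        summary["pct_translation_with_abundance"] = percent(n_both, n_translation)
    return summary


def crosstab_targets(gene_class: pd.DataFrame, tiers: pd.DataFrame) -> pd.DataFrame:
    """Class and change-flag proportions per target tier.

    Tiers are the nested memberships (0, 1+, 10+, 25+, 50+); the ``0``
    row is the complement of ``1+``.  Proportions are NaN for empty
    tiers.
    """
    joined = gene_class.join(tiers, how="left")
    joined["utr3_count"] = joined["utr3_count"].fillna(0)
    masks = {"0": joined["utr3_count"] == 0}
    for label, col in (("1+", "tier_1plus"), ("10+", "tier_10plus"),
                       ("25+", "tier_25plus"), ("50+", "tier_50plus")):
        masks[label] = joined[col].fillna(False).astype(bool) if col in joined else (
            joined["utr3_count"] >= int(label.rstrip("+"))
        )
    flag_cols = [
        c for c in ("changed_any", "changed_mono", "changed_light", "changed_heavy")
        if c in joined.columns
    ]
    rows = []
    for label, mask in masks.items():
        sub = joined[mask]
        n = len(sub)
        row = {"tier": label, "n_genes": n}
        for cls in CLASSES:
            row[f"prop_{cls}"] = (sub["class"] == cls).mean() if n else np.nan
        for col in flag_cols:
            row[f"prop_{col}"] = sub[col].fillna(False).astype(bool).mean() if n else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("tier")


def expression_window(mean_log2: float, delta_counts: float = 1000.0) -> tuple[float, float]:
    """High-expression window: log2 of the mean count +- ``delta_counts``."""
    mean_counts = 2.0**mean_log2
    if mean_counts <= delta_counts:
        raise ValueError(
            f"2**{mean_log2} = {mean_counts:.1f} does not exceed delta {delta_counts}"
        )
    return (
        math.log2(mean_counts - delta_counts),
        math.log2(mean_counts + delta_counts),
    )


def genes_in_window(
    mean_counts: pd.Series, mean_log2: float, delta_counts: float = 1000.0
) -> pd.Index:
    """Genes whose mean normalized count lies inside the window."""
    lower, upper = expression_window(mean_log2, delta_counts)
    lo, hi = 2.0**lower, 2.0**upper
    return mean_counts.index[(mean_counts >= lo) & (mean_counts <= hi)]


def window_shift_test(all_values: Iterable[float], subset_values: Iterable[float]) -> float:
    """Two-sided Wilcoxon rank-sum p for a shift between the two samples."""
    x = np.asarray(list(all_values), dtype=float)
    y = np.asarray(list(subset_values), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    return float(stats.ranksums(x, y).pvalue)
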