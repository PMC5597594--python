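"""Polysome-distribution analysis.

Interaction LRT between condition-by-fraction and fraction-only NB
GLMs, per-fraction post-hoc Welch tests with monosome/light/heavy
group flags, ribosome-association differential expression on
fraction-summed counts, and the heavy-fraction ribosome-load
statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from polytrans import nb_glm
from polytrans.matrix import TOTAL, FractionCountMatrix

__all__ = [
    "FractionDesign",
    "profile_lrt",
    "profile_analysis",
    "posthoc_fraction_tests",
    "ribosome_association_de",
    "riboload",
]


@dataclass(frozen=True)
class FractionDesign:
    """Gradient layout: fraction labels and their functional groups."""

    fractions: tuple[int, ...] = tuple(range(4, 17))
    monosomes: tuple[int, ...] = (4, 5, 6, 7)
    light: tuple[int, ...] = (8, 9, 10)
    heavy: tuple[int, ...] = tuple(range(11, 17))
    conditions: tuple[str, str] = ("L", "LE")

    def __post_init__(self) -> None:
        groups = self.monosomes + self.light + self.heavy
        if sorted(groups) != sorted(self.fractions) or len(set(self.fractions)) != len(
            self.fractions
        ):
            raise ValueError("monosome/light/heavy groups must partition the fractions")

    def group_of(self, fraction: int) -> str:
        if fraction in self.monosomes:
            return "mono"
        if fraction in self.light:
            return "light"
        return "heavy"


def _fraction_samples(fcm: FractionCountMatrix, design: FractionDesign) -> pd.DataFrame:
    meta = fcm.samples[fcm.samples["fraction"] != TOTAL].copy()
    meta["fraction"] = meta["fraction"].astype(int)
    missing = set(design.fractions) - set(meta["fraction"])
    if missing:
        raise ValueError(f"missing fractions in count matrix: {sorted(missing)}")
    return meta


def _design_matrices(
    meta: pd.DataFrame, design: FractionDesign, reduced: str
) -> tuple[np.ndarray, np.ndarray]:
    # cell-means parametrization (one indicator per condition x fraction
    # cell) spans the same space as intercept + main effects + interaction
    # but stays well conditioned under IRLS
    cond = (meta["condition"] == design.conditions[1]).to_numpy(float)
    frac_oh = pd.get_dummies(
        pd.Categorical(meta["fraction"], categories=design.fractions)
    ).to_numpy(float)
    full = np.hstack([frac_oh * (1.0 - cond)[:, None], frac_oh * cond[:, None]])
    full = full[:, full.any(axis=0)]
    if reduced == "as-printed":
        red = frac_oh
    elif reduced == "with-condition":
        red = np.hstack([frac_oh, cond[:, None]])
    else:
        raise ValueError("reduced must be 'as-printed' or 'with-condition'")
    return full, red


def profile_lrt(
    counts: np.ndarray,
    meta: pd.DataFrame,
    size_factors: np.ndarray,
    alpha: float,
    design: FractionDesign = FractionDesign(),
    reduced: str = "as-printed",
) -> tuple[float, float]:
    """Condition-by-fraction LRT for a single gene.

    Fits the full NB GLM (condition + fraction + interaction) and the
    reduced model (fraction only, as printed; optionally keeping the
    condition main effect) and returns (statistic, p).
    """
    full_x, red_x = _design_matrices(meta, design, reduced)
    full = nb_glm.fit_nb_glm(counts, full_x, size_factors, alpha)
    red = nb_glm.fit_nb_glm(counts, red_x, size_factors, alpha)
    return nb_glm.lrt(full, red)


def posthoc_fraction_tests(
    norm_counts: pd.DataFrame,
    meta: pd.DataFrame,
    design: FractionDesign = FractionDesign(),
    p_threshold: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-fraction Welch t-tests between conditions for every gene.

    Tests log2(normalized count + 0.5) per fraction; returns (p-value
    table genes x fractions, flags table with changed_any/mono/light/
    heavy).  Zero variance in both groups yields p = 1 when the means
    agree and p = 0 otherwise.
    """
    cond_a, cond_b = design.conditions
    logs = np.log2(norm_counts + 0.5)
    pvals = pd.DataFrame(index=norm_counts.index, columns=list(design.fractions), dtype=float)
    for f in design.fractions:
        ids_a = meta.index[(meta["fraction"] == f) & (meta["condition"] == cond_a)]
        ids_b = meta.index[(meta["fraction"] == f) & (meta["condition"] == cond_b)]
        a = logs[ids_a].to_numpy()
        b = logs[ids_b].to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
            # near-identical replicate values are a legitimate input here
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.ttest_ind(a, b, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
        degenerate = np.isnan(p)
        equal_means = np.isclose(a.mean(axis=1), b.mean(axis=1))
        p[degenerate & equal_means] = 1.0
        p[degenerate & ~equal_means] = 0.0
        pvals[f] = p

    sig = pvals < p_threshold
    flags = pd.DataFrame(index=norm_counts.index)
    flags["changed_mono"] = sig[list(design.monosomes)].any(axis=1)
    flags["changed_light"] = sig[list(design.light)].any(axis=1)
    flags["changed_heavy"] = sig[list(design.heavy)].any(axis=1)
    flags["changed_any"] = sig.any(axis=1)
    return pvals, flags


def profile_analysis(
    fcm: FractionCountMatrix,
    design: FractionDesign = FractionDesign(),
    reduced: str = "as-printed",
    padj_threshold: float = 0.01,
    posthoc_threshold: float = 0.01,
    alphas: np.ndarray | None = None,
) -> pd.DataFrame:
    """Full polysome-distribution result table.

    One row per gene: LRT statistic/p/padj, the 13 per-fraction
    post-hoc p-values (columns ``p_f<label>``) and the change flags.
    """
    meta = _fraction_samples(fcm, design)
    counts = fcm.counts[meta.index]
    sf = nb_glm.estimate_size_factors(counts)
    full_x, _ = _design_matrices(meta, design, reduced)
    if alphas is None:
        alphas = nb_glm.estimate_dispersion(counts, sf, full_x)

    stats_p = np.full((len(counts), 2), np.nan)
    for i in range(len(counts)):
        y = counts.iloc[i].to_numpy()
        if y.sum() == 0:
            stats_p[i] = (0.0, np.nan)
            continue
        stats_p[i] = profile_lrt(y, meta, sf, float(alphas[i]), design, reduced)

    out = pd.DataFrame(
        {"lrt_stat": stats_p[:, 0], "lrt_p": stats_p[:, 1]}, index=counts.index
    )
    out["lrt_padj"] = nb_glm.bh_adjust(out["lrt_p"].to_numpy())

    norm = counts / sf
    pvals, flags = posthoc_fraction_tests(norm, meta, design, posthoc_threshold)
    for f in design.fractions:
        out[f"p_f{f}"] = pvals[f]
    out = out.join(flags)
    out["profile_change"] = out["lrt_padj"] < padj_threshold
    return out


def ribosome_association_de(
    fcm: FractionCountMatrix,
    design: FractionDesign = FractionDesign(),
) -> pd.DataFrame:
    """Wald DE on fraction-summed counts (ribosome-associated mRNA)."""
    summed = fcm.sum_over_fractions()
    return nb_glm.differential_expression(
        summed.counts,
        summed.samples["condition"],
        reference=design.conditions[0],
    )


def riboload(
    fcm: FractionCountMatrix,
    design: FractionDesign = FractionDesign(),
    window: tuple[float, float] = (0.75, 1.25),
) -> pd.DataFrame:
    """Heavy-fraction read proportion per gene and condition.

    For each condition, size-factor-normalized counts are averaged over
    replicates per fraction; the statistic is the heavy-group share of
    the total across fractions.  ``fold`` is condition2 / condition1
    and ``changed`` is true when the fold falls outside the open
    ``window``.  Genes with zero total in either condition get NA.
    """
    meta = _fraction_samples(fcm, design)
    counts = fcm.counts[meta.index]
    sf = pd.Series(nb_glm.estimate_size_factors(counts), index=meta.index)
    norm = counts / sf
    heavy = set(design.heavy)

    shares = {}
    for cond in design.conditions:
        per_frac = []
        for f in design.fractions:
            ids = meta.index[(meta["fraction"] == f) & (meta["condition"] == cond)]
            per_frac.append(norm[ids].mean(axis=1))
        frac_means = pd.concat(per_frac, axis=1)
        frac_means.columns = list(design.fractions)
        total = frac_means.sum(axis=1)
        heavy_sum = frac_means[[f for f in design.fractions if f in heavy]].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            shares[cond] = (heavy_sum / total).where(total > 0)

    out = pd.DataFrame(index=counts.index)
    c1, c2 = design.conditions
    out[f"riboload_{c1}"] = shares[c1]
    out[f"riboload_{c2}"] = shares[c2]
    with np.errstate(invalid="ignore", divide="ignore"):
        out["fold"] = out[f"riboload_{c2}"] / out[f"riboload_{c1}"]
    lo, hi = window
    out["changed"] = ((out["fold"] <= lo) | (out["fold"] >= hi)).astype("boolean")
    out.loc[out["fold"].isna(), "changed"] = pd.NA
    return out
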