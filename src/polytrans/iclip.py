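"""Crosslink-site annotation, permutation peak enrichment and target tiers."""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from polytrans.readproc import CrosslinkSite
from polytrans.synthetic_data import GeneModel

__all__ = [
    "FEATURE_PRECEDENCE",
    "annotate_features",
    "peak_enrichment",
    "stratify_targets",
    "TIER_THRESHOLDS",
]

# mature-mRNA features first; anything unmatched is intergenic
FEATURE_PRECEDENCE = ("3UTR", "5UTR", "ORF", "ncRNA", "intron")

TIER_THRESHOLDS = (("50+", 50), ("25+", 25), ("10+", 10), ("1+", 1))


def _site_feature(site: CrosslinkSite, models: Sequence[GeneModel]) -> tuple[str, Optional[str]]:
    hits: dict[str, str] = {}
    for gm in models:
        if gm.contig != site.contig or gm.strand != site.strand:
            continue
        for s, e, kind in gm.features:
            if s <= site.position < e and kind not in hits:
                hits[kind] = gm.gene_id
    for kind in FEATURE_PRECEDENCE:
        if kind in hits:
            return kind, hits[kind]
    return "intergenic", None


def annotate_features(
    crosslinks: Iterable[CrosslinkSite],
    gene_models: Sequence[GeneModel],
) -> tuple[pd.DataFrame, pd.Series]:
    """Label each site with its genomic feature and host gene.

    Overlapping features resolve by :data:`FEATURE_PRECEDENCE`; sites
    outside every model are intergenic.  The second return value is the
    cDNA-count-weighted feature distribution (fractions summing to 1).
    """
    rows = []
    for site in crosslinks:
        kind, gene = _site_feature(site, gene_models)
        rows.append((site.contig, site.position, site.strand, site.count, kind, gene))
    table = pd.DataFrame(
        rows, columns=["contig", "position", "strand", "count", "feature", "gene"]
    )
    labels = list(FEATURE_PRECEDENCE) + ["intergenic"]
    if len(table):
        weights = table.groupby("feature")["count"].sum()
        dist = weights.reindex(labels, fill_value=0).astype(float)
        dist /= dist.sum()
    else:
        dist = pd.Series(0.0, index=labels)
    return table, dist


def _assign_regions(
    annotated: pd.DataFrame,
    gene_models: Sequence[GeneModel],
    intergenic_segment: int,
) -> pd.DataFrame:
    by_id = {gm.gene_id: gm for gm in gene_models}
    region_id, lo, hi = [], [], []
    for _, row in annotated.iterrows():
        gm = by_id.get(row["gene"])
        if gm is not None:
            region_id.append(row["gene"])
            lo.append(gm.start)
            hi.append(gm.end)
        else:
            seg = int(row["position"]) // intergenic_segment
            region_id.append(f"{row['contig']}:seg{seg}:{row['strand']}")
            lo.append(seg * intergenic_segment)
            hi.append((seg + 1) * intergenic_segment)
    out = annotated.copy()
    out["region"] = region_id
    out["region_start"] = lo
    out["region_end"] = hi
    return out


def _window_scores(positions: np.ndarray, counts: np.ndarray, half_window: int) -> np.ndarray:
    order = np.argsort(positions)
    pos, cnt = positions[order], counts[order]
    csum = np.concatenate([[0], np.cumsum(cnt)])
    left = np.searchsorted(pos, positions - half_window, side="left")
    right = np.searchsorted(pos, positions + half_window, side="right")
    return csum[right] - csum[left]


def peak_enrichment(
    crosslinks: Iterable[CrosslinkSite],
    gene_models: Sequence[GeneModel],
    half_window: int = 15,
    n_perm: int = 100,
    fdr_cut: float = 0.05,
    seed: Optional[int] = None,
    intergenic_segment: int = 10_000,
) -> pd.DataFrame:
    """Permutation enrichment of crosslink sites within host regions.

    Each site's score sums unique-cDNA counts within +-``half_window``
    nt.  The null re-places the region's crosslink events uniformly
    within the region ``n_perm`` times; FDR at score s is the mean
    permuted number of sites scoring >= s over the observed number,
    clipped to [0, 1] and made monotone non-increasing in score.
    Returns one row per site with its window, score, FDR and a
    ``significant`` flag (FDR < ``fdr_cut``).
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be a positive integer")
    rng = np.random.default_rng(seed)
    annotated, _ = annotate_features(crosslinks, gene_models)
    if annotated.empty:
        return pd.DataFrame(
            columns=[
                "contig", "center", "strand", "start", "end",
                "count", "score", "fdr", "significant", "region",
            ]
        )
    annotated = _assign_regions(annotated, gene_models, intergenic_segment)

    results = []
    for region, grp in annotated.groupby("region", sort=True):
        positions = grp["position"].to_numpy()
        counts = grp["count"].to_numpy()
        n_events = int(counts.sum())
        lo = int(grp["region_start"].iloc[0])
        hi = int(grp["region_end"].iloc[0])
        scores = _window_scores(positions, counts, half_window)

        levels = np.unique(scores)  # ascending
        obs_ge = np.array([(scores >= s).sum() for s in levels], dtype=float)
        perm_ge = np.zeros_like(obs_ge)
        for _ in range(n_perm):
            placed = rng.integers(lo, hi, size=n_events)
            ppos, pcnt = np.unique(placed, return_counts=True)
            pscores = _window_scores(ppos, pcnt, half_window)
            perm_ge += np.array([(pscores >= s).sum() for s in levels], dtype=float)
        fdr_levels = np.clip(perm_ge / n_perm / obs_ge, 0.0, 1.0)
        # enforce monotone non-increasing FDR with growing score
        for i in range(len(levels) - 2, -1, -1):
            fdr_levels[i] = max(fdr_levels[i], fdr_levels[i + 1])
        level_of = {s: f for s, f in zip(levels, fdr_levels)}

        for (_, row), score in zip(grp.iterrows(), scores):
            fdr = level_of[score]
            results.append(
                (
                    row["contig"],
                    int(row["position"]),
                    row["strand"],
                    int(row["position"]) - half_window,
                    int(row["position"]) + half_window + 1,
                    int(row["count"]),
                    int(score),
                    float(fdr),
                    bool(fdr < fdr_cut),
                    region,
                )
            )
    out = pd.DataFrame(
        results,
        columns=[
            "contig", "center", "strand", "start", "end",
            "count", "score", "fdr", "significant", "region",
        ],
    )
    return out.sort_values(["contig", "center", "strand"]).reset_index(drop=True)


def stratify_targets(
    annotated_sites: pd.DataFrame,
    gene_ids: Optional[Iterable[str]] = None,
    target_cut: int = 50,
) -> pd.DataFrame:
    """Tier genes by their total 3'UTR unique-cDNA count.

    ``annotated_sites`` is the output of :func:`annotate_features`
    (optionally filtered to significant sites).  Tiers are nested
    (``tier_1plus`` .. ``tier_50plus``); the ``tier`` label is the
    highest attained and ``is_target`` requires a total strictly above
    ``target_cut``.
    """
    utr = annotated_sites[annotated_sites["feature"] == "3UTR"]
    totals = utr.groupby("gene")["count"].sum()
    if gene_ids is not None:
        totals = totals.reindex(list(gene_ids), fill_value=0)
    totals = totals.astype(int)

    out = pd.DataFrame({"utr3_count": totals})
    out.index.name = "gene"
    tier = pd.Series("0", index=out.index)
    for label, cut in TIER_THRESHOLDS:
        col = f"tier_{label.replace('+', 'plus')}"
        out[col] = out["utr3_count"] >= cut
        tier = tier.where(~((out["utr3_count"] >= cut) & (tier == "0")), label)
    out["tier"] = tier
    out["is_target"] = out["utr3_count"] > target_cut
    return out
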