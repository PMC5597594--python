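"""Gene-by-sample count matrices with fraction/condition annotations."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TOTAL = "total"


@dataclass
class FractionCountMatrix:
    """Integer count matrix (genes x samples) plus per-sample metadata.

    ``samples`` is indexed by sample id and carries the columns
    ``condition``, ``replicate`` and ``fraction``.  ``fraction`` holds the
    gradient fraction label (an integer) for polysome libraries or the
    string ``"total"`` for whole-lysate libraries.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.samples.index):
            missing = set(self.counts.columns) ^ set(self.samples.index)
            raise ValueError(
                f"count columns and sample sheet disagree on ids: {sorted(missing)}"
            )
        for col in ("condition", "replicate", "fraction"):
            if col not in self.samples.columns:
                raise ValueError(f"sample sheet misses required column {col!r}")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise ValueError("count matrix contains non-integer values")
            self.counts = self.counts.astype(np.int64)
            values = self.counts.to_numpy()
        if (values < 0).any():
            gene, sample = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative count at gene {self.counts.index[gene]!r}, "
                f"sample {self.counts.columns[sample]!r}"
            )

    # -- selection ---------------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def conditions(self) -> list:
        return sorted(self.samples["condition"].unique())

    @property
    def fractions(self) -> list[int]:
        labels = [f for f in self.samples["fraction"].unique() if f != TOTAL]
        return sorted(int(f) for f in labels)

    def select(self, condition=None, fraction=None, replicate=None) -> "FractionCountMatrix":
        mask = pd.Series(True, index=self.samples.index)
        if condition is not None:
            mask &= self.samples["condition"] == condition
        if fraction is not None:
            mask &= self.samples["fraction"].astype(str) == str(fraction)
        if replicate is not None:
            mask &= self.samples["replicate"] == replicate
        ids = self.samples.index[mask]
        return FractionCountMatrix(self.counts[ids], self.samples.loc[ids])

    def sum_over_fractions(self) -> "FractionCountMatrix":
        """Collapse fraction libraries to one column per (condition, replicate)."""
        frac = self.samples[self.samples["fraction"] != TOTAL]
        groups = frac.groupby(["condition", "replicate"], sort=True)
        cols, meta = {}, []
        for (cond, rep), sub in groups:
            name = f"{cond}_r{rep}"
            cols[name] = self.counts[sub.index].sum(axis=1)
            meta.append((name, cond, rep, TOTAL))
        counts = pd.DataFrame(cols, index=self.counts.index)
        samples = pd.DataFrame(
            meta, columns=["sample", "condition", "replicate", "fraction"]
        ).set_index("sample")
        return FractionCountMatrix(counts, samples)

    def normalized(self, size_factors: pd.Series) -> pd.DataFrame:
        return self.counts / size_factors.reindex(self.counts.columns)
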