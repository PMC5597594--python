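"""Synthetic inputs with known ground truth.

Generates NB-distributed fraction/total count matrices, 3'-end reads
with sample barcodes, UMIs and poly(A) tails, and CLIP reads anchored
one base downstream of planted crosslink sites.  Every stochastic
choice is recorded so recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from polytrans.matrix import TOTAL, FractionCountMatrix
from polytrans.readproc import RawRead

__all__ = [
    "SimConfig",
    "SimTruth",
    "GeneModel",
    "GENE_CLASSES",
    "simulate_polysome_counts",
    "simulate_reads_3prime",
    "simulate_iclip_reads",
    "make_gene_models",
    "TIER_LAMBDAS",
]

GENE_CLASSES = ("neither", "abundance_only", "translation_only", "both")

DEFAULT_CLASS_PROPORTIONS = {
    "neither": 0.70,
    "abundance_only": 0.10,
    "translation_only": 0.10,
    "both": 0.10,
}

# default expected unique-cDNA yield per target tier
TIER_LAMBDAS = {"0": 0.0, "1+": 4.0, "10+": 16.0, "25+": 35.0, "50+": 90.0}


@dataclass(frozen=True)
class SimConfig:
    n_genes: int
    n_replicates: int = 4
    fractions: tuple[int, ...] = tuple(range(4, 17))
    conditions: tuple[str, str] = ("L", "LE")
    base_mean_log: tuple[float, float] = (np.log(200.0), 1.0)
    dispersion: float | tuple[float, float] = 0.05
    class_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS)
    )
    abundance_effect: float = 2.0
    translation_effect: float = 0.3
    depth: float = 1.0
    size_factor_sigma: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_replicates < 1:
            raise ValueError("n_genes and n_replicates must be positive")
        if any(b <= a for a, b in zip(self.fractions, self.fractions[1:])):
            raise ValueError("fraction labels must be strictly increasing")
        total = sum(self.class_proportions.get(c, 0.0) for c in GENE_CLASSES)
        if abs(total - 1.0) > 1e-9 or set(self.class_proportions) - set(GENE_CLASSES):
            raise ValueError(
                f"class_proportions must cover {GENE_CLASSES} and sum to 1"
            )
        if self.abundance_effect <= 0 or self.translation_effect < 0:
            raise ValueError("effects must be positive")
        if not 0 <= self.translation_effect < 1:
            raise ValueError("translation_effect is a mass fraction in [0, 1)")


@dataclass
class SimTruth:
    """Ground truth emitted by the generator.

    ``genes`` has one row per gene: class label, realized abundance fold
    and profile-shift magnitude, and the per-condition fraction profiles
    (simplex weights, one column per fraction per condition).
    ``size_factors`` records the per-sample depth multipliers.
    """

    genes: pd.DataFrame
    size_factors: pd.Series


@dataclass(frozen=True)
class GeneModel:
    """Gene annotation: ordered, non-overlapping typed intervals
    (0-based half-open) on one contig/strand."""

    gene_id: str
    contig: str
    strand: str
    features: tuple[tuple[int, int, str], ...]

    def __post_init__(self) -> None:
        spans = sorted((s, e) for s, e, _ in self.features)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError(f"{self.gene_id}: overlapping feature intervals")
        for s, e, t in self.features:
            if e <= s:
                raise ValueError(f"{self.gene_id}: empty interval ({s}, {e})")
            if t not in {"5UTR", "ORF", "3UTR", "intron", "ncRNA"}:
                raise ValueError(f"{self.gene_id}: unknown feature type {t!r}")

    @property
    def start(self) -> int:
        return min(s for s, _, _ in self.features)

    @property
    def end(self) -> int:
        return max(e for _, e, _ in self.features)

    def feature_span(self, kind: str) -> Optional[tuple[int, int]]:
        spans = [(s, e) for s, e, t in self.features if t == kind]
        if not spans:
            return None
        return min(s for s, _ in spans), max(e for _, e in spans)


# ---------------------------------------------------------------------------
# count simulation
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    mu = np.asarray(mu, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), mu.shape)
    out = np.empty(mu.shape, dtype=np.int64)
    poisson = alpha < 1e-12
    if poisson.any():
        out[poisson] = rng.poisson(mu[poisson])
    if (~poisson).any():
        r = 1.0 / alpha[~poisson]
        p = r / (r + mu[~poisson])
        out[~poisson] = rng.negative_binomial(r, p)
    return out


def _baseline_profiles(rng: np.random.Generator, n_genes: int, n_frac: int) -> np.ndarray:
    # unimodal template peaking in the light-polysome region, Dirichlet noise
    x = np.arange(n_frac)
    template = np.exp(-0.5 * ((x - (n_frac - 1) / 2.2) / (n_frac / 4.0)) ** 2)
    template /= template.sum()
    return rng.dirichlet(template * 60.0, size=n_genes)


def _shift_mass(profile: np.ndarray, mono: np.ndarray, heavy: np.ndarray, effect: float) -> np.ndarray:
    """Move ``effect`` of the monosome-group mass onto the heavy group."""
    shifted = profile.copy()
    moved = effect * profile[mono].sum()
    shifted[mono] *= 1.0 - effect
    hw = profile[heavy]
    if hw.sum() > 0:
        shifted[heavy] += moved * hw / hw.sum()
    else:
        shifted[heavy] += moved / heavy.sum()
    return shifted / shifted.sum()


def simulate_polysome_counts(
    config: SimConfig,
) -> tuple[FractionCountMatrix, FractionCountMatrix, SimTruth]:
    """Simulate fraction-resolved and total count matrices plus truth.

    Fraction counts are NB with mean
    ``size_factor * depth * abundance(gene, condition) * profile(gene,
    condition, fraction)``; totals use the abundance alone.  Both
    matrices and the truth are deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    g, nf, nr = config.n_genes, len(config.fractions), config.n_replicates
    cond_l, cond_e = config.conditions
    genes = [f"gene{i:05d}" for i in range(g)]

    classes = rng.choice(
        GENE_CLASSES,
        size=g,
        p=[config.class_proportions.get(c, 0.0) for c in GENE_CLASSES],
    )
    meanlog, sdlog = config.base_mean_log
    abundance = rng.lognormal(meanlog, sdlog, size=g)
    if isinstance(config.dispersion, tuple):
        shape, scale = config.dispersion
        alphas = rng.gamma(shape, scale, size=g)
    else:
        alphas = np.full(g, float(config.dispersion))

    has_ab = np.isin(classes, ("abundance_only", "both"))
    has_tr = np.isin(classes, ("translation_only", "both"))
    ab_fold = np.where(has_ab, config.abundance_effect, 1.0)
    tr_shift = np.where(has_tr, config.translation_effect, 0.0)
    # the recorded class reflects the *realized* effects: unit effect
    # magnitudes demote genes to "neither"
    real_ab = ab_fold != 1.0
    real_tr = tr_shift > 0.0
    classes = np.where(
        real_ab & real_tr, "both",
        np.where(real_ab, "abundance_only",
                 np.where(real_tr, "translation_only", "neither")),
    )

    prof_l = _baseline_profiles(rng, g, nf)
    labels = np.array(config.fractions)
    mono = labels <= 7
    heavy = labels >= 11
    prof_e = prof_l.copy()
    for i in np.where(tr_shift > 0)[0]:
        prof_e[i] = _shift_mass(prof_l[i], mono, heavy, tr_shift[i])

    # fraction samples
    sample_ids, meta = [], []
    for cond in (cond_l, cond_e):
        for f in config.fractions:
            for r in range(1, nr + 1):
                sid = f"{cond}_f{f:02d}_r{r}"
                sample_ids.append(sid)
                meta.append((sid, cond, r, f))
    sf = pd.Series(
        rng.lognormal(0.0, config.size_factor_sigma, size=len(sample_ids)),
        index=sample_ids,
    )

    mu = np.empty((g, len(sample_ids)))
    for j, (sid, cond, r, f) in enumerate(meta):
        fi = list(config.fractions).index(f)
        prof = prof_e if cond == cond_e else prof_l
        ab = abundance * (ab_fold if cond == cond_e else 1.0)
        mu[:, j] = config.depth * sf[sid] * ab * prof[:, fi]
    counts = _nb_draw(rng, mu, alphas[:, None])
    fcm = FractionCountMatrix(
        pd.DataFrame(counts, index=genes, columns=sample_ids),
        pd.DataFrame(meta, columns=["sample", "condition", "replicate", "fraction"])
        .set_index("sample"),
    )

    # total samples
    tot_ids, tot_meta = [], []
    for cond in (cond_l, cond_e):
        for r in range(1, nr + 1):
            sid = f"{cond}_total_r{r}"
            tot_ids.append(sid)
            tot_meta.append((sid, cond, r, TOTAL))
    tot_sf = pd.Series(
        rng.lognormal(0.0, config.size_factor_sigma, size=len(tot_ids)), index=tot_ids
    )
    mu_tot = np.empty((g, len(tot_ids)))
    for j, (sid, cond, r, _) in enumerate(tot_meta):
        ab = abundance * (ab_fold if cond == cond_e else 1.0)
        mu_tot[:, j] = config.depth * tot_sf[sid] * ab
    counts_tot = _nb_draw(rng, mu_tot, alphas[:, None])
    fcm_tot = FractionCountMatrix(
        pd.DataFrame(counts_tot, index=genes, columns=tot_ids),
        pd.DataFrame(tot_meta, columns=["sample", "condition", "replicate", "fraction"])
        .set_index("sample"),
    )

    truth_genes = pd.DataFrame(
        {
            "gene": genes,
            "class": classes,
            "abundance_fold": ab_fold,
            "profile_shift": tr_shift,
            "base_abundance": abundance,
            "dispersion": alphas,
        }
    ).set_index("gene")
    for fi, f in enumerate(config.fractions):
        truth_genes[f"profile_{cond_l}_f{f}"] = prof_l[:, fi]
        truth_genes[f"profile_{cond_e}_f{f}"] = prof_e[:, fi]
    truth = SimTruth(truth_genes, pd.concat([sf, tot_sf]))
    return fcm, fcm_tot, truth


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

def make_gene_models(
    n_genes: int,
    rng: np.random.Generator,
    utr5_len: int = 100,
    orf_len: int = 600,
    utr3_len: int = 400,
    spacing: int = 2000,
    contig: str = "chrS",
    minus_fraction: float = 0.0,
) -> list[GeneModel]:
    """Lay out simple single-contig gene models with 5UTR/ORF/3UTR."""
    models = []
    pos = 1000
    for i in range(n_genes):
        strand = "-" if rng.random() < minus_fraction else "+"
        s5 = (pos, pos + utr5_len, "5UTR")
        orf = (pos + utr5_len, pos + utr5_len + orf_len, "ORF")
        s3 = (pos + utr5_len + orf_len, pos + utr5_len + orf_len + utr3_len, "3UTR")
        feats = (s5, orf, s3) if strand == "+" else (
            (s5[0], s5[1], "3UTR"),
            orf,
            (s3[0], s3[1], "5UTR"),
        )
        models.append(GeneModel(f"gene{i:05d}", contig, strand, feats))
        pos += utr5_len + orf_len + utr3_len + spacing
    return models


# ---------------------------------------------------------------------------
# 3'-end reads
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int, exclude_a_tail: bool = False) -> str:
    seq = "".join(rng.choice(_BASES, size=length))
    return seq


def _fresh_umi(rng: np.random.Generator, length: int, used: set, key) -> str:
    while True:
        umi = "".join(rng.choice(_BASES, size=length))
        if (key, umi) not in used:
            used.add((key, umi))
            return umi


def simulate_reads_3prime(
    config: SimConfig,
    gene_models: Sequence[GeneModel],
    sample_barcodes: Mapping[str, str],
    molecules_per_gene: float = 5.0,
    body_length: int = 40,
    tail_length: int = 20,
    tail_purity: float = 1.0,
    duplication_rate: float = 0.0,
) -> tuple[list[RawRead], pd.DataFrame]:
    """Simulate barcoded 3'-end reads with poly(A) tails.

    Each molecule yields a read whose barcode read is the sample's
    5 known bases plus a 5-base UMI, whose body ends at the gene's
    3'UTR end, and whose tail is ``tail_length`` A's with per-base
    purity ``tail_purity``.  With probability ``duplication_rate`` a
    molecule is emitted twice (a PCR duplicate).  UMIs are unique per
    (sample, gene, position, length), so deduplication can recover the
    molecule count exactly.  Returns the reads and a truth table with
    one row per read.
    """
    rng = np.random.default_rng(config.seed + 1)
    reads: list[RawRead] = []
    rows = []
    used: set = set()
    idx = 0
    for sample, code in sorted(sample_barcodes.items()):
        if len(code) != 5:
            raise ValueError("polyribo known barcodes must have 5 bases")
        for gm in gene_models:
            span = gm.feature_span("3UTR")
            if span is None:
                raise ValueError(f"{gm.gene_id} has no 3'UTR")
            n_mol = rng.poisson(molecules_per_gene)
            for _ in range(n_mol):
                # 3' end anchored at the UTR end, small jitter upstream
                end = span[1] - int(rng.integers(0, 10))
                start = max(span[0], end - body_length)
                length = end - start
                umi = _fresh_umi(rng, 5, used, (sample, gm.gene_id, start, length))
                body = _random_seq(rng, length)
                if tail_length > 0:
                    tail = "".join(
                        "A" if rng.random() < tail_purity else str(rng.choice(_BASES[1:]))
                        for _ in range(tail_length)
                    )
                else:
                    tail = ""
                seq = body + tail
                n_copies = 2 if rng.random() < duplication_rate else 1
                for copy in range(n_copies):
                    rid = f"r3p_{idx:07d}"
                    idx += 1
                    reads.append(
                        RawRead(rid, seq, "I" * len(seq), barcode_read=code + umi)
                    )
                    rows.append(
                        (
                            rid,
                            sample,
                            gm.gene_id,
                            gm.contig,
                            start,
                            length,
                            gm.strand,
                            umi,
                            copy > 0,
                        )
                    )
    truth = pd.DataFrame(
        rows,
        columns=[
            "read_id",
            "sample",
            "gene",
            "contig",
            "start",
            "length",
            "strand",
            "umi",
            "is_duplicate",
        ],
    )
    return reads, truth


# ---------------------------------------------------------------------------
# CLIP reads
# ---------------------------------------------------------------------------

def simulate_iclip_reads(
    config: SimConfig,
    gene_models: Sequence[GeneModel],
    target_tiers: Mapping[str, str],
    sample_barcodes: Mapping[str, str],
    tier_lambdas: Mapping[str, float] = TIER_LAMBDAS,
    site_window: int = 30,
    n_sites_per_gene: int = 3,
    read_length: int = 35,
    duplication_rate: float = 0.0,
) -> tuple[list[RawRead], pd.DataFrame, pd.DataFrame]:
    """Simulate CLIP reads anchored downstream of planted crosslink sites.

    Crosslink events concentrate on ``n_sites_per_gene`` positions
    inside a U-rich window at the 3'UTR; each event's read starts one
    base downstream of its site and carries a 3 known + 4 UMI 5'
    barcode and an ``AT`` 3' barcode.  Returns (reads, per-read truth,
    true site table).
    """
    rng = np.random.default_rng(config.seed + 2)
    by_gene = {gm.gene_id: gm for gm in gene_models}
    reads: list[RawRead] = []
    rows, site_rows = [], []
    used: set = set()
    idx = 0
    samples = sorted(sample_barcodes.items())
    for gene_id, tier in sorted(target_tiers.items()):
        gm = by_gene[gene_id]
        lam = float(tier_lambdas[tier])
        span = gm.feature_span("3UTR")
        if span is None:
            raise ValueError(f"{gene_id} has no 3'UTR")
        lo = max(span[0] + 1, span[1] - site_window)
        sites = sorted(set(int(p) for p in rng.integers(lo, span[1], n_sites_per_gene)))
        n_events = rng.poisson(lam)
        if n_events == 0:
            continue
        for s in sites:
            site_rows.append((gene_id, gm.contig, s, gm.strand))
        for _ in range(n_events):
            site = int(rng.choice(sites))
            sample, code = samples[int(rng.integers(0, len(samples)))]
            if gm.strand == "+":
                start = site + 1
            else:
                # read 5' end one base 5' of the site in transcript orientation
                five_prime = site - 1
                start = five_prime - (read_length - 1)
            umi = _fresh_umi(rng, 4, used, (sample, gm.contig, start, read_length))
            body = _random_seq(rng, read_length)
            seq = code + umi + body + "AT"
            n_copies = 2 if rng.random() < duplication_rate else 1
            for copy in range(n_copies):
                rid = f"clip_{idx:07d}"
                idx += 1
                reads.append(RawRead(rid, seq, "I" * len(seq)))
                rows.append(
                    (
                        rid,
                        sample,
                        gene_id,
                        gm.contig,
                        start,
                        read_length,
                        gm.strand,
                        umi,
                        site,
                        copy > 0,
                    )
                )
    truth = pd.DataFrame(
        rows,
        columns=[
            "read_id",
            "sample",
            "gene",
            "contig",
            "start",
            "length",
            "strand",
            "umi",
            "site",
            "is_duplicate",
        ],
    )
    true_sites = pd.DataFrame(
        site_rows, columns=["gene", "contig", "position", "strand"]
    )
    return reads, truth, true_sites
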