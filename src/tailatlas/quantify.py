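"""Expression quantification, differential calls and tail-length histograms.

Because maternal mRNA is globally degraded during oocyte maturation,
total-read normalization is misleading; read counts are instead normalized
by the number of reads mapped to protein-coding genes on the mitochondrial
genome, which are untouched by cytoplasmic deadenylases.  Differential
expression between two samples is a plain twofold cutoff on MT-normalized
counts (with an optional two-tailed t-test across replicates), and
tail-length histograms use 1 nt bins with the terminal bin absorbing all
longer tails.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_SCALE = 1000.0
DEFAULT_PSEUDOCOUNT = 0.5
DEFAULT_FOLD = 2.0


class MTNormalizationError(ValueError):
    """A sample has zero reads on MT protein-coding genes."""


@dataclass
class ExpressionTable:
    """Raw and MT-normalized counts, genes x samples."""

    raw: pd.DataFrame  # genes x samples, integer counts
    mt_counts: pd.Series  # per sample
    scale: float
    normalized: pd.DataFrame

    def log2_normalized(self, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.DataFrame:
        return np.log2(self.normalized + pseudocount)


def counts_matrix(gene_counts: pd.DataFrame) -> pd.DataFrame:
    """Pivot a (gene, sample, count) long table into genes x samples."""
    return (
        gene_counts.pivot_table(index="gene", columns="sample", values="count", fill_value=0)
        .astype(int)
        .rename_axis(index="gene", columns="sample")
    )


def mt_normalize(counts: pd.DataFrame, mt_genes, scale: float = DEFAULT_SCALE) -> ExpressionTable:
    """Normalize per-sample counts by MT protein-coding reads.

    normalized = raw / MT-count * scale.  Raises when a sample has no MT
    reads — the normalization is undefined there.
    """
    mt_genes = [g for g in mt_genes if g in counts.index]
    mt = counts.loc[mt_genes].sum(axis=0).astype(float)
    zero = mt[mt == 0]
    if not zero.empty or not mt_genes:
        bad = ", ".join(zero.index) if not zero.empty else "all samples"
        raise MTNormalizationError(f"no MT protein-coding reads in: {bad}")
    normalized = counts.div(mt, axis=1) * scale
    return ExpressionTable(raw=counts, mt_counts=mt, scale=scale, normalized=normalized)


@dataclass
class DECall:
    gene: str
    fold_change: float  # (A + pc) / (B + pc) on normalized counts
    direction: str  # up | down | unchanged
    p_value: float | None = None
    q_value: float | None = None


def call_de(
    table: ExpressionTable,
    samples_a,
    samples_b,
    fold: float = DEFAULT_FOLD,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Twofold-rule differential expression of condition A vs condition B.

    ``samples_a``/``samples_b`` are sample names (replicates averaged on the
    normalized scale).  Genes with at least one raw read in either condition
    are included.  With >= 2 replicates per side a two-tailed Welch t-test on
    log2 normalized counts is reported alongside (Benjamini-Hochberg
    adjusted), but the call itself is the fold cutoff.
    """
    samples_a = list(np.atleast_1d(samples_a))
    samples_b = list(np.atleast_1d(samples_b))
    raw_any = (table.raw[samples_a].sum(axis=1) >= 1) | (table.raw[samples_b].sum(axis=1) >= 1)
    norm = table.normalized.loc[raw_any]
    mean_a = norm[samples_a].mean(axis=1)
    mean_b = norm[samples_b].mean(axis=1)
    fc = (mean_a + pseudocount) / (mean_b + pseudocount)
    direction = pd.Series("unchanged", index=fc.index)
    direction[fc >= fold] = "up"
    direction[fc <= 1.0 / fold] = "down"
    out = pd.DataFrame(
        {"gene": fc.index, "fold_change": fc.values, "direction": direction.values}
    )
    if len(samples_a) >= 2 and len(samples_b) >= 2:
        log = np.log2(norm + pseudocount)
        t, p = stats.ttest_ind(
            log[samples_a], log[samples_b], axis=1, equal_var=False
        )
        out["p_value"] = p
        out["q_value"] = false_discovery_rate(p)
    return out


def false_discovery_rate(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaN inputs stay NaN)."""
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.size, np.nan)
    valid = np.flatnonzero(~np.isnan(p))
    n = valid.size
    if n == 0:
        return out
    pv = p[valid]
    order = np.argsort(pv)
    ranked = pv[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.empty(n)
    adjusted[order] = np.minimum(ranked, 1.0)
    out[valid] = adjusted
    return out


@dataclass
class TailHistogram:
    """1 nt binned tail-length histogram with a capped terminal bin."""

    bins: np.ndarray  # 1..cap
    counts: np.ndarray  # raw transcript counts per bin
    heights: np.ndarray  # counts / normalizer
    cap: int
    mode: str  # "mt" | "total"
    normalizer: float

    def window_mass(self, lo: int, hi: int) -> float:
        """Summed normalized height over bins lo..hi inclusive."""
        sel = (self.bins >= lo) & (self.bins <= hi)
        return float(self.heights[sel].sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin": self.bins, "count": self.counts, "height": self.heights,
             "cap": self.cap, "mode": self.mode}
        )


def tail_histogram(
    tail_lengths,
    cap: int = 250,
    mode: str = "mt",
    mt_count: float | None = None,
) -> TailHistogram:
    """Histogram of tail lengths (>= 1 nt included; > cap pooled into the cap bin).

    ``mode="mt"`` divides bin counts by ``mt_count`` (reads on MT
    protein-coding genes); ``mode="total"`` divides by the number of included
    transcripts.
    """
    lengths = np.asarray(list(tail_lengths), dtype=int)
    lengths = lengths[lengths >= 1]
    capped = np.minimum(lengths, cap)
    counts = np.bincount(capped, minlength=cap + 1)[1:]
    if mode == "mt":
        if mt_count is None or mt_count <= 0:
            raise MTNormalizationError("mt mode requires a positive MT read count")
        normalizer = float(mt_count)
    elif mode == "total":
        normalizer = float(max(len(lengths), 1))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return TailHistogram(
        bins=np.arange(1, cap + 1),
        counts=counts,
        heights=counts / normalizer,
        cap=cap,
        mode=mode,
        normalizer=normalizer,
    )


def intron_rate(frame: pd.DataFrame) -> pd.Series:
    """Fraction of assigned reads that contain intronic sequence, per sample.

    New transcription would show up as intron-containing reads; during
    oocyte maturation transcription is silent, so this rate should stay flat
    across conditions.
    """
    from .assign import AMBIGUOUS, UNASSIGNED

    ok = frame[~frame.gene.isin([UNASSIGNED, AMBIGUOUS])]
    return ok.groupby("sample").intron_containing.mean()
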