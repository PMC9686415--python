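"""Methylome landscape statistics.

Three views of a methylome:

* level histograms — the fraction of methylated cytosines whose level falls
  in each 10%-wide bin, per context;
* CpG-density x methylation matrices — 200 bp tiling windows placed on a
  grid of CpG-dinucleotide count (from sequence) versus mean CG methylation
  (from calls), with a median methylation trace per density column;
* metagene profiles — mean methylation across the seven length-normalized
  gene features (upstream, first exon, first intron, internal exons,
  internal introns, last exon, downstream), with a 5-bin moving average.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GENE_FEATURES, AnnotationSet

N_LEVEL_BINS = 10


@dataclass
class LevelHistogram:
    """Fraction of methylated cytosines per 10%-wide level bin."""

    context: str
    fractions: np.ndarray          # length 10; sums to 1 when any mC exists
    n_mc: int
    bin_edges: np.ndarray = field(
        default_factory=lambda: np.linspace(0.0, 1.0, N_LEVEL_BINS + 1)
    )


def site_levels(
    records: pd.DataFrame, context: str | None = None, min_total: int = 4
) -> pd.DataFrame:
    """Covered sites with a ``level`` column; optionally one context."""
    df = records[records["total"] >= min_total]
    if context is not None:
        df = df[df["context"] == context]
    df = df.copy()
    df["level"] = df["meth"] / df["total"]
    return df


def level_bin(levels: np.ndarray) -> np.ndarray:
    """Bin index floor(level * 10); level 1.0 joins the top bin."""
    return np.minimum((np.asarray(levels) * N_LEVEL_BINS).astype(int),
                      N_LEVEL_BINS - 1)


def level_histogram(
    records: pd.DataFrame, context: str, min_total: int = 4
) -> LevelHistogram:
    """Distribution of per-site methylation levels among methylated sites."""
    df = site_levels(records, context, min_total)
    df = df[df["meth"] >= 1]
    counts = np.bincount(level_bin(df["level"].to_numpy()), minlength=N_LEVEL_BINS)
    n = int(counts.sum())
    fractions = counts / n if n else counts.astype(float)
    return LevelHistogram(context=context, fractions=fractions, n_mc=n)


# ---------------------------------------------------------------------------
# CpG density x methylation matrix


@dataclass
class DensityMethylationMatrix:
    """Tiling-window counts on a (level bin x CpG density) grid."""

    counts: np.ndarray             # shape (10 level bins, max_density + 1)
    column_medians: np.ndarray     # median level per density column (NaN if empty)
    density_marginal: np.ndarray
    level_marginal: np.ndarray
    window_bp: int
    n_windows: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=[f"[{i/10:.1f},{(i+1)/10:.1f})" for i in range(N_LEVEL_BINS)],
            columns=np.arange(self.counts.shape[1]),
        )


def cpg_positions(sequence: str) -> np.ndarray:
    """0-based start positions of CpG dinucleotides on the forward strand."""
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))


def _window_mask(starts: np.ndarray, window_bp: int, mask, chrom: str) -> np.ndarray:
    """Which windows intersect the interval mask (>=1 bp overlap)."""
    if mask is None:
        return np.ones(len(starts), dtype=bool)
    keep = np.zeros(len(starts), dtype=bool)
    for c, s, e in mask:
        if c == chrom:
            keep |= (starts < e) & (starts + window_bp > s)
    return keep


def density_meth_matrix(
    sequences: dict[str, str],
    records: pd.DataFrame,
    window_bp: int = 200,
    min_total: int = 4,
    max_density: int | None = None,
    mask=None,
) -> DensityMethylationMatrix:
    """CpG-density versus methylation matrix over non-overlapping tiles.

    Each window contributes its sequence CpG-dinucleotide count (x) and the
    unweighted mean level of its covered CG-context sites (y); windows with
    no covered CpG site are excluded.  ``mask``, a list of (chrom, start,
    end) intervals, restricts the analysis to windows intersecting a genomic
    feature track.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    sites = site_levels(records, "CG", min_total)
    dens_list, lvl_list = [], []
    for chrom, seq in sequences.items():
        n_win = len(seq) // window_bp
        if n_win == 0:
            continue
        starts = np.arange(n_win) * window_bp
        cpg = cpg_positions(seq)
        cpg = cpg[cpg // window_bp < n_win]
        density = np.bincount(cpg // window_bp, minlength=n_win)

        sub = sites[sites["chrom"] == chrom]
        w = sub["pos"].to_numpy(dtype=np.int64) // window_bp
        ok = w < n_win
        w = w[ok]
        lv = sub["level"].to_numpy(dtype=float)[ok]
        lsum = np.bincount(w, weights=lv, minlength=n_win)
        lcnt = np.bincount(w, minlength=n_win)

        keep = (lcnt > 0) & _window_mask(starts, window_bp, mask, chrom)
        dens_list.append(density[keep])
        lvl_list.append(lsum[keep] / lcnt[keep])

    density = np.concatenate(dens_list) if dens_list else np.zeros(0, int)
    level = np.concatenate(lvl_list) if lvl_list else np.zeros(0)
    if max_density is None:
        max_density = int(density.max()) if len(density) else 0
    dens_col = np.minimum(density, max_density)
    lbin = level_bin(level)
    counts = np.zeros((N_LEVEL_BINS, max_density + 1), dtype=int)
    np.add.at(counts, (lbin, dens_col), 1)
    medians = np.full(max_density + 1, np.nan)
    for d in np.unique(dens_col):
        medians[d] = float(np.median(level[dens_col == d]))
    return DensityMethylationMatrix(
        counts=counts,
        column_medians=medians,
        density_marginal=counts.sum(axis=0),
        level_marginal=counts.sum(axis=1),
        window_bp=window_bp,
        n_windows=int(len(level)),
    )


# ---------------------------------------------------------------------------
# metagene profile


@dataclass
class MetageneProfile:
    """Per-context, per-feature bin series of mean methylation level."""

    bins_per_feature: int
    features: tuple = GENE_FEATURES
    means: dict = field(default_factory=dict)      # (context, feature) -> array
    smoothed: dict = field(default_factory=dict)   # 5-bin moving average
    n_sites: dict = field(default_factory=dict)
    n_genes_per_feature: dict = field(default_factory=dict)

    def series(self, context: str, smoothed: bool = True) -> np.ndarray:
        src = self.smoothed if smoothed else self.means
        return np.concatenate([src[(context, f)] for f in self.features])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (ctx, feat), m in self.means.items():
            sm = self.smoothed[(ctx, feat)]
            for b in range(len(m)):
                rows.append(
                    {
                        "context": ctx, "feature": feat, "bin": b,
                        "mean_level": m[b], "smoothed": sm[b],
                    }
                )
        return pd.DataFrame(rows)


def moving_average(x: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered moving average with a shrinking window at the edges."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    half = window // 2
    c = np.concatenate([[0.0], np.nancumsum(x)])
    valid = np.concatenate([[0], np.cumsum(~np.isnan(x))])
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        k = valid[hi] - valid[lo]
        out[i] = (c[hi] - c[lo]) / k if k else np.nan
    return out


def _bin_boundaries(length: int, bins: int) -> np.ndarray:
    """Integer partition of ``length`` into ``bins`` chunks; the remainder
    goes to the leading (5') bins.  Returns cumulative end offsets."""
    base, rem = divmod(length, bins)
    sizes = np.full(bins, base)
    sizes[:rem] += 1
    return np.cumsum(sizes)


def _feature_bin_offsets(
    intervals: list[tuple[int, int]], strand: str, pos: np.ndarray
) -> tuple[np.ndarray, int]:
    """Transcription-orientation offsets of ``pos`` within a (possibly
    multi-interval) feature, plus the feature's total length.

    ``intervals`` are genomic and already ordered in transcription
    orientation; positions outside the feature return offset -1.
    """
    total = sum(e - s for s, e in intervals)
    off = np.full(len(pos), -1, dtype=np.int64)
    acc = 0
    for s, e in intervals:
        inside = (pos >= s) & (pos < e)
        if strand == "+":
            off[inside] = acc + (pos[inside] - s)
        else:
            off[inside] = acc + (e - 1 - pos[inside])
        acc += e - s
    return off, total


def metagene_profile(
    records: pd.DataFrame,
    annotation: AnnotationSet,
    bins_per_feature: int = 20,
    min_total: int = 4,
    contexts: tuple = ("CG", "CHG", "CHH"),
    smooth_window: int = 5,
) -> MetageneProfile:
    """Mean methylation across the 7 length-normalized gene features.

    Each feature of each gene is split into ``bins_per_feature`` equal bins
    (integer remainder spread over the 5'-most bins); site levels are
    averaged within a bin across all genes carrying that feature.  Genes
    lacking a feature (single-exon genes) contribute only to the features
    they have.  A centered ``smooth_window``-bin moving average (shrinking
    at the edges) accompanies the raw means.
    """
    if bins_per_feature < smooth_window:
        import warnings

        warnings.warn("bins_per_feature below the smoothing window; the "
                      "moving average is degenerate")
    B = bins_per_feature
    sums: dict = {
        (c, f): np.zeros(B) for c in contexts for f in GENE_FEATURES
    }
    cnts: dict = {
        (c, f): np.zeros(B, dtype=int) for c in contexts for f in GENE_FEATURES
    }
    genes_per_feature = {f: 0 for f in GENE_FEATURES}

    sites = site_levels(records, None, min_total)
    sites = sites[sites["context"].isin(contexts)]
    by_chrom = {c: g.sort_values("pos") for c, g in sites.groupby("chrom")}

    for gene in annotation.genes:
        sub = by_chrom.get(gene.chrom)
        if sub is None:
            continue
        gpos = sub["pos"].to_numpy(dtype=np.int64)
        gctx = sub["context"].to_numpy()
        glev = sub["level"].to_numpy(dtype=float)
        for feat, intervals in gene.features().items():
            if not intervals:
                continue
            genes_per_feature[feat] += 1
            lo = min(s for s, _ in intervals)
            hi = max(e for _, e in intervals)
            i0, i1 = np.searchsorted(gpos, [lo, hi])
            if i0 == i1:
                continue
            p = gpos[i0:i1]
            off, length = _feature_bin_offsets(intervals, gene.strand, p)
            inside = off >= 0
            if not inside.any() or length == 0:
                continue
            ends = _bin_boundaries(length, B)
            bidx = np.searchsorted(ends, off[inside], side="right")
            bidx = np.minimum(bidx, B - 1)
            for c in contexts:
                sel = gctx[i0:i1][inside] == c
                if sel.any():
                    np.add.at(sums[(c, feat)], bidx[sel], glev[i0:i1][inside][sel])
                    np.add.at(cnts[(c, feat)], bidx[sel], 1)

    prof = MetageneProfile(bins_per_feature=B, n_genes_per_feature=genes_per_feature)
    for key in sums:
        with np.errstate(invalid="ignore"):
            mean = np.where(cnts[key] > 0, sums[key] / np.maximum(cnts[key], 1), np.nan)
        prof.means[key] = mean
        prof.smoothed[key] = moving_average(mean, smooth_window)
        prof.n_sites[key] = int(cnts[key].sum())
    return prof


# ---------------------------------------------------------------------------
# CpG islands (Gardiner-Garden & Frommer style)


def call_cpg_islands(
    sequence: str,
    chrom: str = "",
    min_length: int = 200,
    min_gc: float = 0.5,
    min_obs_exp: float = 0.6,
) -> list[tuple[str, int, int]]:
    """Sliding-criteria CpG island calls on one sequence.

    A 200 bp window qualifies when GC content >= ``min_gc`` and the
    observed/expected CpG ratio (CpG * N / (C * G)) >= ``min_obs_exp``;
    overlapping or adjacent qualifying windows are merged and merged runs
    shorter than ``min_length`` are dropped.
    """
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    n = len(arr)
    w = min_length
    if n < w:
        return []
    is_c = (arr == ord("C")).astype(np.int32)
    is_g = (arr == ord("G")).astype(np.int32)
    is_cpg = np.zeros(n, dtype=np.int32)
    is_cpg[:-1] = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))
    cc = np.concatenate([[0], np.cumsum(is_c)])
    cg = np.concatenate([[0], np.cumsum(is_g)])
    ccpg = np.concatenate([[0], np.cumsum(is_cpg)])
    starts = np.arange(0, n - w + 1)
    nc = cc[starts + w] - cc[starts]
    ng = cg[starts + w] - cg[starts]
    ncpg = ccpg[starts + w] - ccpg[starts]
    gc = (nc + ng) / w
    with np.errstate(divide="ignore", invalid="ignore"):
        obs_exp = np.where(nc * ng > 0, ncpg * w / np.maximum(nc * ng, 1), 0.0)
    ok = (gc >= min_gc) & (obs_exp >= min_obs_exp)
    islands: list[tuple[str, int, int]] = []
    run_start = None
    prev = None
    for s in np.flatnonzero(ok):
        if run_start is None:
            run_start, prev = int(s), int(s)
        elif s <= prev + w:   # overlapping or adjacent qualifying windows
            prev = int(s)
        else:
            islands.append((chrom, run_start, prev + w))
            run_start, prev = int(s), int(s)
    if run_start is not None:
        islands.append((chrom, run_start, prev + w))
    return [(c, s, e) for c, s, e in islands if e - s >= min_length]
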