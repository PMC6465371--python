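"""Spike-in normalisation, strand-specific binning, metagene and TSS dynamics.

TT-seq coverage is consumed as bedGraph, normalised by spike-in size factors
(median-of-ratios against a geometric-mean reference), and binned into
fixed-width strand-specific tracks (100 bp for nascent coverage, 50 bp for
3'-end data and TSS dynamics). Metagene profiles resample each gene body into
50 equal bins with 2 kb flanks at 100 bp; proximal polymerase dynamics are
the per-bin treated-minus-control change around the TSS together with its
first difference (the rate of accumulation change).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .annotation import GeneModel

TT_BIN = 100
POLYA_BIN = 50


# ---------------------------------------------------------------------------
# size factors
# ---------------------------------------------------------------------------


def estimate_size_factors(spikein_counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factor per sample from a spike-in count matrix.

    Rows are spike-ins, columns samples. The reference is the per-spike-in
    geometric mean across samples, using only spike-ins with positive counts
    in every sample; the factor for a sample is the median ratio of its
    counts to the reference.
    """
    counts = spikein_counts.astype(float)
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no spike-in has positive counts in every sample; "
            "consider adding a pseudocount to the matrix"
        )
    sub = counts.loc[positive]
    log_ref = np.log(sub).mean(axis=1)
    factors = np.exp(np.log(sub).sub(log_ref, axis=0).median(axis=0))
    return factors


# ---------------------------------------------------------------------------
# binned tracks
# ---------------------------------------------------------------------------


@dataclass
class CoverageTrack:
    """Fixed-bin strand-specific signal for one sample.

    ``values[chrom][i]`` is mean per-bp signal in bin ``i`` after division by
    the size factor (and optional per-million scaling).
    """

    sample_id: str
    condition: str
    strand: str
    bin_size: int
    seq_lengths: dict[str, int]
    values: dict[str, np.ndarray] = field(default_factory=dict)

    def per_bp(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-bp signal over [start, end); zero outside sequence bounds."""
        out = np.zeros(end - start)
        L = self.seq_lengths[chrom]
        lo, hi = max(start, 0), min(end, L)
        if hi <= lo:
            return out
        bins = self.values[chrom]
        idx = np.arange(lo, hi) // self.bin_size
        out[lo - start:hi - start] = bins[idx]
        return out

    def region_sum(self, chrom: str, start: int, end: int) -> float:
        """Signal mass in [start, end): sum of per-bp values."""
        return float(self.per_bp(chrom, start, end).sum())


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": int, "end": int, "value": float},
    )
    return df


def bin_coverage(
    bedgraph: pd.DataFrame | str | Path,
    seq_lengths: Mapping[str, int],
    bin_size: int,
    strand: str,
    size_factor: float = 1.0,
    sample_id: str = "sample",
    condition: str = "na",
    per_million: bool = False,
) -> CoverageTrack:
    """Bin a bedGraph into a :class:`CoverageTrack`.

    Bin value = interval-length-weighted signal sum over the bin / bin width
    / size factor. With ``per_million`` the track is additionally scaled by
    1e6 over the raw (pre-factor) total signal mass.
    """
    if not isinstance(bedgraph, pd.DataFrame):
        bedgraph = read_bedgraph(bedgraph)
    values: dict[str, np.ndarray] = {}
    total_mass = 0.0
    for chrom, L in seq_lengths.items():
        arr = np.zeros(L)
        sub = bedgraph[bedgraph["chrom"] == chrom]
        if len(sub):
            if (sub["end"] > L).any() or (sub["start"] < 0).any():
                raise ValueError(f"bedGraph interval beyond {chrom} length {L}")
            for s, e, v in zip(sub["start"], sub["end"], sub["value"]):
                arr[s:e] = v
        total_mass += arr.sum()
        n_bins = (L + bin_size - 1) // bin_size
        starts = np.arange(0, L, bin_size)
        sums = np.add.reduceat(arr, starts)
        values[chrom] = sums / bin_size / size_factor
        assert values[chrom].size == n_bins
    if per_million and total_mass > 0:
        scale = 1e6 / total_mass
        for chrom in values:
            values[chrom] *= scale
    return CoverageTrack(
        sample_id=sample_id,
        condition=condition,
        strand=strand,
        bin_size=bin_size,
        seq_lengths=dict(seq_lengths),
        values=values,
    )


def merge_tracks(tracks: Sequence[CoverageTrack], sample_id: str = "merged") -> CoverageTrack:
    """Average replicate tracks bin-wise (same binning required)."""
    first = tracks[0]
    if any(t.bin_size != first.bin_size for t in tracks):
        raise ValueError("tracks differ in bin size")
    values = {
        chrom: np.mean([t.values[chrom] for t in tracks], axis=0)
        for chrom in first.values
    }
    return CoverageTrack(
        sample_id=sample_id,
        condition=first.condition,
        strand=first.strand,
        bin_size=first.bin_size,
        seq_lengths=first.seq_lengths,
        values=values,
    )


# ---------------------------------------------------------------------------
# metagene profiles
# ---------------------------------------------------------------------------


@dataclass
class MetageneProfile:
    sense: np.ndarray
    antisense: np.ndarray
    n_body_bins: int
    flank_bp: int
    flank_bin: int
    n_genes: int
    n_excluded: int

    @property
    def n_flank_bins(self) -> int:
        return self.flank_bp // self.flank_bin

    @staticmethod
    def rescale(values: np.ndarray, lo: float = 1.0, hi: float = 100.0) -> np.ndarray:
        vmin, vmax = float(np.min(values)), float(np.max(values))
        if vmax == vmin:
            return np.full_like(values, lo)
        return lo + (values - vmin) * (hi - lo) / (vmax - vmin)

    def to_frame(self, rescaled: bool = False) -> pd.DataFrame:
        nf = self.n_flank_bins
        labels = (
            [f"up_{i}" for i in range(nf)]
            + [f"body_{i}" for i in range(self.n_body_bins)]
            + [f"down_{i}" for i in range(nf)]
        )
        df = pd.DataFrame(
            {"bin": labels, "sense": self.sense, "antisense": self.antisense}
        )
        if rescaled:
            df["sense_rescaled"] = self.rescale(self.sense)
            df["antisense_rescaled"] = self.rescale(self.antisense)
        return df


def _resample_body(per_bp: np.ndarray, n_bins: int) -> np.ndarray:
    """Area-weighted resampling of a per-bp profile into n equal bins."""
    L = per_bp.size
    cs = np.concatenate([[0.0], np.cumsum(per_bp)])
    edges = np.linspace(0.0, L, n_bins + 1)
    cum_at_edges = np.interp(edges, np.arange(L + 1), cs)
    widths = np.diff(edges)
    return np.diff(cum_at_edges) / widths


def metagene_profile(
    tracks: Mapping[str, CoverageTrack],
    genes: Iterable[GeneModel],
    n_body_bins: int = 50,
    flank_bp: int = 2000,
    flank_bin: int = 100,
    exclude_flank_overlaps: bool = False,
) -> MetageneProfile:
    """Average gene-body metagene with fixed-width flanks.

    ``tracks`` maps strand ('+'/'-') to a binned track. For each gene the
    body (TSS to TES) is resampled area-weighted into ``n_body_bins``; flanks
    are binned at ``flank_bin``. Bin 1 sits at the TSS for genes on either
    strand. The sense profile reads the track matching the gene's strand,
    the antisense profile the opposite track over the same coordinates.
    """
    gene_list = list(genes)
    if exclude_flank_overlaps:
        spans = [(g.chrom, g.start, g.end) for g in gene_list]
        kept = []
        for g in gene_list:
            w = (g.start - flank_bp, g.end + flank_bp)
            clash = any(
                c == g.chrom and s < w[1] and e > w[0] and not (s == g.start and e == g.end)
                for c, s, e in spans
            )
            if not clash:
                kept.append(g)
        gene_list = kept
    nf = flank_bp // flank_bin
    total = nf + n_body_bins + nf
    sense_acc = np.zeros(total)
    anti_acc = np.zeros(total)
    n_used = n_excluded = 0
    for g in gene_list:
        if g.length < n_body_bins:
            n_excluded += 1
            continue
        same = tracks[g.strand]
        other = tracks["-" if g.strand == "+" else "+"]
        for acc, track in ((sense_acc, same), (anti_acc, other)):
            body = track.per_bp(g.chrom, g.start, g.end)
            if g.strand == "+":
                up = track.per_bp(g.chrom, g.start - flank_bp, g.start)
                down = track.per_bp(g.chrom, g.end, g.end + flank_bp)
            else:
                body = body[::-1]
                up = track.per_bp(g.chrom, g.end, g.end + flank_bp)[::-1]
                down = track.per_bp(g.chrom, g.start - flank_bp, g.start)[::-1]
            prof = np.concatenate(
                [
                    up.reshape(nf, flank_bin).mean(axis=1),
                    _resample_body(body, n_body_bins),
                    down.reshape(nf, flank_bin).mean(axis=1),
                ]
            )
            acc += prof
        n_used += 1
    if n_used == 0:
        raise ValueError("no gene long enough for the metagene profile")
    return MetageneProfile(
        sense=sense_acc / n_used,
        antisense=anti_acc / n_used,
        n_body_bins=n_body_bins,
        flank_bp=flank_bp,
        flank_bin=flank_bin,
        n_genes=n_used,
        n_excluded=n_excluded,
    )


# ---------------------------------------------------------------------------
# proximal polymerase dynamics
# ---------------------------------------------------------------------------


@dataclass
class DynamicsProfile:
    bin_centers: np.ndarray     # bp relative to TSS
    change: np.ndarray          # mean treated - control per bin
    rate: np.ndarray            # first difference of change
    rate_rescaled: np.ndarray   # rate mapped onto [min(change), max(change)]
    change_smooth: np.ndarray
    rate_smooth: np.ndarray
    n_genes: int


def tss_dynamics(
    control: Mapping[str, CoverageTrack],
    treated: Mapping[str, CoverageTrack],
    genes: Iterable[GeneModel],
    upstream: int = 500,
    downstream: int = 10000,
    loess_frac: float = 0.2,
) -> DynamicsProfile:
    """Treated-minus-control signal change around the TSS and its rate.

    Both track sets must share the same bin size (typically 50 bp). The
    change is averaged over genes in windows from ``upstream`` bp before to
    ``downstream`` bp after the TSS; the rate is the successive difference,
    linearly rescaled to the range of the change for joint display; loess
    curves are fitted for presentation.
    """
    bin_size = next(iter(control.values())).bin_size
    for trk in list(control.values()) + list(treated.values()):
        if trk.bin_size != bin_size:
            raise ValueError("control/treated tracks differ in bin size")
    span = upstream + downstream
    n_bins = span // bin_size
    acc = np.zeros(n_bins)
    n_genes = 0
    for g in genes:
        if g.strand == "+":
            s, e = g.start - upstream, g.start + downstream
            sl = slice(None)
        else:
            s, e = g.end - downstream, g.end + upstream
            sl = slice(None, None, -1)
        diff = (
            treated[g.strand].per_bp(g.chrom, s, e)
            - control[g.strand].per_bp(g.chrom, s, e)
        )[sl]
        acc += diff[: n_bins * bin_size].reshape(n_bins, bin_size).mean(axis=1)
        n_genes += 1
    if n_genes == 0:
        raise ValueError("no genes supplied")
    change = acc / n_genes
    rate = np.diff(change)
    cmin, cmax = float(change.min()), float(change.max())
    rmin, rmax = float(rate.min()), float(rate.max())
    if rmax > rmin:
        rate_rescaled = cmin + (rate - rmin) * (cmax - cmin) / (rmax - rmin)
    else:
        rate_rescaled = np.full_like(rate, cmin)
    centers = -upstream + (np.arange(n_bins) + 0.5) * bin_size
    change_smooth = lowess(
        change, centers, frac=loess_frac, return_sorted=False
    )
    rate_smooth = lowess(
        rate_rescaled, centers[1:], frac=loess_frac, return_sorted=False
    )
    return DynamicsProfile(
        bin_centers=centers,
        change=change,
        rate=rate,
        rate_rescaled=rate_rescaled,
        change_smooth=change_smooth,
        rate_smooth=rate_smooth,
        n_genes=n_genes,
    )


# ---------------------------------------------------------------------------
# replicate agreement
# ---------------------------------------------------------------------------


def replicate_correlation(tracks: Sequence[CoverageTrack]) -> pd.DataFrame:
    """Pairwise Spearman correlation matrix of binned tracks.

    Constant tracks yield NaN against everything (correlation undefined).
    """
    if len(tracks) < 2:
        raise ValueError("need at least two tracks")
    first = tracks[0]
    for t in tracks:
        if t.bin_size != first.bin_size or t.seq_lengths != first.seq_lengths:
            raise ValueError("tracks are not on identical binning")
    flat = [
        np.concatenate([t.values[c] for c in sorted(t.values)]) for t in tracks
    ]
    names = [t.sample_id for t in tracks]
    n = len(tracks)
    mat = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i, n):
            if np.ptp(flat[i]) == 0 or np.ptp(flat[j]) == 0:
                val = np.nan if i != j else 1.0
            elif i == j:
                val = 1.0
            else:
                val = stats.spearmanr(flat[i], flat[j]).statistic
            mat[i, j] = mat[j, i] = val
    return pd.DataFrame(mat, index=names, columns=names)
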