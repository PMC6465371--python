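"""Poly(A) 3'-end peak filtering, annotation and condition-specific calling.

Oligo-dT-primed 3'-end libraries produce artifact peaks where the primer
anneals to genomic adenosine tracts instead of true poly(A) tails. A peak is
flagged as an internal-priming artifact and removed when no polyadenylation
signal (PAS) hexamer occurs in the 100 bp upstream of the cleavage site
(transcript-sense) *and* the 50 bp downstream contain a 25-mer with at least
22 adenosines (a 25-A stretch with at most 3 mismatches).

Retained peaks are annotated hierarchically: peaks within the TES window
(-200/+600 bp along the transcription direction) are 3'UTR peaks; remaining
genic peaks are exonic or intronic by the reduced gene model (protein-coding
genes take priority over longer ones); everything else is intergenic.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel
from .simulate import PAS_MOTIFS, revcomp

CATEGORIES = ("tes_utr", "exon", "intron", "intergenic")

PAS_UPSTREAM_WINDOW = 100
A_STRETCH_WINDOW = 50
A_STRETCH_LEN = 25
A_STRETCH_MIN_A = 22  # 25-mer with at most 3 mismatches
TES_WINDOW = (-200, 600)  # transcript-sense, relative to the TES


def read_peaks(path: str | Path) -> pd.DataFrame:
    """Read a BED-like peak table (TSV with header).

    Required columns: chrom, start, end, name, qscore, strand; optional
    ``summit``; remaining numeric columns are per-sample counts.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "name", "qscore", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"peak table missing columns: {sorted(missing)}")
    return df


def peak_positions(peaks: pd.DataFrame) -> np.ndarray:
    """Single-base cleavage coordinate: summit column if present, else midpoint."""
    if "summit" in peaks.columns:
        return peaks["summit"].to_numpy(int)
    return ((peaks["start"] + peaks["end"]) // 2).to_numpy(int)


class _SeqSource:
    """Uniform fetch over a pyfaidx.Fasta or a plain {chrom: str} mapping."""

    def __init__(self, genome):
        self._genome = genome

    def fetch(self, chrom: str, start: int, end: int) -> str:
        start = max(start, 0)
        if isinstance(self._genome, Mapping):
            return self._genome[chrom][start:end].upper()
        return str(self._genome[chrom][start:end]).upper()


def _max_a_in_kmer(seq: str, k: int = A_STRETCH_LEN) -> int:
    if len(seq) < k:
        return 0
    isa = np.frombuffer(seq.encode(), dtype=np.uint8) == ord("A")
    window = np.convolve(isa.astype(int), np.ones(k, dtype=int), mode="valid")
    return int(window.max())


def filter_internal_priming(
    peaks: pd.DataFrame,
    genome,
    upstream: int = PAS_UPSTREAM_WINDOW,
    downstream: int = A_STRETCH_WINDOW,
    min_a: int = A_STRETCH_MIN_A,
    stretch_len: int = A_STRETCH_LEN,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split peaks into (retained, removed) by the internal-priming test.

    Adds ``pas_motif`` (first matching PAS hexamer in the upstream window,
    scanned in canonical order, or empty) and ``a_stretch`` columns. A peak
    is removed iff it lacks a PAS motif and has a downstream A-stretch.
    ``genome`` is a pyfaidx.Fasta or a {chrom: sequence} mapping; windows are
    clipped at sequence ends.
    """
    src = _SeqSource(genome)
    pos = peak_positions(peaks)
    motifs: list[str] = []
    stretches: list[bool] = []
    for p, chrom, strand in zip(pos, peaks["chrom"], peaks["strand"]):
        if strand == "+":
            up = src.fetch(chrom, p - upstream, p)
            down = src.fetch(chrom, p + 1, p + 1 + downstream)
        else:
            up = revcomp(src.fetch(chrom, p + 1, p + 1 + upstream))
            down = revcomp(src.fetch(chrom, p - downstream, p))
        hit = ""
        for motif in PAS_MOTIFS:
            if motif in up:
                hit = motif
                break
        motifs.append(hit)
        stretches.append(_max_a_in_kmer(down, stretch_len) >= min_a)
    out = peaks.copy()
    out["pas_motif"] = motifs
    out["a_stretch"] = stretches
    removed_mask = (out["pas_motif"] == "") & out["a_stretch"]
    return out[~removed_mask].copy(), out[removed_mask].copy()


def annotate_peaks(
    peaks: pd.DataFrame, genes: Mapping[str, GeneModel]
) -> pd.DataFrame:
    """Assign each peak one genomic category and (when genic) a gene.

    Hierarchy: TES window first (tes_utr), then exon/intron overlap with the
    reduced gene model, else intergenic. When a peak overlaps several genes,
    protein-coding genes win, then longer genes.
    """
    pos = peak_positions(peaks)
    out = peaks.copy()
    categories: list[str] = []
    gene_ids: list[str] = []
    gene_list = sorted(
        genes.values(),
        key=lambda g: (g.biotype != "protein_coding", -g.length, g.gene_id),
    )
    for p, chrom, strand in zip(pos, peaks["chrom"], peaks["strand"]):
        category, gid = "intergenic", ""
        # step 1: TES windows, strand-aware, same priority order
        for g in gene_list:
            if g.chrom != chrom or g.strand != strand:
                continue
            if g.strand == "+":
                lo, hi = g.tes + TES_WINDOW[0], g.tes + TES_WINDOW[1]
            else:
                lo, hi = g.tes - TES_WINDOW[1], g.tes - TES_WINDOW[0]
            if lo <= p <= hi:
                category, gid = "tes_utr", g.gene_id
                break
        # step 2: genic overlap
        if category == "intergenic":
            for g in gene_list:
                if g.chrom != chrom or g.strand != strand:
                    continue
                if g.start <= p < g.end:
                    in_exon = any(s <= p < e for s, e in g.exons)
                    category = "exon" if in_exon else "intron"
                    gid = g.gene_id
                    break
        categories.append(category)
        gene_ids.append(gid)
    out["category"] = categories
    out["gene_id"] = gene_ids
    return out


def differential_peaks(
    peaks: pd.DataFrame,
    cols_a: Sequence[str] | str,
    cols_b: Sequence[str] | str,
    min_qscore: float = 5.0,
    min_reads: int = 64,
    log_ratio_threshold: float = 1.0,
    per_sample_minimum: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Condition-specific peaks by log-ratio of pseudocounted read counts.

    Peaks with -log10 q below ``min_qscore`` are dropped. For the remainder
    the log-ratio log2((a+1)/(b+1)) is computed on summed counts per
    condition; a peak is a-specific when reads >= ``min_reads`` (combined by
    default, per-condition with ``per_sample_minimum``) and log-ratio > 1,
    b-specific when < -1. Returns (a_specific, b_specific, unchanged).
    """
    if isinstance(cols_a, str):
        cols_a = [cols_a]
    if isinstance(cols_b, str):
        cols_b = [cols_b]
    kept = peaks[peaks["qscore"] >= min_qscore].copy()
    a = kept[list(cols_a)].sum(axis=1).astype(float)
    b = kept[list(cols_b)].sum(axis=1).astype(float)
    kept["log_ratio"] = np.log2((a + 1.0) / (b + 1.0))
    if per_sample_minimum:
        enough = (a >= min_reads) & (b >= min_reads)
    else:
        enough = (a + b) >= min_reads
    a_specific = kept[enough & (kept["log_ratio"] > log_ratio_threshold)]
    b_specific = kept[enough & (kept["log_ratio"] < -log_ratio_threshold)]
    unchanged = kept.drop(index=a_specific.index.union(b_specific.index))
    return a_specific.copy(), b_specific.copy(), unchanged.copy()


def peak_region_distribution(
    peaks: pd.DataFrame,
    count_cols: Sequence[str],
    top_n: int = 5000,
    n_intensity_bins: int = 10,
) -> pd.DataFrame:
    """Category fractions of the top-intensity peaks across intensity bins.

    Peaks are ranked by total read intensity; the ``top_n`` strongest are
    split into ``n_intensity_bins`` equal rank bins (bin 1 = strongest) and
    per-bin category fractions are returned (rows sum to 1).
    """
    if "category" not in peaks.columns:
        raise ValueError("peaks must be annotated before ranking")
    intensity = peaks[list(count_cols)].sum(axis=1)
    order = intensity.sort_values(ascending=False).index
    if top_n > len(order):
        import warnings

        warnings.warn(
            f"top_n={top_n} exceeds {len(order)} available peaks; using all"
        )
        top_n = len(order)
    ranked = peaks.loc[order[:top_n]].reset_index(drop=True)
    bins = np.minimum(
        (np.arange(top_n) * n_intensity_bins) // max(top_n, 1),
        n_intensity_bins - 1,
    )
    ranked["intensity_bin"] = bins + 1
    frac = (
        ranked.groupby("intensity_bin")["category"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
    )
    for cat in CATEGORIES:
        if cat not in frac.columns:
            frac[cat] = 0.0
    return frac[list(CATEGORIES)]
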