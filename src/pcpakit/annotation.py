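"""Custom gene annotation: transcript selection, reduced gene models, strata.

The analysis operates on a *reduced* per-gene representation: the union of the
exons of all retained isoforms, with introns defined as the complement within
the gene span. Transcripts are retained by abundance (gene TPM, isoform
fraction, with a rescue for highly expressed minor isoforms), genes are
stratified by biotype (protein-coding / long non-coding / short non-coding)
and, for protein-coding genes, by length quartiles with a further subdivision
of the shortest quartile.

Coordinates are 0-based half-open throughout; GTF input (1-based closed) is
converted on read.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

KMEANS_SEED = 1729
MIN_BIOTYPE_MEMBERS = 20

LENGTH_CLASSES = (
    "long",
    "medium_long",
    "medium_short",
    "short",
    "very_short",
    "ultra_short",
)
BIOTYPE_GROUPS = ("protein_coding", "long_noncoding", "short_noncoding")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class GeneModel:
    """Reduced exon/intron representation of one gene.

    ``exons`` are merged, disjoint, sorted intervals (0-based half-open);
    ``introns`` are the gaps between them, so exons and introns partition
    the gene span exactly.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]]
    biotype: str = "protein_coding"
    biotype_group: str | None = None
    length_class: str | None = None
    representative_transcript: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if self.end <= self.start:
            raise ValueError(f"{self.gene_id}: empty span")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def introns(self) -> list[tuple[int, int]]:
        gaps = []
        for (s1, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if s2 > e1:
                gaps.append((e1, s2))
        return gaps

    @property
    def n_introns(self) -> int:
        return len(self.introns)

    def exons_stranded(self) -> list[tuple[int, int]]:
        """Exons in transcription order (first exon first)."""
        return self.exons if self.strand == "+" else self.exons[::-1]

    @property
    def tss(self) -> int:
        """TSS coordinate (the base at which transcription starts)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


@dataclass
class GeneSet:
    name: str
    members: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")


# ---------------------------------------------------------------------------
# interval helpers
# ---------------------------------------------------------------------------


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals, merged and sorted. Touching intervals fuse."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        if e <= s:
            raise ValueError(f"empty interval [{s},{e})")
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def subtract_intervals(
    window: tuple[int, int], blockers: Iterable[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Remove ``blockers`` from ``window``; returns remaining fragments."""
    fragments = [window]
    for bs, be in sorted(blockers):
        out: list[tuple[int, int]] = []
        for fs, fe in fragments:
            if be <= fs or bs >= fe:
                out.append((fs, fe))
                continue
            if bs > fs:
                out.append((fs, bs))
            if be < fe:
                out.append((be, fe))
        fragments = out
    return fragments


# ---------------------------------------------------------------------------
# GTF / table input
# ---------------------------------------------------------------------------


def read_gtf(path: str | Path) -> pd.DataFrame:
    """Read a GTF into a 0-based half-open exon table.

    Returns one row per exon with columns ``chrom, start, end, strand,
    gene_id, transcript_id, biotype``. Accepts either ``gene_type`` or
    ``gene_biotype`` attribute keys; missing biotypes default to
    ``protein_coding``.
    """
    import pyranges as pr

    df = pr.read_gtf(str(path)).df
    biotype_col = None
    for cand in ("gene_type", "gene_biotype"):
        if cand in df.columns:
            biotype_col = cand
            break
    # biotype usually annotated on the gene feature only; propagate per gene
    if biotype_col is not None:
        gene_bt = (
            df.dropna(subset=[biotype_col])
            .groupby("gene_id")[biotype_col]
            .first()
        )
    else:
        gene_bt = pd.Series(dtype=object)
    exons = df[df["Feature"] == "exon"].copy()
    if exons.empty:
        raise ValueError(f"{path}: no exon features found")
    out = pd.DataFrame(
        {
            "chrom": exons["Chromosome"].astype(str),
            "start": exons["Start"].astype(int),
            "end": exons["End"].astype(int),
            "strand": exons["Strand"].astype(str),
            "gene_id": exons["gene_id"].astype(str),
            "transcript_id": exons["transcript_id"].astype(str),
        }
    )
    out["biotype"] = (
        out["gene_id"].map(gene_bt).fillna("protein_coding").astype(str)
    )
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# transcript selection
# ---------------------------------------------------------------------------


def select_transcripts(
    quant: pd.DataFrame,
    gene_tpm_min: float = 2.0,
    frac_min: float = 0.2,
    rescue_tpm: float = 5.0,
) -> set[str]:
    """Retain transcripts of adequately expressed genes and isoform usage.

    All transcripts of genes with summed TPM below ``gene_tpm_min`` are
    dropped. Within retained genes, isoforms contributing less than
    ``frac_min`` of the gene's TPM are dropped unless their own TPM exceeds
    ``rescue_tpm``.

    Parameters
    ----------
    quant
        Table with columns ``transcript_id, gene_id, tpm``.
    """
    required = {"transcript_id", "gene_id", "tpm"}
    missing = required - set(quant.columns)
    if missing:
        raise ValueError(f"quant table missing columns: {sorted(missing)}")
    if (quant["tpm"] < 0).any():
        raise ValueError("negative TPM values in quant table")
    q = quant.copy()
    gene_tpm = q.groupby("gene_id")["tpm"].transform("sum")
    q["fraction"] = np.where(gene_tpm > 0, q["tpm"] / gene_tpm, 0.0)
    keep = (
        (gene_tpm >= gene_tpm_min)
        & ((q["fraction"] >= frac_min) | (q["tpm"] > rescue_tpm))
    )
    return set(q.loc[keep, "transcript_id"])


def reduce_gene_model(
    gene_id: str,
    transcript_exons: Mapping[str, Sequence[tuple[int, int]]],
    chrom: str,
    strand: str | Sequence[str],
    biotype: str = "protein_coding",
    representative: str | None = None,
) -> GeneModel:
    """Merge the exons of all retained isoforms into one reduced gene model."""
    if not transcript_exons:
        raise ValueError(f"{gene_id}: no retained transcripts")
    if not isinstance(strand, str):
        strands = set(strand)
        if len(strands) != 1:
            raise ValueError(f"{gene_id}: transcripts on mixed strands {strands}")
        strand = strands.pop()
    all_exons = [iv for exons in transcript_exons.values() for iv in exons]
    merged = merge_intervals(all_exons)
    return GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        start=merged[0][0],
        end=merged[-1][1],
        exons=merged,
        biotype=biotype,
        representative_transcript=representative,
    )


def choose_representative(
    transcript_exons: Mapping[str, Sequence[tuple[int, int]]],
    utr_reads: Mapping[str, float] | None = None,
) -> str:
    """Representative isoform: highest 3'UTR-assigned poly(A) read sum.

    Ties (and the no-peak-data case) are broken by longer transcript, then
    lexicographic id.
    """

    def span(tid: str) -> int:
        exons = transcript_exons[tid]
        return max(e for _, e in exons) - min(s for s, _ in exons)

    def key(tid: str):
        reads = utr_reads.get(tid, 0.0) if utr_reads else 0.0
        return (-reads, -span(tid), tid)

    return min(transcript_exons, key=key)


def build_gene_models(
    exon_table: pd.DataFrame,
    retained_transcripts: set[str] | None = None,
    utr_reads: Mapping[str, float] | None = None,
) -> dict[str, GeneModel]:
    """Build reduced GeneModels from a :func:`read_gtf` exon table."""
    tbl = exon_table
    if retained_transcripts is not None:
        tbl = tbl[tbl["transcript_id"].isin(retained_transcripts)]
    models: dict[str, GeneModel] = {}
    for gene_id, sub in tbl.groupby("gene_id", sort=True):
        strands = set(sub["strand"])
        if len(strands) != 1:
            raise ValueError(f"{gene_id}: transcripts on mixed strands {strands}")
        per_tx: dict[str, list[tuple[int, int]]] = {}
        for tid, txsub in sub.groupby("transcript_id"):
            per_tx[str(tid)] = list(zip(txsub["start"], txsub["end"]))
        rep = choose_representative(per_tx, utr_reads)
        models[str(gene_id)] = reduce_gene_model(
            str(gene_id),
            per_tx,
            chrom=str(sub["chrom"].iloc[0]),
            strand=strands.pop(),
            biotype=str(sub["biotype"].iloc[0]),
            representative=rep,
        )
    return models


# ---------------------------------------------------------------------------
# stratification
# ---------------------------------------------------------------------------


def stratify_lengths(
    lengths: Mapping[str, int],
) -> tuple[dict[str, str], dict[str, float]]:
    """Assign protein-coding genes to six length classes.

    Quartile boundaries are computed from the input length distribution
    (type-7 linear-interpolation quantiles). The shortest quartile is further
    split at its own 0.33 and 0.66 quantiles into short / very_short /
    ultra_short. Genes falling exactly on a boundary go to the shorter class.

    Returns ``(labels, boundaries)`` where boundaries has keys
    ``q25, q50, q75, short_33, short_66`` (bp).
    """
    if len(lengths) < 8:
        raise ValueError("need at least 8 genes to stratify by length quartiles")
    vals = np.asarray(list(lengths.values()), dtype=float)
    if (vals <= 0).any():
        raise ValueError("non-positive gene lengths")
    q25, q50, q75 = np.quantile(vals, [0.25, 0.50, 0.75])
    short_vals = vals[vals <= q25]
    if short_vals.size:
        b33, b66 = np.quantile(short_vals, [0.33, 0.66])
    else:  # degenerate: all lengths equal
        b33 = b66 = q25
    boundaries = {
        "q25": float(q25),
        "q50": float(q50),
        "q75": float(q75),
        "short_33": float(b33),
        "short_66": float(b66),
    }
    labels: dict[str, str] = {}
    for gid, ln in lengths.items():
        if ln > q75:
            labels[gid] = "long"
        elif ln > q50:
            labels[gid] = "medium_long"
        elif ln > q25:
            labels[gid] = "medium_short"
        elif ln > b66:
            labels[gid] = "short"
        elif ln > b33:
            labels[gid] = "very_short"
        else:
            labels[gid] = "ultra_short"
    return labels, boundaries


def classify_biotypes(
    biotypes: Mapping[str, str],
    lengths: Mapping[str, int],
    min_members: int = MIN_BIOTYPE_MEMBERS,
    seed: int = KMEANS_SEED,
) -> dict[str, str]:
    """Collapse raw biotype labels to three groups.

    Protein-coding genes pass through. Raw biotypes with fewer than
    ``min_members`` genes are labelled ``unclassified``. The remaining
    non-coding genes are split into long vs short non-coding by k-means
    (k=2, 10 restarts) on log10 gene length; the cluster with the larger
    centroid is ``long_noncoding``. The assignment is order-invariant: genes
    are labelled by nearest centroid after fitting on sorted lengths.
    """
    counts = pd.Series(list(biotypes.values())).value_counts()
    groups: dict[str, str] = {}
    noncoding: list[str] = []
    for gid, bt in biotypes.items():
        if bt == "protein_coding":
            groups[gid] = "protein_coding"
        elif counts.get(bt, 0) < min_members:
            groups[gid] = "unclassified"
        else:
            noncoding.append(gid)
    if not noncoding:
        return groups
    if len(noncoding) < 2:
        warnings.warn("fewer than 2 non-coding genes; all assigned long_noncoding")
        for gid in noncoding:
            groups[gid] = "long_noncoding"
        return groups
    x = np.log10([max(lengths[g], 1) for g in sorted(noncoding)])
    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(x.reshape(-1, 1))
    centroids = km.cluster_centers_.ravel()
    long_centroid = centroids.max()
    short_centroid = centroids.min()
    for gid in noncoding:
        v = np.log10(max(lengths[gid], 1))
        groups[gid] = (
            "long_noncoding"
            if abs(v - long_centroid) <= abs(v - short_centroid)
            else "short_noncoding"
        )
    return groups


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------


def load_gene_set(
    paths: Sequence[str | Path],
    annotation_genes: set[str],
    name: str = "gene_set",
) -> tuple[GeneSet, int]:
    """Union of gene-list files intersected with the annotation.

    Files hold one id per line; ``#`` starts a comment. Returns the gene set
    and the number of ids not found in the annotation.
    """
    union: set[str] = set()
    for path in paths:
        with open(path) as fh:
            for line in fh:
                token = line.split("#", 1)[0].strip()
                if token:
                    union.add(token)
    if not union:
        raise ValueError("gene-set files contained no ids")
    matched = union & annotation_genes
    unmatched = len(union) - len(matched)
    if unmatched:
        logger.info("gene set %s: %d ids not in annotation", name, unmatched)
    return GeneSet(name=name, members=matched), unmatched


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------


def write_gene_models(
    models: Mapping[str, GeneModel], bed_path: str | Path, tsv_path: str | Path
) -> None:
    """Write reduced models as BED12 plus a per-gene summary TSV."""
    with open(bed_path, "w") as bed:
        for gid in sorted(models):
            m = models[gid]
            sizes = ",".join(str(e - s) for s, e in m.exons) + ","
            starts = ",".join(str(s - m.start) for s, _ in m.exons) + ","
            bed.write(
                f"{m.chrom}\t{m.start}\t{m.end}\t{gid}\t0\t{m.strand}\t"
                f"{m.start}\t{m.end}\t0\t{len(m.exons)}\t{sizes}\t{starts}\n"
            )
    rows = [
        {
            "gene_id": gid,
            "length": m.length,
            "biotype_group": m.biotype_group,
            "length_class": m.length_class,
            "representative_transcript": m.representative_transcript,
        }
        for gid, m in sorted(models.items())
    ]
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
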