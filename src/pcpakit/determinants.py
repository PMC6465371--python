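"""Gene-architecture determinants of premature cleavage and polyadenylation.

Genes prone to PCPA tend to be long, intron-rich, low in U1 snRNP binding
motifs relative to polyadenylation signals (a low U1/PAS ratio weakens
telescripting protection), and to carry more intronic poly(A) sites. This
module quantifies those determinants per gene, compares them between all
genes and PCPA genes (Wilcoxon rank-sum + Cohen's d), fits the quadratic
relation between transcript length and the number of intronic poly(A)
sites, and scores splice-site conservation with donor/acceptor position
weight matrices built from GT..AG introns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .annotation import GeneModel
from .polya import _SeqSource
from .simulate import PAS_CANONICAL, U1_MOTIFS, revcomp

DETERMINANTS = (
    "length",
    "first_intron_length",
    "n_introns",
    "gc_fraction",
    "expression",
    "u1_pas_ratio",
    "n_intronic_pas_sites",
)

DONOR_WIDTH = 9       # 3 exonic bases + 6 intronic, GT at intron +1,+2
ACCEPTOR_WIDTH = 15   # 15-mer ending at the intron's final base (..AG)
PWM_PSEUDOCOUNT = 0.5
PWM_BACKGROUND = 0.25
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


def count_overlapping(seq: str, motif: str) -> int:
    """Overlapping occurrences of ``motif`` in ``seq``."""
    count = start = 0
    while True:
        idx = seq.find(motif, start)
        if idx < 0:
            return count
        count += 1
        start = idx + 1


def gene_sense_sequence(genome, gene: GeneModel) -> str:
    src = _SeqSource(genome)
    seq = src.fetch(gene.chrom, gene.start, gene.end)
    return seq if gene.strand == "+" else revcomp(seq)


def compute_determinants(
    genes: Mapping[str, GeneModel],
    genome,
    expression: Mapping[str, float] | pd.Series | None = None,
    annotated_peaks: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One DeterminantRecord row per gene.

    Motifs are counted as overlapping occurrences on the sense strand from
    TSS to TES; GC over the same span. ``u1_pas_ratio`` is pseudocounted,
    (u1+1)/(pas+1). ``n_intronic_pas_sites`` comes from the annotated peak
    table (category == 'intron') when provided.
    """
    expr = pd.Series(expression) if expression is not None else None
    intronic_pas: Mapping[str, int] = {}
    if annotated_peaks is not None:
        intronic_pas = (
            annotated_peaks[annotated_peaks["category"] == "intron"]
            .groupby("gene_id")
            .size()
            .to_dict()
        )
    rows = []
    for gid, g in genes.items():
        seq = gene_sense_sequence(genome, g)
        if len(seq) != g.length:
            raise ValueError(f"{gid}: gene span outside the genome sequence")
        u1 = sum(count_overlapping(seq, m) for m in U1_MOTIFS)
        pas = count_overlapping(seq, PAS_CANONICAL)
        gc = (seq.count("G") + seq.count("C")) / max(len(seq), 1)
        introns = g.introns
        first_intron = (
            (introns[0][1] - introns[0][0]) if g.strand == "+" else
            (introns[-1][1] - introns[-1][0])
        ) if introns else 0
        rows.append(
            {
                "gene_id": gid,
                "length": g.length,
                "first_intron_length": first_intron,
                "n_introns": len(introns),
                "gc_fraction": gc,
                "expression": float(expr.get(gid, np.nan)) if expr is not None else np.nan,
                "u1_count": u1,
                "pas_count": pas,
                "u1_pas_ratio": (u1 + 1.0) / (pas + 1.0),
                "n_intronic_pas_sites": int(intronic_pas.get(gid, 0)),
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Cohen's d with pooled, Bessel-corrected standard deviation (a vs b)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = a.size, b.size
    va = a.var(ddof=1) if na > 1 else 0.0
    vb = b.var(ddof=1) if nb > 1 else 0.0
    pooled = ((na - 1) * va + (nb - 1) * vb) / max(na + nb - 2, 1)
    if pooled == 0:
        return float("nan")
    return float((a.mean() - b.mean()) / np.sqrt(pooled))


def compare_determinants(
    records: pd.DataFrame,
    pcpa_genes: Iterable[str],
    ddr_genes: Iterable[str] | None = None,
    determinants: Sequence[str] = DETERMINANTS,
) -> pd.DataFrame:
    """Rank-sum p and Cohen's d per determinant, PCPA genes vs all genes.

    d > 0 means the determinant is larger in PCPA genes. When a DDR set is
    given, its median within the PCPA group is reported alongside.
    """
    pcpa = records.index.intersection(pd.Index(pcpa_genes))
    if pcpa.empty:
        raise ValueError("no PCPA genes among the records")
    ddr = (
        records.index.intersection(pd.Index(ddr_genes))
        if ddr_genes is not None
        else pd.Index([])
    )
    rows = []
    for det in determinants:
        if det not in records.columns:
            continue
        x_all = records[det].dropna()
        x_pcpa = records.loc[pcpa, det].dropna()
        if x_pcpa.empty or x_all.empty:
            continue
        p = stats.ranksums(x_all, x_pcpa).pvalue
        d = cohens_d(x_pcpa.to_numpy(), x_all.to_numpy())
        rows.append(
            {
                "determinant": det,
                "p_value": float(p),
                "cohens_d": d,
                "median_all": float(x_all.median()),
                "median_pcpa": float(x_pcpa.median()),
                "median_pcpa_ddr": float(
                    records.loc[pcpa.intersection(ddr), det].median()
                ) if len(pcpa.intersection(ddr)) else np.nan,
                "small_sample": min(len(x_pcpa), len(x_all)) < 10,
            }
        )
    return pd.DataFrame(rows).set_index("determinant")


@dataclass
class QuadraticFit:
    params: np.ndarray      # intercept, linear, quadratic
    bse: np.ndarray
    r_squared: float

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        return self.params[0] + self.params[1] * x + self.params[2] * x**2


def fit_quadratic(x: np.ndarray, y: np.ndarray) -> QuadraticFit:
    x = np.asarray(x, float)
    X = sm.add_constant(np.column_stack([x, x**2]))
    fit = sm.OLS(np.asarray(y, float), X).fit()
    return QuadraticFit(params=fit.params, bse=fit.bse, r_squared=fit.rsquared)


def pas_length_regression(
    records: pd.DataFrame,
    ddr_genes: Iterable[str],
    x_col: str = "length",
    y_col: str = "n_intronic_pas_sites",
) -> dict:
    """Quadratic fits of intronic poly(A) site count on length, all vs DDR.

    Fits y ~ 1 + x + x^2 on all genes and on DDR genes only, computes the
    per-DDR-gene difference of predictions (DDR model minus all-genes
    model) and a Wilcoxon signed-rank test on those differences.
    """
    if len(records) < 10:
        raise ValueError("need at least 10 genes for the regression")
    x = records[x_col].to_numpy(float)
    y = records[y_col].to_numpy(float)
    fit_all = fit_quadratic(x, y)
    ddr = records.index.intersection(pd.Index(ddr_genes))
    result = {"fit_all": fit_all, "fit_ddr": None, "differences": None,
              "wilcoxon_p": np.nan}
    if len(ddr) < 3:
        import warnings

        warnings.warn("fewer than 3 DDR genes; deviation test skipped")
        return result
    xd = records.loc[ddr, x_col].to_numpy(float)
    yd = records.loc[ddr, y_col].to_numpy(float)
    fit_ddr = fit_quadratic(xd, yd)
    diff = fit_ddr.predict(xd) - fit_all.predict(xd)
    result["fit_ddr"] = fit_ddr
    result["differences"] = pd.Series(diff, index=ddr)
    if np.any(diff != 0):
        result["wilcoxon_p"] = float(stats.wilcoxon(diff).pvalue)
    else:
        result["wilcoxon_p"] = 1.0
    return result


# ---------------------------------------------------------------------------
# splice-site PWMs
# ---------------------------------------------------------------------------


@dataclass
class SpliceSitePWM:
    """Donor (4x9) and acceptor (4x15) column-stochastic frequency matrices."""

    donor: np.ndarray
    acceptor: np.ndarray
    n_introns: int
    pseudocount: float = PWM_PSEUDOCOUNT
    background: float = PWM_BACKGROUND

    def score_site(self, seq: str, matrix: np.ndarray) -> float:
        if len(seq) != matrix.shape[1]:
            raise ValueError("sequence length does not match the matrix")
        total = 0.0
        for j, base in enumerate(seq):
            p = matrix[_BASE_INDEX.get(base, 0), j] if base in _BASE_INDEX else self.background
            total += np.log2(p / self.background)
        return float(total)

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        idx = list("ACGT")
        return (
            pd.DataFrame(self.donor, index=idx),
            pd.DataFrame(self.acceptor, index=idx),
        )


def _intron_windows(genome, chrom: str, start: int, end: int, strand: str
                    ) -> tuple[str, str]:
    """(donor 9-mer, acceptor 15-mer) in transcription sense for one intron."""
    src = _SeqSource(genome)
    if strand == "+":
        donor = src.fetch(chrom, start - 3, start + 6)
        acceptor = src.fetch(chrom, end - ACCEPTOR_WIDTH, end)
    else:
        donor = revcomp(src.fetch(chrom, end - 6, end + 3))
        acceptor = revcomp(src.fetch(chrom, start, start + ACCEPTOR_WIDTH))
    return donor, acceptor


def build_splice_pwms(
    introns: Sequence[tuple[str, int, int, str]],
    genome,
    min_introns: int = 20,
    pseudocount: float = PWM_PSEUDOCOUNT,
) -> SpliceSitePWM:
    """Position weight matrices from all introns with canonical GT..AG ends.

    ``introns`` are (chrom, start, end, strand) tuples, 0-based half-open in
    genome coordinates. Donors contribute a 9-mer (last 3 exonic bases +
    first 6 intronic; GT fixed at intron positions +1,+2), acceptors the
    15-mer ending at the intron's last base (..AG). Column frequencies use
    a pseudocount of 0.5 per base.
    """
    donor_counts = np.zeros((4, DONOR_WIDTH))
    acceptor_counts = np.zeros((4, ACCEPTOR_WIDTH))
    n = 0
    for chrom, start, end, strand in introns:
        donor, acceptor = _intron_windows(genome, chrom, start, end, strand)
        if len(donor) != DONOR_WIDTH or len(acceptor) != ACCEPTOR_WIDTH:
            continue
        if donor[3:5] != "GT" or acceptor[-2:] != "AG":
            continue
        for j, base in enumerate(donor):
            if base in _BASE_INDEX:
                donor_counts[_BASE_INDEX[base], j] += 1
        for j, base in enumerate(acceptor):
            if base in _BASE_INDEX:
                acceptor_counts[_BASE_INDEX[base], j] += 1
        n += 1
    if n < min_introns:
        raise ValueError(f"only {n} canonical GT..AG introns; need {min_introns}")
    donor_freq = (donor_counts + pseudocount) / (donor_counts + pseudocount).sum(axis=0)
    acceptor_freq = (acceptor_counts + pseudocount) / (acceptor_counts + pseudocount).sum(axis=0)
    return SpliceSitePWM(donor=donor_freq, acceptor=acceptor_freq, n_introns=n,
                         pseudocount=pseudocount)


def score_introns(
    introns: Sequence[tuple[str, int, int, str]],
    pwms: SpliceSitePWM,
    genome,
    has_intronic_pas: Iterable[bool] | None = None,
    min_intron_length: int = 24,
) -> pd.DataFrame:
    """Combined donor+acceptor log-odds score per intron.

    Introns shorter than ``min_intron_length`` (donor and acceptor windows
    would overlap) are excluded and counted in the ``excluded`` attribute of
    the returned frame. With a ``has_intronic_pas`` flag vector the frame
    carries a group column for the with/without-PAS comparison.
    """
    flags = list(has_intronic_pas) if has_intronic_pas is not None else None
    rows = []
    excluded = 0
    for i, (chrom, start, end, strand) in enumerate(introns):
        if end - start < min_intron_length:
            excluded += 1
            continue
        donor, acceptor = _intron_windows(genome, chrom, start, end, strand)
        if len(donor) != DONOR_WIDTH or len(acceptor) != ACCEPTOR_WIDTH:
            excluded += 1
            continue
        score = pwms.score_site(donor, pwms.donor) + pwms.score_site(
            acceptor, pwms.acceptor
        )
        rows.append(
            {"chrom": chrom, "start": start, "end": end, "strand": strand,
             "score": score,
             "has_pas": bool(flags[i]) if flags is not None else False}
        )
    out = pd.DataFrame(rows)
    out.attrs["excluded"] = excluded
    return out


def compare_intron_scores(scored: pd.DataFrame) -> dict:
    """Rank-sum + Cohen's d between introns with and without intronic PAS."""
    with_pas = scored.loc[scored["has_pas"], "score"].to_numpy()
    without = scored.loc[~scored["has_pas"], "score"].to_numpy()
    if with_pas.size == 0 or without.size == 0:
        return {"p_value": np.nan, "cohens_d": np.nan,
                "n_with": int(with_pas.size), "n_without": int(without.size)}
    return {
        "p_value": float(stats.ranksums(with_pas, without).pvalue),
        "cohens_d": cohens_d(with_pas, without),
        "n_with": int(with_pas.size),
        "n_without": int(without.size),
    }
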