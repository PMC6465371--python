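"""Per-gene statistics: intron retention, PCPA scores, usage odds, expression.

The central quantities:

* IR index = log2(intron ratio / exon ratio), where each ratio is
  (treated coverage + 1)/(control coverage + 1) over the gene's reduced
  intronic or exonic territory. Retention: adjusted p < 0.05 and IR > 1;
  loss: adjusted p < 0.05 and IR < -1 (Fisher's exact test on the 2x2
  count table, Benjamini-Hochberg adjusted).
* exon-score = last-exon log2(treated/control) minus first-exon
  log2(treated/control); iQ-score = log2(iQ1/iQ4) of treated reads in the
  first vs last quarter of the internal region between the first 5' splice
  site and the last 3' splice site. A gene undergoes PCPA when
  exon-score < -1 and iQ-score > 1.
* Intronic poly(A) usage odds ratio per gene:
  [(intronic+0.5)/(3'UTR+0.5)]_treated / [(intronic+0.5)/(3'UTR+0.5)]_control.
* Differential expression by a negative-binomial Wald test on size-factor
  normalised exonic counts (|log2FC| > 1 and adjusted p < 0.1).
* Aggregated gene-set shift as a permutation z-score against equal-sized
  random sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .annotation import GeneModel, subtract_intervals
from .coverage import CoverageTrack

IR_MIN_EXON_READS = 10
IR_MIN_INTRON_READS = 5
IR_INDEX_THRESHOLD = 1.0
IR_ALPHA = 0.05
EXON_SCORE_THRESHOLD = -1.0
IQ_SCORE_THRESHOLD = 1.0
DE_LFC_THRESHOLD = 1.0
DE_ALPHA = 0.1


# ---------------------------------------------------------------------------
# counting helpers
# ---------------------------------------------------------------------------


def gene_region_counts(
    track: CoverageTrack, gene: GeneModel
) -> dict[str, int]:
    """Integer read counts over the reduced exonic/intronic territory plus
    the first/last exon and the internal iQ quarters (transcription order)."""
    exon = sum(track.region_sum(gene.chrom, s, e) for s, e in gene.exons)
    intron = sum(track.region_sum(gene.chrom, s, e) for s, e in gene.introns)
    stranded = gene.exons_stranded()
    first = track.region_sum(gene.chrom, *stranded[0])
    last = track.region_sum(gene.chrom, *stranded[-1])
    out = {
        "exon": int(round(exon)),
        "intron": int(round(intron)),
        "first_exon": int(round(first)),
        "last_exon": int(round(last)),
        "iq1": 0,
        "iq4": 0,
    }
    if len(gene.exons) >= 2:
        # internal region: first 5' splice site to last 3' splice site
        region_start = gene.exons[0][1]
        region_end = gene.exons[-1][0]
        span = region_end - region_start
        q = span / 4.0
        quarters = [
            (region_start, int(round(region_start + q))),
            (int(round(region_end - q)), region_end),
        ]
        iq1_iv, iq4_iv = quarters if gene.strand == "+" else quarters[::-1]
        out["iq1"] = int(round(track.region_sum(gene.chrom, *iq1_iv)))
        out["iq4"] = int(round(track.region_sum(gene.chrom, *iq4_iv)))
    return out


# ---------------------------------------------------------------------------
# intron retention
# ---------------------------------------------------------------------------


def intron_retention_index(
    counts: pd.DataFrame,
    min_exon_reads: int = IR_MIN_EXON_READS,
    min_intron_reads: int = IR_MIN_INTRON_READS,
    index_threshold: float = IR_INDEX_THRESHOLD,
    alpha: float = IR_ALPHA,
) -> pd.DataFrame:
    """IR index, class and BH-adjusted Fisher p per gene.

    ``counts`` must carry integer columns ``exon_treated, exon_control,
    intron_treated, intron_control`` indexed by gene. Genes with fewer than
    ``min_exon_reads`` exonic reads in both conditions, or fewer than
    ``min_intron_reads`` intronic reads in both, are untested (class
    ``none``, index NaN).
    """
    cols = ["exon_treated", "exon_control", "intron_treated", "intron_control"]
    c = counts[cols].astype(float)
    if (c < 0).any().any():
        raise ValueError("negative counts")
    exon_ratio = (c["exon_treated"] + 1) / (c["exon_control"] + 1)
    intron_ratio = (c["intron_treated"] + 1) / (c["intron_control"] + 1)
    ir = np.log2(intron_ratio / exon_ratio)
    tested = (
        (c[["exon_treated", "exon_control"]].max(axis=1) >= min_exon_reads)
        & (c[["intron_treated", "intron_control"]].max(axis=1) >= min_intron_reads)
    )
    pvals = pd.Series(np.nan, index=counts.index)
    for gid in counts.index[tested]:
        table = [
            [c.at[gid, "exon_treated"], c.at[gid, "intron_treated"]],
            [c.at[gid, "exon_control"], c.at[gid, "intron_control"]],
        ]
        pvals.at[gid] = stats.fisher_exact(np.asarray(table, int)).pvalue
    padj = pd.Series(np.nan, index=counts.index)
    if tested.any():
        padj[tested] = multipletests(pvals[tested], method="fdr_bh")[1]
    out = pd.DataFrame(index=counts.index)
    out["ir_index"] = np.where(tested, ir, np.nan)
    out["ir_p_adj"] = padj
    out["ir_class"] = "none"
    sig = tested & (padj < alpha)
    out.loc[sig & (ir > index_threshold), "ir_class"] = "retention"
    out.loc[sig & (ir < -index_threshold), "ir_class"] = "loss"
    return out


# ---------------------------------------------------------------------------
# PCPA call
# ---------------------------------------------------------------------------


def pcpa_call(
    counts: pd.DataFrame,
    pseudocount: float = 1.0,
    exon_score_threshold: float = EXON_SCORE_THRESHOLD,
    iq_score_threshold: float = IQ_SCORE_THRESHOLD,
) -> pd.DataFrame:
    """Exon-score, iQ-score and the PCPA flag per gene.

    ``counts`` columns: ``first_treated, first_control, last_treated,
    last_control, iq1, iq4`` and optionally boolean ``assessable`` (genes
    with a single exon have no internal region and are never called).
    """
    c = counts.astype(
        {k: float for k in
         ("first_treated", "first_control", "last_treated", "last_control",
          "iq1", "iq4")}
    )
    pc = pseudocount
    exon_score = np.log2((c["last_treated"] + pc) / (c["last_control"] + pc)) - np.log2(
        (c["first_treated"] + pc) / (c["first_control"] + pc)
    )
    iq_score = np.log2((c["iq1"] + pc) / (c["iq4"] + pc))
    assessable = (
        counts["assessable"].astype(bool)
        if "assessable" in counts.columns
        else pd.Series(True, index=counts.index)
    )
    out = pd.DataFrame(index=counts.index)
    out["exon_score"] = exon_score
    out["iq_score"] = iq_score
    out["assessable"] = assessable
    out["pcpa"] = (
        assessable
        & (exon_score < exon_score_threshold)
        & (iq_score > iq_score_threshold)
    )
    return out


# ---------------------------------------------------------------------------
# intronic polyadenylation usage
# ---------------------------------------------------------------------------


def intronic_usage_or(
    peak_counts: pd.DataFrame,
    tpm: Mapping[str, float] | pd.Series | None = None,
    tpm_min: float = 1.0,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Odds ratio of intronic vs 3'UTR poly(A) usage, treated over control.

    ``peak_counts`` is indexed by gene with columns ``intronic_treated,
    intronic_control, utr_treated, utr_control`` (summed peak reads).
    Genes with zero intronic reads in both conditions are excluded; with a
    ``tpm`` mapping, genes at or below ``tpm_min`` are removed entirely.
    """
    df = peak_counts.copy()
    if tpm is not None:
        tpm = pd.Series(tpm)
        df = df[df.index.map(lambda g: tpm.get(g, 0.0) > tpm_min)]
    if df.empty:
        raise ValueError("no eligible genes for usage odds ratios")
    c = df.astype(float)
    pc = pseudocount
    odds_t = (c["intronic_treated"] + pc) / (c["utr_treated"] + pc)
    odds_c = (c["intronic_control"] + pc) / (c["utr_control"] + pc)
    out = pd.DataFrame(index=df.index)
    out["odds_ratio"] = odds_t / odds_c
    out["odds_treated"] = odds_t
    out["odds_control"] = odds_c
    out["excluded"] = (c["intronic_treated"] == 0) & (c["intronic_control"] == 0)
    return out


def compare_or_distributions(
    or_a: Sequence[float], or_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test between odds-ratio distributions."""
    res = stats.ks_2samp(np.asarray(or_a), np.asarray(or_b))
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------


def differential_expression(
    counts: pd.DataFrame,
    condition: Mapping[str, str],
    size_factors: Mapping[str, float] | pd.Series | None = None,
    lfc_threshold: float = DE_LFC_THRESHOLD,
    alpha: float = DE_ALPHA,
    min_total_reads: int = 10,
) -> pd.DataFrame:
    """Negative-binomial Wald test per gene on normalised counts.

    ``counts`` is genes x samples; ``condition`` maps sample to
    'control'/'treated'. The gene-wise dispersion is estimated by the
    method of moments and stabilised with the cohort median. Genes whose
    total raw count falls below ``min_total_reads`` are reported not
    significant regardless of fold change.
    """
    samples = list(counts.columns)
    treated = [s for s in samples if condition[s] == "treated"]
    control = [s for s in samples if condition[s] == "control"]
    if not treated or not control:
        raise ValueError("both conditions need at least one replicate")
    sf = (
        pd.Series({s: 1.0 for s in samples})
        if size_factors is None
        else pd.Series(size_factors)
    )
    norm = counts / sf[samples]
    mu_t = norm[treated].mean(axis=1)
    mu_c = norm[control].mean(axis=1)
    lfc = np.log2((mu_t + 0.5) / (mu_c + 0.5))

    # method-of-moments dispersion, pooled across conditions and stabilised
    def _disp(sub: pd.DataFrame) -> pd.Series:
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1) if sub.shape[1] > 1 else pd.Series(0.0, index=sub.index)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (v - m) / m**2
        return a.replace([np.inf, -np.inf], np.nan)

    disp = pd.concat([_disp(norm[treated]), _disp(norm[control])], axis=1).mean(axis=1)
    informative = disp[(norm.mean(axis=1) > 5) & disp.notna() & (disp > 0)]
    common = float(informative.median()) if len(informative) else 0.01
    alpha_g = np.maximum(disp.fillna(common).clip(lower=0.0), common)

    nt, nc = len(treated), len(control)
    ln2sq = np.log(2.0) ** 2
    var_log2 = (
        (1.0 / np.maximum(mu_t, 0.5) + alpha_g) / nt
        + (1.0 / np.maximum(mu_c, 0.5) + alpha_g) / nc
    ) / ln2sq
    se = np.sqrt(var_log2)
    z = lfc / se
    pval = 2.0 * stats.norm.sf(np.abs(z))
    padj = multipletests(pval, method="fdr_bh")[1]
    out = pd.DataFrame(index=counts.index)
    out["log2fc"] = lfc
    out["de_p"] = pval
    out["de_p_adj"] = padj
    low = counts.sum(axis=1) < min_total_reads
    out["de_significant"] = (
        (np.abs(lfc) > lfc_threshold) & (out["de_p_adj"] < alpha) & ~low
    )
    return out


def build_flanking_windows(
    genes: Mapping[str, GeneModel],
    offset: int = 50,
    width: int = 2000,
    min_length: int = 200,
) -> pd.DataFrame:
    """Strand-aware upstream/downstream 2 kb flanks with same-strand genes cut out.

    Upstream: -offset-width..-offset of the TSS; downstream: +offset..
    +offset+width of the TES, both along the transcription direction.
    Fragments shorter than ``min_length`` after subtracting overlapping
    same-strand gene spans are dropped.
    """
    rows = []
    by_key: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for g in genes.values():
        by_key.setdefault((g.chrom, g.strand), []).append((g.start, g.end))
    for gid, g in genes.items():
        if g.strand == "+":
            windows = {
                "upstream": (g.start - offset - width, g.start - offset),
                "downstream": (g.end + offset, g.end + offset + width),
            }
        else:
            windows = {
                "upstream": (g.end + offset, g.end + offset + width),
                "downstream": (g.start - offset - width, g.start - offset),
            }
        blockers = [
            iv for iv in by_key[(g.chrom, g.strand)] if iv != (g.start, g.end)
        ]
        for side, win in windows.items():
            for fs, fe in subtract_intervals(win, blockers):
                if fe - fs >= min_length and fs >= 0:
                    rows.append(
                        {"gene_id": gid, "side": side, "chrom": g.chrom,
                         "start": fs, "end": fe, "strand": g.strand}
                    )
    return pd.DataFrame(rows, columns=["gene_id", "side", "chrom", "start", "end", "strand"])


# ---------------------------------------------------------------------------
# gene-set shift
# ---------------------------------------------------------------------------


def geneset_zscore(
    changes: pd.Series,
    gene_set: Iterable[str],
    n_random: int = 1000,
    seed: int = 0,
) -> float:
    """z-score of the set's mean expression change against random sets.

    The null is ``n_random`` equal-sized gene sets drawn uniformly without
    replacement from all scored genes.
    """
    members = [g for g in gene_set if g in changes.index]
    if not members:
        raise ValueError("gene set has no overlap with scored genes")
    if len(members) > len(changes) // 2:
        raise ValueError("gene set larger than half the scored universe")
    rng = np.random.default_rng(seed)
    vals = changes.to_numpy(float)
    set_mean = float(changes[members].mean())
    k = len(members)
    null = np.array(
        [vals[rng.choice(vals.size, size=k, replace=False)].mean()
         for _ in range(n_random)]
    )
    sd = null.std(ddof=1)
    if sd == 0:
        return 0.0
    return float((set_mean - null.mean()) / sd)


# ---------------------------------------------------------------------------
# length / fold-change relation
# ---------------------------------------------------------------------------


def length_expression_correlation(
    log2fc: pd.Series, lengths: pd.Series, loess_frac: float = 0.3
) -> tuple[float, float, pd.DataFrame]:
    """Spearman correlation of log2 length vs fold change, with a smooth.

    Returns ``(rho, pvalue, smooth)``; rho is NaN when either variable is
    constant. The smooth is a loess curve over log2 length for reporting.
    """
    common = log2fc.index.intersection(lengths.index)
    if len(common) < 10:
        raise ValueError("need at least 10 genes")
    x = np.log2(lengths[common].to_numpy(float))
    y = log2fc[common].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan"), pd.DataFrame({"log2_length": x, "smooth": y})
    rho, p = stats.spearmanr(x, y)
    order = np.argsort(x)
    sm = lowess(y[order], x[order], frac=loess_frac, return_sorted=False)
    smooth = pd.DataFrame({"log2_length": x[order], "smooth": sm})
    return float(rho), float(p), smooth
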