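"""End-to-end orchestration: simulate -> annotate -> coverage -> peaks -> scores.

`run_pipeline` drives the full analysis from a single config mapping and
writes one TSV per result table under the output directory, plus a YAML run
log echoing every threshold and seed. Outputs are deterministic given the
config and seed. Each stage reads only files written by earlier stages, so
reruns reproduce results byte for byte.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import annotation as ann
from . import coverage as cov
from . import determinants as det
from . import polya
from . import scores as sc
from . import simulate as sim

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "simulate": {},          # SimulationConfig overrides; None disables simulation
    "paths": {},             # used instead of simulation outputs when simulate is None
    "tt_bin": 100,
    "dynamics_bin": 50,
    "flank_bp": 2000,
    "dynamics_window": [-500, 10000],
    "loess_span": 0.2,
    "gene_tpm_min": 2.0,
    "frac_min": 0.2,
    "rescue_tpm": 5.0,
    "ir_index_threshold": 1.0,
    "ir_alpha": 0.05,
    "ir_min_exon_reads": 10,
    "ir_min_intron_reads": 5,
    "exon_score_threshold": -1.0,
    "iq_score_threshold": 1.0,
    "pcpa_pseudocount": 1.0,
    "de_lfc_threshold": 1.0,
    "de_alpha": 0.1,
    "peak_min_qscore": 5.0,
    "peak_min_reads": 64,
    "peak_log_ratio_threshold": 1.0,
    "usage_tpm_min": 1.0,
    "n_random_sets": 1000,
    "top_n_peaks": 5000,
}


def load_config(path: str | Path | None = None, **overrides) -> dict:
    cfg = dict(DEFAULT_CONFIG)
    user: dict = {}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
    user.update(overrides)
    unknown = set(user) - set(cfg) - {"outdir"}
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg.update(user)
    return cfg


def run_pipeline(config: Mapping[str, Any], outdir: str | Path) -> dict[str, Any]:
    """Run every stage and write the result bundle under ``outdir``."""
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])

    # ---------------- stage 0: inputs (simulated or provided) --------------
    if cfg["simulate"] is not None:
        sim_cfg = sim.SimulationConfig(seed=seed, **cfg["simulate"])
        sim_dir = outdir / "sim"
        manifest = sim.simulate_all(sim_cfg, sim_dir)
        paths = {
            "gtf": manifest["gtf"],
            "fasta": manifest["fasta"],
            "abundance": manifest["abundance"],
            "spikeins": manifest["spikeins"],
            "peaks": manifest["peaks"],
            "ddr": manifest["ddr"],
            "coverage": {
                s: {st: str(p) for st, p in d.items()}
                for s, d in manifest["coverage"].items()
            },
        }
    else:
        paths = dict(cfg["paths"])
        for key in ("gtf", "fasta", "abundance", "spikeins", "peaks", "ddr"):
            if key not in paths or not Path(paths[key]).exists():
                raise FileNotFoundError(
                    f"pipeline input {key!r} missing: {paths.get(key)}"
                )

    import pyfaidx

    genome = pyfaidx.Fasta(str(paths["fasta"]))
    seq_lengths = {name: len(genome[name]) for name in genome.keys()}

    # ---------------- stage 1: annotation ----------------------------------
    exon_table = ann.read_gtf(paths["gtf"])
    quant = pd.read_csv(paths["abundance"], sep="\t")
    retained = ann.select_transcripts(
        quant,
        gene_tpm_min=cfg["gene_tpm_min"],
        frac_min=cfg["frac_min"],
        rescue_tpm=cfg["rescue_tpm"],
    )
    models = ann.build_gene_models(exon_table, retained_transcripts=retained)
    biotype_groups = ann.classify_biotypes(
        {g: m.biotype for g, m in models.items()},
        {g: m.length for g, m in models.items()},
    )
    pc_lengths = {
        g: m.length for g, m in models.items()
        if biotype_groups[g] == "protein_coding"
    }
    length_classes, boundaries = ann.stratify_lengths(pc_lengths)
    for gid, m in models.items():
        m.biotype_group = biotype_groups[gid]
        m.length_class = length_classes.get(gid)
    ann.write_gene_models(
        models, outdir / "gene_models.bed12", outdir / "gene_models.tsv"
    )
    ddr_set, n_unmatched = ann.load_gene_set(
        [paths["ddr"]], set(models), name="ddr"
    )
    gene_tpm = quant.groupby("gene_id")["tpm"].sum()

    # ---------------- stage 2: coverage ------------------------------------
    spikeins = pd.read_csv(paths["spikeins"], sep="\t", index_col=0)
    size_factors = cov.estimate_size_factors(spikeins)
    size_factors.rename("size_factor").to_csv(outdir / "size_factors.tsv", sep="\t")

    samples = list(paths["coverage"])
    condition = {
        s: ("control" if s.startswith("control") else "treated") for s in samples
    }
    raw_tracks: dict[str, dict[str, cov.CoverageTrack]] = {}
    norm_tracks: dict[str, dict[str, cov.CoverageTrack]] = {}
    fine_tracks: dict[str, dict[str, cov.CoverageTrack]] = {}
    for s in samples:
        raw_tracks[s], norm_tracks[s], fine_tracks[s] = {}, {}, {}
        for strand in "+-":
            bg = cov.read_bedgraph(paths["coverage"][s][strand])
            raw_tracks[s][strand] = cov.bin_coverage(
                bg, seq_lengths, cfg["tt_bin"], strand,
                size_factor=1.0, sample_id=s, condition=condition[s],
            )
            norm_tracks[s][strand] = cov.bin_coverage(
                bg, seq_lengths, cfg["tt_bin"], strand,
                size_factor=float(size_factors[s]), sample_id=s,
                condition=condition[s],
            )
            fine_tracks[s][strand] = cov.bin_coverage(
                bg, seq_lengths, cfg["dynamics_bin"], strand,
                size_factor=float(size_factors[s]), sample_id=s,
                condition=condition[s],
            )

    rep_corr = cov.replicate_correlation(
        [norm_tracks[s]["+"] for s in samples]
    )
    rep_corr.to_csv(outdir / "replicate_correlation.tsv", sep="\t")

    merged: dict[str, dict[str, cov.CoverageTrack]] = {}
    merged_fine: dict[str, dict[str, cov.CoverageTrack]] = {}
    for cond in ("control", "treated"):
        reps = [s for s in samples if condition[s] == cond]
        merged[cond] = {
            st: cov.merge_tracks([norm_tracks[s][st] for s in reps], sample_id=cond)
            for st in "+-"
        }
        merged_fine[cond] = {
            st: cov.merge_tracks([fine_tracks[s][st] for s in reps], sample_id=cond)
            for st in "+-"
        }

    meta_control = cov.metagene_profile(
        merged["control"], models.values(), flank_bp=cfg["flank_bp"]
    )
    meta_treated = cov.metagene_profile(
        merged["treated"], models.values(), flank_bp=cfg["flank_bp"]
    )
    meta = meta_control.to_frame().rename(
        columns={"sense": "control_sense", "antisense": "control_antisense"}
    )
    mt = meta_treated.to_frame()
    meta["treated_sense"] = mt["sense"]
    meta["treated_antisense"] = mt["antisense"]
    meta.to_csv(outdir / "metagene.tsv", sep="\t", index=False)

    up, down = cfg["dynamics_window"]
    dyn = cov.tss_dynamics(
        merged_fine["control"], merged_fine["treated"], models.values(),
        upstream=-up, downstream=down, loess_frac=cfg["loess_span"],
    )
    pd.DataFrame(
        {
            "bin_center": dyn.bin_centers,
            "change": dyn.change,
            "rate": np.concatenate([[np.nan], dyn.rate]),
            "rate_rescaled": np.concatenate([[np.nan], dyn.rate_rescaled]),
            "change_smooth": dyn.change_smooth,
        }
    ).to_csv(outdir / "tss_dynamics.tsv", sep="\t", index=False)

    # ---------------- stage 3: poly(A) peaks -------------------------------
    peaks = polya.read_peaks(paths["peaks"])
    retained_peaks, removed_peaks = polya.filter_internal_priming(peaks, genome)
    annotated = polya.annotate_peaks(retained_peaks, models)
    annotated.to_csv(outdir / "peaks_annotated.tsv", sep="\t", index=False)
    removed_peaks.to_csv(outdir / "peaks_removed.tsv", sep="\t", index=False)

    treated_cols = [s for s in samples if condition[s] == "treated"]
    control_cols = [s for s in samples if condition[s] == "control"]
    t_spec, c_spec, unchanged = polya.differential_peaks(
        annotated, treated_cols, control_cols,
        min_qscore=cfg["peak_min_qscore"],
        min_reads=cfg["peak_min_reads"],
        log_ratio_threshold=cfg["peak_log_ratio_threshold"],
    )
    t_spec.assign(specific="treated").to_csv(
        outdir / "peaks_treated_specific.tsv", sep="\t", index=False
    )
    c_spec.assign(specific="control").to_csv(
        outdir / "peaks_control_specific.tsv", sep="\t", index=False
    )
    dist = polya.peak_region_distribution(
        annotated, samples, top_n=min(cfg["top_n_peaks"], len(annotated))
    )
    dist.to_csv(outdir / "peak_region_distribution.tsv", sep="\t")

    # ---------------- stage 4: per-gene scores -----------------------------
    region_counts = {}
    for cond in ("control", "treated"):
        for gid, m in models.items():
            counts = sc.gene_region_counts(merged[cond][m.strand], m)
            region_counts.setdefault(gid, {}).update(
                {f"{k}_{cond}": v for k, v in counts.items()}
            )
    rc = pd.DataFrame.from_dict(region_counts, orient="index")

    ir = sc.intron_retention_index(
        rc.rename(
            columns={
                "exon_treated": "exon_treated", "exon_control": "exon_control",
                "intron_treated": "intron_treated",
                "intron_control": "intron_control",
            }
        ),
        min_exon_reads=cfg["ir_min_exon_reads"],
        min_intron_reads=cfg["ir_min_intron_reads"],
        index_threshold=cfg["ir_index_threshold"],
        alpha=cfg["ir_alpha"],
    )

    pcpa_counts = pd.DataFrame(
        {
            "first_treated": rc["first_exon_treated"],
            "first_control": rc["first_exon_control"],
            "last_treated": rc["last_exon_treated"],
            "last_control": rc["last_exon_control"],
            "iq1": rc["iq1_treated"],
            "iq4": rc["iq4_treated"],
            "assessable": [len(models[g].exons) >= 2 for g in rc.index],
        },
        index=rc.index,
    )
    pcpa = sc.pcpa_call(
        pcpa_counts,
        pseudocount=cfg["pcpa_pseudocount"],
        exon_score_threshold=cfg["exon_score_threshold"],
        iq_score_threshold=cfg["iq_score_threshold"],
    )

    # usage odds ratios from annotated peaks
    genic = annotated[annotated["category"].isin(["intron", "tes_utr"])]
    usage_rows = {}
    for gid, sub in genic.groupby("gene_id"):
        intronic = sub[sub["category"] == "intron"]
        utr = sub[sub["category"] == "tes_utr"]
        usage_rows[gid] = {
            "intronic_treated": intronic[treated_cols].to_numpy().sum(),
            "intronic_control": intronic[control_cols].to_numpy().sum(),
            "utr_treated": utr[treated_cols].to_numpy().sum(),
            "utr_control": utr[control_cols].to_numpy().sum(),
        }
    usage_counts = pd.DataFrame.from_dict(usage_rows, orient="index")
    usage = sc.intronic_usage_or(
        usage_counts, tpm=gene_tpm, tpm_min=cfg["usage_tpm_min"]
    )
    usage.to_csv(outdir / "usage_odds.tsv", sep="\t")

    # differential expression on per-replicate exonic counts
    de_counts = pd.DataFrame(
        {
            s: {
                gid: int(round(sum(
                    raw_tracks[s][m.strand].region_sum(m.chrom, a, b)
                    for a, b in m.exons
                )))
                for gid, m in models.items()
            }
            for s in samples
        }
    )
    de = sc.differential_expression(
        de_counts, condition, size_factors,
        lfc_threshold=cfg["de_lfc_threshold"], alpha=cfg["de_alpha"],
    )

    flanks = sc.build_flanking_windows(models)
    flanks.to_csv(outdir / "flanking_windows.tsv", sep="\t", index=False)

    ddr_z = sc.geneset_zscore(
        de["log2fc"].dropna(), ddr_set.members,
        n_random=cfg["n_random_sets"], seed=seed,
    )
    lengths = pd.Series({g: m.length for g, m in models.items()})
    rho, rho_p, smooth = sc.length_expression_correlation(de["log2fc"], lengths)
    smooth.to_csv(outdir / "length_lfc_smooth.tsv", sep="\t", index=False)

    # ---------------- stage 5: determinants --------------------------------
    records = det.compute_determinants(
        models, genome, expression=gene_tpm, annotated_peaks=annotated
    )
    records.to_csv(outdir / "determinant_records.tsv", sep="\t")
    pcpa_set = set(pcpa.index[pcpa["pcpa"]])
    if pcpa_set:
        tests = det.compare_determinants(records, pcpa_set, ddr_set.members)
        tests.to_csv(outdir / "determinant_tests.tsv", sep="\t")
    else:
        tests = pd.DataFrame()
    reg = det.pas_length_regression(records, ddr_set.members)

    all_introns = [
        (m.chrom, s, e, m.strand) for m in models.values() for s, e in m.introns
    ]
    intron_pas_pos = set(
        zip(annotated.loc[annotated["category"] == "intron", "chrom"],
            polya.peak_positions(annotated[annotated["category"] == "intron"]))
    )
    has_pas = [
        any(c == chrom and s <= p < e for c, p in intron_pas_pos)
        for chrom, s, e, _ in all_introns
    ]
    pwm_result: dict[str, Any] = {}
    try:
        pwms = det.build_splice_pwms(all_introns, genome)
        donor_df, acceptor_df = pwms.to_frames()
        donor_df.to_csv(outdir / "pwm_donor.tsv", sep="\t")
        acceptor_df.to_csv(outdir / "pwm_acceptor.tsv", sep="\t")
        intron_scores = det.score_introns(all_introns, pwms, genome, has_pas)
        intron_scores.to_csv(outdir / "intron_scores.tsv", sep="\t", index=False)
        pwm_result = det.compare_intron_scores(intron_scores)
    except ValueError as exc:
        logger.warning("splice PWM stage skipped: %s", exc)

    # ---------------- report -----------------------------------------------
    master = pd.DataFrame(index=sorted(models))
    master.index.name = "gene_id"
    master["length"] = [models[g].length for g in master.index]
    master["length_class"] = [models[g].length_class for g in master.index]
    master["biotype_group"] = [models[g].biotype_group for g in master.index]
    for frame in (ir, pcpa, de):
        master = master.join(frame)
    master = master.join(usage[["odds_ratio"]])
    master = master.join(records[["u1_pas_ratio", "n_intronic_pas_sites",
                                  "gc_fraction"]])
    master.to_csv(outdir / "gene_scores.tsv", sep="\t")

    summary = {
        "n_genes": len(models),
        "n_pcpa": int(pcpa["pcpa"].sum()),
        "n_ir_retention": int((ir["ir_class"] == "retention").sum()),
        "n_ir_loss": int((ir["ir_class"] == "loss").sum()),
        "n_de_significant": int(de["de_significant"].sum()),
        "n_peaks_removed": len(removed_peaks),
        "n_peaks_retained": len(annotated),
        "ddr_zscore": float(ddr_z),
        "length_lfc_spearman": float(rho),
        "ddr_unmatched_ids": n_unmatched,
        "pas_length_wilcoxon_p": float(reg["wilcoxon_p"]),
        "intron_score_comparison": {
            k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
            for k, v in pwm_result.items()
        },
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)

    schema = {
        "gene_scores.tsv": {
            "gene_id": "gene identifier",
            "length": "reduced gene span length (bp)",
            "ir_index": "log2 intron/exon coverage-change ratio",
            "ir_class": "loss / retention / none",
            "ir_p_adj": "BH-adjusted Fisher p for the IR table",
            "exon_score": "last-minus-first exon log2 fold change",
            "iq_score": "log2 iQ1/iQ4 treated reads",
            "pcpa": "premature cleavage and polyadenylation call",
            "log2fc": "differential expression log2 fold change",
            "de_p_adj": "BH-adjusted Wald p",
            "de_significant": "|log2fc|>1 and adjusted p<0.1",
            "odds_ratio": "intronic vs 3'UTR usage OR, treated/control",
            "u1_pas_ratio": "(U1 motifs+1)/(PAS motifs+1) over the gene body",
            "n_intronic_pas_sites": "annotated intronic poly(A) peaks",
            "gc_fraction": "GC content TSS..TES",
        }
    }
    with open(outdir / "schema.json", "w") as fh:
        json.dump(schema, fh, indent=2, sort_keys=True)

    run_log = {
        "seed": seed,
        "thresholds": {
            k: cfg[k] for k in sorted(DEFAULT_CONFIG) if k not in ("paths", "simulate")
        },
        "boundaries_bp": boundaries,
        "size_factors": {k: float(v) for k, v in size_factors.items()},
    }
    with open(outdir / "run_log.yaml", "w") as fh:
        yaml.safe_dump(run_log, fh, sort_keys=True)

    return {
        "models": models,
        "boundaries": boundaries,
        "size_factors": size_factors,
        "replicate_correlation": rep_corr,
        "metagene": {"control": meta_control, "treated": meta_treated},
        "dynamics": dyn,
        "peaks_annotated": annotated,
        "peaks_removed": removed_peaks,
        "differential_peaks": (t_spec, c_spec, unchanged),
        "region_distribution": dist,
        "ir": ir,
        "pcpa": pcpa,
        "usage": usage,
        "de": de,
        "ddr_zscore": ddr_z,
        "length_lfc": (rho, rho_p),
        "determinants": records,
        "determinant_tests": tests,
        "pas_length_regression": reg,
        "intron_score_comparison": pwm_result,
        "summary": summary,
        "master": master,
        "paths": paths,
    }
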