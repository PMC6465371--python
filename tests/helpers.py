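"""Shared utilities for building analysis inputs from simulations."""

from __future__ import annotations

import pandas as pd

from pcpakit import coverage as cov
from pcpakit import scores as sc
from pcpakit.annotation import GeneModel
from pcpakit.simulate import CHROM, Simulation, simulate_tt_coverage


def models_from_sim(sim: Simulation) -> dict[str, GeneModel]:
    """Reduced gene models straight from the generator's structures."""
    out = {}
    for g in sim.genes:
        exons = sorted(g.g_iv(a, b) for a, b in g.exons_sense)
        out[g.gene_id] = GeneModel(
            g.gene_id, CHROM, g.strand, g.start, g.end, exons
        )
    return out


def merged_condition_tracks(
    sim: Simulation, outdir, bin_size: int = 100
) -> dict[str, dict[str, cov.CoverageTrack]]:
    """Simulate coverage and return replicate-merged tracks per condition."""
    paths, _ = simulate_tt_coverage(sim, outdir)
    merged = {}
    for cond in ("control", "treated"):
        reps = [s for s in sim.config.samples if s.startswith(cond)]
        merged[cond] = {
            st: cov.merge_tracks(
                [
                    cov.bin_coverage(
                        cov.read_bedgraph(paths[s][st]),
                        sim.seq_lengths, bin_size, st,
                    )
                    for s in reps
                ],
                sample_id=cond,
            )
            for st in "+-"
        }
    return merged


def region_count_table(
    models: dict[str, GeneModel],
    merged: dict[str, dict[str, cov.CoverageTrack]],
) -> pd.DataFrame:
    rows: dict[str, dict[str, int]] = {}
    for gid, m in models.items():
        for cond in ("control", "treated"):
            counts = sc.gene_region_counts(merged[cond][m.strand], m)
            rows.setdefault(gid, {}).update(
                {f"{k}_{cond}": v for k, v in counts.items()}
            )
    return pd.DataFrame.from_dict(rows, orient="index")


def pcpa_calls_from_counts(rc: pd.DataFrame, models) -> pd.DataFrame:
    counts = pd.DataFrame(
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
    return sc.pcpa_call(counts)
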