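"""Session fixtures: one composite simulation plus effect-isolated variants."""

from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from pcpakit.pipeline import load_config, run_pipeline
from pcpakit.simulate import SimulationConfig, simulate_genome

from helpers import (
    merged_condition_tracks,
    models_from_sim,
    pcpa_calls_from_counts,
    region_count_table,
)

SEED = 1


@pytest.fixture(scope="session")
def composite_run(tmp_path_factory):
    """Full pipeline on the default composite simulation (all effects on)."""
    outdir = tmp_path_factory.mktemp("composite")
    result = run_pipeline(load_config(seed=SEED), outdir)
    result["outdir"] = outdir
    return result


@pytest.fixture(scope="session")
def pcpa_isolated(tmp_path_factory):
    """Truncation only: 200 genes, a quarter with survival 0.1 at a proximal
    intronic site, no other treated effects."""
    cfg = SimulationConfig(
        n_genes=200, fraction_pcpa=0.25, fraction_ir=0.0, fraction_de=0.0,
        tss_gain_amplitude=0.0, seed=SEED,
    )
    sim = simulate_genome(cfg)
    outdir = tmp_path_factory.mktemp("pcpa_iso")
    merged = merged_condition_tracks(sim, outdir)
    models = models_from_sim(sim)
    rc = region_count_table(models, merged)
    calls = pcpa_calls_from_counts(rc, models)
    return {"sim": sim, "models": models, "counts": rc, "calls": calls}


@pytest.fixture(scope="session")
def ir_isolated(tmp_path_factory):
    """Planted 4x intron retention and 4x loss, nothing else."""
    cfg = SimulationConfig(
        n_genes=200, fraction_pcpa=0.0, fraction_ir=0.3, fraction_de=0.0,
        tss_gain_amplitude=0.0, seed=SEED,
    )
    sim = simulate_genome(cfg)
    outdir = tmp_path_factory.mktemp("ir_iso")
    merged = merged_condition_tracks(sim, outdir)
    models = models_from_sim(sim)
    rc = region_count_table(models, merged)
    return {"sim": sim, "models": models, "counts": rc}


@pytest.fixture(scope="session")
def null_run(tmp_path_factory):
    """All effect sizes zero: treated and control share one expectation."""
    cfg = SimulationConfig(
        n_genes=200, fraction_pcpa=0.0, fraction_ir=0.0, fraction_de=0.0,
        tss_gain_amplitude=0.0, seed=SEED,
    )
    sim = simulate_genome(cfg)
    outdir = tmp_path_factory.mktemp("null")
    merged = merged_condition_tracks(sim, outdir)
    models = models_from_sim(sim)
    rc = region_count_table(models, merged)
    calls = pcpa_calls_from_counts(rc, models)
    return {"sim": sim, "models": models, "counts": rc, "calls": calls,
            "merged": merged, "outdir": outdir}
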