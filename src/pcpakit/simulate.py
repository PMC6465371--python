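"""Synthetic data with known ground truth for every pipeline stage.

The generator builds a miniature single-chromosome genome ("chrS") carrying
multi-exon genes with canonical GT..AG introns, planted polyadenylation
signals (AATAAA) at true cleavage sites, U1 snRNP binding motifs, and
adenosine-run decoys that mimic internal-priming artifacts of oligo-dT
3'-end sequencing. From that genome it simulates:

* strand-specific TT-seq-like coverage (bedGraph) for paired control/treated
  samples with two replicates each — the treated condition shows 5'-proximal
  signal accumulation and, for genes with a planted premature cleavage and
  polyadenylation (PCPA) site, attenuated coverage downstream of that site;
* spike-in counts with known per-sample scaling, for size-factor recovery;
* a poly(A) 3'-end peak table whose read counts shift from 3'UTR sites to
  intronic sites in treated samples of PCPA genes;
* a truth table recording every planted effect per gene and per peak.

Noise model: Poisson per coverage bin; multinomial allocation of a Poisson
total across a gene's poly(A) sites. Genes are separated by >=2 kb spacers so
flanking-window logic downstream is exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CHROM = "chrS"

U1_MOTIFS = ("GGTGAG", "GGTAAG", "GTGAGT")
PAS_CANONICAL = "AATAAA"
PAS_MOTIFS = (
    "AATAAA", "ATTAAA", "AGTAAA", "TATAAA", "AATATA", "AATACA",
    "CATAAA", "GATAAA", "AATGAA", "ACTAAA", "AAGAAA", "AATAGA",
)

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# splice-site consensus profiles used when planting donors/acceptors.
# Donor: 3 exonic bases then 6 intronic (GT fixed at intron +1,+2).
_DONOR_PROFILE = [
    {"A": 0.35, "C": 0.35, "G": 0.18, "T": 0.12},   # exon -3
    {"A": 0.60, "C": 0.12, "G": 0.12, "T": 0.16},   # exon -2
    {"G": 0.80, "A": 0.10, "C": 0.05, "T": 0.05},   # exon -1
    {"G": 1.0},                                      # intron +1
    {"T": 1.0},                                      # intron +2
    {"A": 0.60, "G": 0.25, "C": 0.08, "T": 0.07},   # intron +3
    {"A": 0.70, "T": 0.12, "G": 0.10, "C": 0.08},   # intron +4
    {"G": 0.80, "A": 0.10, "T": 0.05, "C": 0.05},   # intron +5
    {"T": 0.50, "A": 0.20, "G": 0.20, "C": 0.10},   # intron +6
]
# Acceptor: 15-mer ending at the intron's last base (..polypyrimidine..NCAG).
_ACCEPTOR_PROFILE = (
    [{"T": 0.45, "C": 0.35, "A": 0.10, "G": 0.10}] * 11
    + [
        {"C": 0.65, "T": 0.25, "A": 0.05, "G": 0.05},  # -4
        {"C": 0.70, "T": 0.30},                         # -3 branch-ish
        {"A": 1.0},                                     # -2
        {"G": 1.0},                                     # -1
    ]
)


@dataclass
class SimulationConfig:
    """Knobs of the generative model; defaults define the study conditions."""

    n_genes: int = 200
    #: log-length distribution of ordinary genes (bp)
    length_log_mean: float = np.log(8000.0)
    length_log_sd: float = 0.55
    #: PCPA genes are drawn longer by this factor (premature termination is
    #: a long-gene phenotype)
    pcpa_length_factor: float = 2.5
    fraction_pcpa: float = 0.25
    truncation_survival: float = 0.1
    fraction_ir: float = 0.2
    ir_fold: float = 4.0
    fraction_de: float = 0.15
    de_log2fc: float = 2.0
    #: treated 5'-proximal gain: amplitude (x gene rate), center & sd (bp)
    tss_gain_amplitude: float = 3.0
    tss_gain_center: float = 1000.0
    tss_gain_sd: float = 300.0
    #: mean reads per bp per gene in the control condition
    read_depth: float = 0.5
    intron_level: float = 0.4
    coverage_bin: int = 50
    n_artifact_peaks: int = 50
    artifact_high_q_fraction: float = 0.6
    #: planted motif rates per kb of gene body
    u1_rate_per_kb: float = 1.5
    u1_pcpa_factor: float = 0.25
    pas_rate_per_kb: float = 0.1
    pas_pcpa_factor: float = 6.0
    #: poly(A)-seq reads per gene (Poisson mean at relative expression 1)
    polya_depth: float = 300.0
    #: fraction of treated PCPA-gene poly(A) reads shifted to intronic sites
    pcpa_intronic_shift: float = 0.8
    baseline_intronic_fraction: float = 0.1
    n_spikeins: int = 30
    spikein_mean_count: float = 5000.0
    #: per-sample library scaling factors
    spikein_scaling: dict = field(
        default_factory=lambda: {
            "control_rep1": 1.0,
            "control_rep2": 1.0,
            "treated_rep1": 1.0,
            "treated_rep2": 1.0,
        }
    )
    ddr_size: int = 30
    gc_content: float = 0.45
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fraction_pcpa", "fraction_ir", "fraction_de",
                     "truncation_survival", "pcpa_intronic_shift",
                     "baseline_intronic_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        if self.read_depth <= 0 or self.polya_depth <= 0:
            raise ValueError("depth parameters must be positive")

    @property
    def samples(self) -> list[str]:
        return list(self.spikein_scaling)


@dataclass
class SimGene:
    gene_id: str
    strand: str
    offset: int            # genome coordinate of the 5'-most base of the span
    length: int
    exons_sense: list[tuple[int, int]]   # sense coords, 0 = TSS
    rate: float            # control reads/bp on exons
    rel_expr: float
    pcpa: bool = False
    pcpa_sense: int | None = None        # sense coord of the PCPA cleavage
    ir_status: str = "none"
    de_log2fc: float = 0.0
    utr_cleavage_sense: int = 0
    intronic_cleavage_sense: list[int] = field(default_factory=list)
    u1_planted: int = 0
    pas_planted: int = 0

    # -- coordinate mapping -------------------------------------------------
    def g(self, p: int) -> int:
        """Sense position -> genome coordinate."""
        return self.offset + p if self.strand == "+" else self.offset + self.length - 1 - p

    def g_iv(self, a: int, b: int) -> tuple[int, int]:
        """Sense half-open interval -> genome half-open interval."""
        if self.strand == "+":
            return self.offset + a, self.offset + b
        return self.offset + self.length - b, self.offset + self.length - a

    @property
    def start(self) -> int:
        return self.offset

    @property
    def end(self) -> int:
        return self.offset + self.length

    @property
    def introns_sense(self) -> list[tuple[int, int]]:
        return [
            (e1, s2)
            for (_, e1), (s2, _) in zip(self.exons_sense, self.exons_sense[1:])
        ]


@dataclass
class SimulationTruth:
    """Planted effects keyed to the generated files."""

    genes: pd.DataFrame
    peaks: pd.DataFrame
    seed: int


@dataclass
class Simulation:
    config: SimulationConfig
    seq: np.ndarray                 # uint8 codes 0..3 = ACGT
    genes: list[SimGene]
    truth: SimulationTruth
    decoys: pd.DataFrame            # position, strand of planted A-run decoys

    @property
    def sequence(self) -> str:
        return codes_to_str(self.seq)

    @property
    def seq_lengths(self) -> dict[str, int]:
        return {CHROM: int(self.seq.size)}


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def _str_to_codes(s: str) -> np.ndarray:
    lut = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    return lut[np.frombuffer(s.encode(), dtype=np.uint8)]


def _sample_profile(rng: np.random.Generator, profile) -> str:
    out = []
    for col in profile:
        bases = list(col)
        probs = np.array([col[b] for b in bases])
        out.append(rng.choice(bases, p=probs / probs.sum()))
    return "".join(out)


class _Genome:
    """Mutable genome with strand-aware motif planting."""

    def __init__(self, rng: np.random.Generator, length: int, gc: float):
        at = (1 - gc) / 2
        gc2 = gc / 2
        self.seq = rng.choice(
            4, size=length, p=[at, gc2, gc2, at]
        ).astype(np.uint8)

    def write_sense(self, gene: SimGene, sense_pos: int, motif: str) -> None:
        """Write ``motif`` so it reads in transcription direction at sense_pos."""
        s, e = gene.g_iv(sense_pos, sense_pos + len(motif))
        written = motif if gene.strand == "+" else revcomp(motif)
        self.seq[s:e] = _str_to_codes(written)

    def write_genomic(self, start: int, motif: str) -> None:
        self.seq[start:start + len(motif)] = _str_to_codes(motif)

    def fetch(self, start: int, end: int, strand: str = "+") -> str:
        s = codes_to_str(self.seq[max(start, 0):end])
        return s if strand == "+" else revcomp(s)


def _gene_structure(rng: np.random.Generator, length: int) -> list[tuple[int, int]]:
    """Random exon layout in sense coordinates (min exon 80, min intron 250)."""
    max_exons = max(2, min(12, length // 600))
    n_exons = int(rng.integers(2, max_exons + 1))
    base = n_exons * 80 + (n_exons - 1) * 250
    while base > length:
        n_exons -= 1
        base = n_exons * 80 + (n_exons - 1) * 250
    if n_exons < 2:
        n_exons, base = 2, 2 * 80 + 250
    extra = length - base
    n_seg = 2 * n_exons - 1
    add = rng.multinomial(extra, np.full(n_seg, 1.0 / n_seg))
    exons, pos = [], 0
    for i in range(n_seg):
        seg = (80 if i % 2 == 0 else 250) + int(add[i])
        if i % 2 == 0:
            exons.append((pos, pos + seg))
        pos += seg
    # stretch last exon to close any rounding gap
    if pos != length:
        s, _ = exons[-1]
        exons[-1] = (s, length)
    return exons


def simulate_genome(config: SimulationConfig) -> Simulation:
    """Build the genome, gene structures, planted motifs and the truth table."""
    rng = np.random.default_rng(config.seed)
    n = config.n_genes

    is_pcpa = rng.random(n) < config.fraction_pcpa
    lengths = np.exp(rng.normal(config.length_log_mean, config.length_log_sd, n))
    lengths = np.where(is_pcpa, lengths * config.pcpa_length_factor, lengths)
    lengths = np.clip(lengths, 1200, None).astype(int)

    strands = np.where(rng.random(n) < 0.5, "+", "-")
    spacers = rng.integers(2200, 3200, size=n + 1)

    genes: list[SimGene] = []
    offset = int(spacers[0])
    rel_expr = np.exp(rng.normal(0.0, 0.4, n))
    for i in range(n):
        g = SimGene(
            gene_id=f"G{i + 1:04d}",
            strand=str(strands[i]),
            offset=offset,
            length=int(lengths[i]),
            exons_sense=_gene_structure(rng, int(lengths[i])),
            rate=config.read_depth * float(rel_expr[i]),
            rel_expr=float(rel_expr[i]),
            pcpa=bool(is_pcpa[i]),
        )
        genes.append(g)
        offset += g.length + int(spacers[i + 1])
    genome_len = offset

    genome = _Genome(rng, genome_len, config.gc_content)

    # --- intron retention / differential-expression assignment -------------
    non_pcpa = [g for g in genes if not g.pcpa and len(g.exons_sense) >= 2]
    rng.shuffle(non_pcpa)
    n_ir = int(round(config.fraction_ir * len(non_pcpa)))
    for j, g in enumerate(non_pcpa[:n_ir]):
        g.ir_status = "retention" if j % 2 == 0 else "loss"
    de_pool = [g for g in non_pcpa[n_ir:]]
    n_de = int(round(config.fraction_de * len(de_pool)))
    for j, g in enumerate(de_pool[:n_de]):
        g.de_log2fc = config.de_log2fc * (1 if j % 2 == 0 else -1)

    # --- plant sequence features per gene -----------------------------------
    for g in genes:
        reserved = np.zeros(g.length, dtype=bool)

        def reserve(a: int, b: int) -> None:
            reserved[max(a, 0):min(b, g.length)] = True

        for (istart, iend) in g.introns_sense:
            donor = _sample_profile(rng, _DONOR_PROFILE)
            genome.write_sense(g, istart - 3, donor)
            reserve(istart - 3, istart + 6)
            acceptor = _sample_profile(rng, _ACCEPTOR_PROFILE)
            genome.write_sense(g, iend - 15, acceptor)
            reserve(iend - 15, iend)

        # 3'UTR cleavage site with canonical PAS 30 bp upstream
        g.utr_cleavage_sense = g.length - 10
        genome.write_sense(g, g.utr_cleavage_sense - 30, PAS_CANONICAL)
        reserve(g.utr_cleavage_sense - 30, g.length)
        g.pas_planted += 1

        # intronic poly(A) sites; for PCPA genes the 5'-most one in
        # introns 1..4 is the premature termination site
        introns = g.introns_sense
        if g.pcpa:
            n_sites = 1 + int(rng.poisson(1.5))
            eligible = introns[: min(4, len(introns))]
        else:
            n_sites = int(rng.random() < 0.5)
            eligible = introns
        # the premature termination site is proximal but past the first
        # quarter of the internal region, so the truncated polymerase still
        # covers the 5' end of the gene body
        band = None
        if g.pcpa and introns:
            iq_start = g.exons_sense[0][1]
            iq_end = g.exons_sense[-1][0]
            span = iq_end - iq_start
            band = (iq_start + int(0.28 * span), iq_start + int(0.55 * span))
        placed: list[int] = []
        for _ in range(n_sites):
            if not eligible:
                break
            if g.pcpa and not placed and band is not None:
                feasible = []
                for istart, iend in eligible:
                    lo = max(istart + 40, band[0])
                    hi = min(iend - 30, g.length - 301, band[1])
                    if hi > lo:
                        feasible.append((lo, hi))
                if feasible:
                    lo, hi = feasible[int(rng.integers(len(feasible)))]
                else:
                    istart, iend = eligible[-1]
                    lo = istart + 40
                    hi = min(iend - 30, g.length - 301)
            else:
                istart, iend = eligible[int(rng.integers(len(eligible)))]
                lo, hi = istart + 40, min(iend - 30, g.length - 301)
                if g.pcpa and placed:
                    # secondary cryptic sites sit downstream of the
                    # termination site
                    lo = max(lo, placed[0] + 50)
            if hi <= lo:
                continue
            for _try in range(100):
                pos = int(rng.integers(lo, hi))
                if not reserved[pos - 35:pos + 6].any():
                    break
            else:
                continue
            genome.write_sense(g, pos - 30, PAS_CANONICAL)
            reserve(pos - 35, pos + 6)
            placed.append(pos)
            g.pas_planted += 1
        g.intronic_cleavage_sense = sorted(placed)
        if g.pcpa and placed:
            g.pcpa_sense = g.intronic_cleavage_sense[0]
        elif g.pcpa:
            # could not fit an intronic site: demote to non-PCPA
            g.pcpa = False

        # U1 motifs (suppress premature termination; fewer in PCPA genes)
        u1_rate = config.u1_rate_per_kb * (
            config.u1_pcpa_factor if g.pcpa else 1.0
        )
        n_u1 = int(rng.poisson(u1_rate * g.length / 1000.0))
        for _ in range(n_u1):
            motif = str(rng.choice(U1_MOTIFS))
            for _try in range(100):
                pos = int(rng.integers(0, g.length - 6))
                if not reserved[pos:pos + 6].any():
                    genome.write_sense(g, pos, motif)
                    reserve(pos, pos + 6)
                    g.u1_planted += 1
                    break
            else:
                raise RuntimeError(
                    f"{g.gene_id}: motif placement collision after 100 retries"
                )
        # extra body PAS motifs (more in PCPA genes -> lower U1/PAS ratio)
        pas_rate = config.pas_rate_per_kb * (
            config.pas_pcpa_factor if g.pcpa else 1.0
        )
        n_pas = int(rng.poisson(pas_rate * g.length / 1000.0))
        for _ in range(n_pas):
            for _try in range(100):
                pos = int(rng.integers(0, g.length - 6))
                if not reserved[pos:pos + 6].any():
                    genome.write_sense(g, pos, PAS_CANONICAL)
                    reserve(pos, pos + 6)
                    g.pas_planted += 1
                    break
            else:
                raise RuntimeError(
                    f"{g.gene_id}: motif placement collision after 100 retries"
                )

    # --- internal-priming decoys in intergenic spacers ----------------------
    decoy_rows = []
    bounds = [(g.start, g.end) for g in genes]
    decoy_pos: list[int] = []
    for k in range(config.n_artifact_peaks):
        for _try in range(500):
            pos = int(rng.integers(800, genome_len - 800))
            if all(pos < s - 700 or pos >= e + 700 for s, e in bounds) and all(
                abs(pos - q) > 250 for q in decoy_pos
            ):
                break
        else:
            raise RuntimeError("could not place artifact decoy away from genes")
        decoy_pos.append(pos)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            genome.write_genomic(pos + 10, "A" * 25)
            up_s, up_e = pos - 100, pos
        else:
            genome.write_genomic(pos - 35, "T" * 25)
            up_s, up_e = pos + 1, pos + 101
        _scrub_pas(genome, up_s, up_e, strand)
        decoy_rows.append({"position": pos, "strand": strand})
    decoys = pd.DataFrame(decoy_rows)

    truth = _build_truth(genes, decoys, config)
    return Simulation(config=config, seq=genome.seq, genes=genes,
                      truth=truth, decoys=decoys)


def _scrub_pas(genome: _Genome, start: int, end: int, strand: str) -> None:
    """Mutate any PAS motif occurrence in [start,end) (sense of ``strand``)."""
    for _ in range(50):
        window = genome.fetch(start, end, strand)
        hit = None
        for motif in PAS_MOTIFS:
            idx = window.find(motif)
            if idx >= 0:
                hit = idx
                break
        if hit is None:
            return
        # mutate the motif's middle base to C (sense); position mapping
        sense_pos = hit + 3
        if strand == "+":
            genome.write_genomic(start + sense_pos, "C")
        else:
            genome.write_genomic(end - 1 - sense_pos, "G")
    raise RuntimeError("failed to scrub PAS motifs from decoy window")


def _build_truth(genes, decoys, config) -> SimulationTruth:
    gene_rows = []
    for g in genes:
        gene_rows.append(
            {
                "gene_id": g.gene_id,
                "chrom": CHROM,
                "strand": g.strand,
                "start": g.start,
                "end": g.end,
                "length": g.length,
                "n_exons": len(g.exons_sense),
                "rel_expr": g.rel_expr,
                "pcpa": g.pcpa,
                "pcpa_site": g.g(g.pcpa_sense) if g.pcpa_sense is not None else -1,
                "ir_status": g.ir_status,
                "de_log2fc": g.de_log2fc,
                "utr_pas": g.g(g.utr_cleavage_sense),
                "intronic_pas": ",".join(
                    str(g.g(p)) for p in g.intronic_cleavage_sense
                ),
                "u1_planted": g.u1_planted,
                "pas_planted": g.pas_planted,
                "seed": config.seed,
            }
        )
    peak_rows = []
    for g in genes:
        peak_rows.append(
            {"peak_id": f"{g.gene_id}_utr", "gene_id": g.gene_id,
             "position": g.g(g.utr_cleavage_sense), "strand": g.strand,
             "kind": "utr", "seed": config.seed}
        )
        for j, p in enumerate(g.intronic_cleavage_sense):
            peak_rows.append(
                {"peak_id": f"{g.gene_id}_i{j}", "gene_id": g.gene_id,
                 "position": g.g(p), "strand": g.strand,
                 "kind": "intronic", "seed": config.seed}
            )
    for k, row in decoys.iterrows():
        peak_rows.append(
            {"peak_id": f"artifact_{k}", "gene_id": "",
             "position": int(row["position"]), "strand": row["strand"],
             "kind": "artifact", "seed": config.seed}
        )
    return SimulationTruth(
        genes=pd.DataFrame(gene_rows),
        peaks=pd.DataFrame(peak_rows),
        seed=config.seed,
    )


# ---------------------------------------------------------------------------
# coverage simulation
# ---------------------------------------------------------------------------


def expected_coverage(sim: Simulation) -> dict[tuple[str, str], np.ndarray]:
    """Noise-free per-bp coverage rate arrays keyed by (condition, strand)."""
    cfg = sim.config
    L = sim.seq.size
    fields = {(c, s): np.zeros(L) for c in ("control", "treated") for s in "+-"}
    for g in sim.genes:
        prof_c = np.full(g.length, g.rate)
        for (istart, iend) in g.introns_sense:
            prof_c[istart:iend] = g.rate * cfg.intron_level
        prof_t = prof_c * 2.0 ** g.de_log2fc
        if g.ir_status == "retention":
            for (istart, iend) in g.introns_sense:
                prof_t[istart:iend] *= cfg.ir_fold
        elif g.ir_status == "loss":
            for (istart, iend) in g.introns_sense:
                prof_t[istart:iend] /= cfg.ir_fold
        if g.pcpa and g.pcpa_sense is not None:
            prof_t[g.pcpa_sense:] *= cfg.truncation_survival
        d = np.arange(g.length)
        prof_t = prof_t + cfg.tss_gain_amplitude * g.rate * np.exp(
            -0.5 * ((d - cfg.tss_gain_center) / cfg.tss_gain_sd) ** 2
        )
        sl = slice(g.start, g.end)
        if g.strand == "+":
            fields[("control", "+")][sl] += prof_c
            fields[("treated", "+")][sl] += prof_t
        else:
            fields[("control", "-")][sl] += prof_c[::-1]
            fields[("treated", "-")][sl] += prof_t[::-1]
    return fields


def simulate_tt_coverage(
    sim: Simulation, outdir: str | Path
) -> tuple[dict[str, dict[str, Path]], pd.DataFrame]:
    """Write per-sample, per-strand bedGraph tracks and the spike-in table.

    Counts per ``coverage_bin`` window are Poisson around the expected rate
    scaled by the sample's library factor; bedGraph values are per-bp
    coverage (counts / bin width). Returns ``(paths, spikein_counts)``.
    """
    cfg = sim.config
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed + 1)
    fields = expected_coverage(sim)
    L = sim.seq.size
    bw = cfg.coverage_bin
    n_bins = (L + bw - 1) // bw
    edges = np.minimum(np.arange(1, n_bins + 1) * bw, L)
    widths = np.diff(np.concatenate([[0], edges]))

    paths: dict[str, dict[str, Path]] = {}
    for sample, scaling in cfg.spikein_scaling.items():
        condition = "control" if sample.startswith("control") else "treated"
        paths[sample] = {}
        for strand, tag in (("+", "plus"), ("-", "minus")):
            rate = fields[(condition, strand)]
            binned = np.add.reduceat(rate, np.arange(0, L, bw))
            counts = rng.poisson(binned * scaling)
            values = counts / widths
            path = outdir / f"{sample}.{tag}.bedgraph"
            with open(path, "w") as fh:
                start = 0
                for b in range(n_bins):
                    if counts[b] > 0:
                        fh.write(
                            f"{CHROM}\t{start}\t{edges[b]}\t{values[b]:.6g}\n"
                        )
                    start = edges[b]
            paths[sample][strand] = path

    base = np.exp(rng.normal(np.log(cfg.spikein_mean_count), 0.3, cfg.n_spikeins))
    spike = {
        sample: rng.poisson(base * scaling)
        for sample, scaling in cfg.spikein_scaling.items()
    }
    spikein = pd.DataFrame(
        spike, index=[f"spike_{i + 1:02d}" for i in range(cfg.n_spikeins)]
    )
    spikein.index.name = "spikein_id"
    spikein.to_csv(outdir / "spikeins.tsv", sep="\t")
    return paths, spikein


# ---------------------------------------------------------------------------
# poly(A) peak simulation
# ---------------------------------------------------------------------------


def simulate_polya(sim: Simulation) -> pd.DataFrame:
    """Peak table with per-sample counts; columns follow the peak-reader dialect.

    Control reads concentrate at the 3'UTR site; in treated samples of PCPA
    genes ``pcpa_intronic_shift`` of the reads move to intronic sites.
    Artifact peaks sit over the planted A-runs with no upstream PAS.
    """
    cfg = sim.config
    rng = np.random.default_rng(cfg.seed + 2)
    rows = []
    for g in sim.genes:
        sites = [("utr", g.g(g.utr_cleavage_sense))] + [
            (f"i{j}", g.g(p)) for j, p in enumerate(g.intronic_cleavage_sense)
        ]
        n_intronic = len(sites) - 1
        if n_intronic:
            base_frac = cfg.baseline_intronic_fraction
            w_control = np.array(
                [1.0 - base_frac] + [base_frac / n_intronic] * n_intronic
            )
        else:
            w_control = np.array([1.0])
        if g.pcpa and n_intronic:
            w_treated = np.array(
                [1.0 - cfg.pcpa_intronic_shift]
                + [cfg.pcpa_intronic_shift / n_intronic] * n_intronic
            )
        else:
            w_treated = w_control
        counts = {}
        for sample, scaling in cfg.spikein_scaling.items():
            w = w_control if sample.startswith("control") else w_treated
            total = rng.poisson(cfg.polya_depth * g.rel_expr * scaling)
            counts[sample] = rng.multinomial(total, w)
        for k, (tag, pos) in enumerate(sites):
            row = {
                "chrom": CHROM,
                "start": pos - 25,
                "end": pos + 25,
                "name": f"{g.gene_id}_{tag}",
                "qscore": float(5.0 + rng.exponential(5.0)),
                "strand": g.strand,
                "summit": pos,
            }
            for sample in cfg.spikein_scaling:
                row[sample] = int(counts[sample][k])
            rows.append(row)
    for k, drow in sim.decoys.iterrows():
        pos = int(drow["position"])
        high = rng.random() < cfg.artifact_high_q_fraction
        row = {
            "chrom": CHROM,
            "start": pos - 25,
            "end": pos + 25,
            "name": f"artifact_{k}",
            "qscore": float(5.0 + rng.exponential(3.0)) if high
            else float(rng.uniform(1.0, 4.9)),
            "strand": drow["strand"],
            "summit": pos,
        }
        for sample in cfg.spikein_scaling:
            row[sample] = int(rng.poisson(8.0))
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------


def write_fasta(sim: Simulation, path: str | Path, width: int = 70) -> Path:
    path = Path(path)
    seq = sim.sequence
    with open(path, "w") as fh:
        fh.write(f">{CHROM}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i:i + width] + "\n")
    return path


def write_gtf(sim: Simulation, path: str | Path) -> Path:
    """One transcript per gene; 1-based closed coordinates as GTF requires."""
    path = Path(path)
    with open(path, "w") as fh:
        for g in sim.genes:
            attrs = f'gene_id "{g.gene_id}"; gene_type "protein_coding";'
            tx = f'{attrs} transcript_id "{g.gene_id}.1";'
            fh.write(
                f"{CHROM}\tsim\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{CHROM}\tsim\ttranscript\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{tx}\n"
            )
            for (a, b) in g.exons_sense:
                s, e = g.g_iv(a, b)
                fh.write(
                    f"{CHROM}\tsim\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{tx}\n"
                )
    return path


def write_abundance(sim: Simulation, path: str | Path) -> Path:
    """TPM table for the single isoform of each gene."""
    total = sum(g.rel_expr for g in sim.genes)
    rows = [
        {
            "transcript_id": f"{g.gene_id}.1",
            "gene_id": g.gene_id,
            "tpm": 1e6 * g.rel_expr / total,
        }
        for g in sim.genes
    ]
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def emit_truth(truth: SimulationTruth, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genes": outdir / "truth_genes.tsv",
        "peaks": outdir / "truth_peaks.tsv",
    }
    truth.genes.to_csv(paths["genes"], sep="\t", index=False)
    truth.peaks.to_csv(paths["peaks"], sep="\t", index=False)
    return paths


def read_truth(outdir: str | Path) -> SimulationTruth:
    outdir = Path(outdir)
    genes = pd.read_csv(
        outdir / "truth_genes.tsv", sep="\t",
        dtype={"intronic_pas": str}, keep_default_na=False,
    )
    genes["intronic_pas"] = genes["intronic_pas"].astype(str)
    peaks = pd.read_csv(
        outdir / "truth_peaks.tsv", sep="\t",
        dtype={"gene_id": str}, keep_default_na=False,
    )
    seed = int(genes["seed"].iloc[0]) if len(genes) else 0
    return SimulationTruth(genes=genes, peaks=peaks, seed=seed)


def simulate_all(config: SimulationConfig, outdir: str | Path) -> dict:
    """Run the full generator and write every artifact under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = simulate_genome(config)
    manifest = {
        "fasta": write_fasta(sim, outdir / "genome.fa"),
        "gtf": write_gtf(sim, outdir / "annotation.gtf"),
        "abundance": write_abundance(sim, outdir / "abundance.tsv"),
    }
    paths, _ = simulate_tt_coverage(sim, outdir)
    manifest["coverage"] = paths
    manifest["spikeins"] = outdir / "spikeins.tsv"
    peaks = simulate_polya(sim)
    peaks.to_csv(outdir / "polya_peaks.tsv", sep="\t", index=False)
    manifest["peaks"] = outdir / "polya_peaks.tsv"
    truth_paths = emit_truth(sim.truth, outdir)
    manifest["truth_genes"] = truth_paths["genes"]
    manifest["truth_peaks"] = truth_paths["peaks"]
    rng_ddr = np.random.default_rng(config.seed + 3)
    gids = sorted(g.gene_id for g in sim.genes)
    ddr_size = max(3, min(config.ddr_size, len(gids) // 4))
    ddr = sorted(rng_ddr.choice(gids, size=ddr_size, replace=False))
    ddr_path = outdir / "ddr_genes.txt"
    ddr_path.write_text("\n".join(ddr) + "\n")
    manifest["ddr"] = ddr_path
    manifest["sim"] = sim
    return manifest
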