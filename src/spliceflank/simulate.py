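"""Self-contained synthetic fixtures with known ground truth.

The generator emulates the study design this package analyzes: a two-isoform
gene per planted splicing event (retained intron, skipped exon, alternative
donor/acceptor), two conditions with a small number of biological replicates
(3 vs 3 by default), per-replicate inclusion levels drawn logit-normally
around condition means with a planted condition shift, gene abundances drawn
log-normally on a TPM scale, motifs planted at controlled per-kilobase
densities inside chosen region classes, and differential-expression /
immunoprecipitation support tables with planted effect gene sets.

Every generator is a pure function of (config, seed): the same seed yields
byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .events import TranscriptModel
from .motifs import MotifPattern, count_motif, occurrence_starts
from .regions import FlankRegion, reverse_complement

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    seed: int = 1
    # genome / annotation
    n_genes: int = 200
    events_per_type: dict = field(
        default_factory=lambda: {"RI": 20, "A3": 14, "A5": 10, "SE": 6}
    )
    exon_length_range: tuple[int, int] = (100, 300)
    intron_length_range: tuple[int, int] = (120, 300)
    alt_span_range: tuple[int, int] = (20, 60)
    intergenic_length: int = 100
    chrom: str = "chr1"
    # quantification
    n_replicates: int = 3
    delta_psi_choices: tuple[float, ...] = (0.4, -0.4)
    control_psi_range: tuple[float, float] = (0.25, 0.75)
    psi_noise_sd: float = 0.2
    gene_tpm_log_mean: float = 3.0
    gene_tpm_log_sd: float = 0.5
    # support tables
    de_n_genes: int = 1000
    de_n_up: int = 60
    de_n_down: int = 60
    de_fold: float = 3.0
    de_n_sources: int = 3
    rip_n_genes: int = 1000
    rip_n_planted: int = 100
    rip_fold: float = 3.0
    rip_n_methods: int = 2
    concordance: float = 1.0
    fold_noise_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.exon_length_range[0] < 20 or self.intron_length_range[0] < 20:
            raise ValueError("exon/intron lengths must be >= 20")
        for d in self.delta_psi_choices:
            if not -0.95 < d < 0.95:
                raise ValueError("planted delta-psi must lie in (-0.95, 0.95)")


def _rand_len(rng, lo_hi) -> int:
    return int(rng.integers(lo_hi[0], lo_hi[1] + 1))


def _make_event_gene(etype: str, strand: str, gene_id: str, start: int,
                     cfg: SimulationConfig, rng) -> tuple[list, int]:
    """Two isoforms realizing exactly one event of `etype`; returns
    (transcript specs, gene end)."""
    ex = lambda: _rand_len(rng, cfg.exon_length_range)
    intr = lambda: _rand_len(rng, cfg.intron_length_range)
    alt = lambda: _rand_len(rng, cfg.alt_span_range)
    g = start
    if etype == "RI":
        L1, I, L2 = ex(), intr(), ex()
        incl = [(g, g + L1 + I + L2)]                      # retains intron
        excl = [(g, g + L1), (g + L1 + I, g + L1 + I + L2)]
        end = g + L1 + I + L2
    elif etype == "SE":
        L1, I1, Lm, I2, L3 = ex(), intr(), ex(), intr(), ex()
        s2 = g + L1 + I1
        s3 = s2 + Lm + I2
        incl = [(g, g + L1), (s2, s2 + Lm), (s3, s3 + L3)]
        excl = [(g, g + L1), (s3, s3 + L3)]
        end = s3 + L3
    else:
        # Alternative-site events: two exon boundaries on one side of an
        # intron.  Sites at the intron's genomic-left boundary give A5 on +
        # and A3 on -, and vice versa.
        L1, d, I, L2 = ex(), alt(), intr(), ex()
        alt_left = (etype == "A5") == (strand == "+")
        if alt_left:
            acc = g + L1 + d + I
            incl = [(g, g + L1 + d), (acc, acc + L2)]      # shorter intron
            excl = [(g, g + L1), (acc, acc + L2)]
            end = acc + L2
        else:
            s = g + L1
            a1 = s + I
            a2 = a1 + d
            incl = [(g, s), (a1, a2 + L2)]                 # shorter intron
            excl = [(g, s), (a2, a2 + L2)]
            end = a2 + L2
    specs = [
        (f"{gene_id}.incl", incl),
        (f"{gene_id}.excl", excl),
    ]
    return specs, end


def make_genome_annotation(cfg: SimulationConfig, seed: int | None = None
                           ) -> tuple[dict[str, str], list[TranscriptModel],
                                      pd.DataFrame]:
    """Random-base genome + annotation with one planted event per event gene.

    Returns (genome {chrom: sequence}, transcripts, truth table).  The truth
    table has one row per event gene: gene_id, event_type, strand,
    inclusion/exclusion transcript, control_psi, delta_psi.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n_event_genes = sum(cfg.events_per_type.values())
    if n_event_genes > cfg.n_genes:
        raise ValueError("events_per_type exceeds n_genes")
    plan = [t for t in sorted(cfg.events_per_type)
            for _ in range(cfg.events_per_type[t])]
    plan += ["single"] * (cfg.n_genes - n_event_genes)

    transcripts: list[TranscriptModel] = []
    truth_rows = []
    pos = cfg.intergenic_length
    for i, etype in enumerate(plan):
        gene_id = f"SYN{i + 1:04d}"
        strand = "+" if i % 2 == 0 else "-"
        if etype == "single":
            L = _rand_len(rng, cfg.exon_length_range)
            specs, end = [(f"{gene_id}.1", [(pos, pos + L)])], pos + L
        else:
            specs, end = _make_event_gene(etype, strand, gene_id, pos,
                                          cfg, rng)
        for tx_id, exons in specs:
            transcripts.append(TranscriptModel(
                transcript_id=tx_id, gene_id=gene_id, chrom=cfg.chrom,
                strand=strand, exons=tuple(exons),
            ))
        if etype != "single":
            delta = float(rng.choice(cfg.delta_psi_choices))
            lo, hi = cfg.control_psi_range
            lo, hi = max(lo, 0.05 - min(delta, 0.0)), min(hi, 0.95 - max(delta, 0.0))
            control_psi = float(rng.uniform(lo, hi))
            truth_rows.append({
                "gene_id": gene_id, "event_type": etype, "strand": strand,
                "inclusion_tx": f"{gene_id}.incl",
                "exclusion_tx": f"{gene_id}.excl",
                "control_psi": control_psi, "delta_psi": delta,
            })
        pos = end + cfg.intergenic_length

    genome_len = pos + cfg.intergenic_length
    seq = "".join(rng.choice(_BASES, size=genome_len))
    truth = pd.DataFrame(truth_rows, columns=[
        "gene_id", "event_type", "strand", "inclusion_tx", "exclusion_tx",
        "control_psi", "delta_psi",
    ])
    return {cfg.chrom: seq}, transcripts, truth


def write_fasta(genome: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            s = genome[chrom]
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


def write_gtf(transcripts: list[TranscriptModel], path: str,
              source: str = "spliceflank_sim") -> None:
    with open(path, "w") as fh:
        for tx in transcripts:
            for start, end in tx.exons:
                attrs = (f'gene_id "{tx.gene_id}"; '
                         f'transcript_id "{tx.transcript_id}";')
                fh.write("\t".join([
                    tx.chrom, source, "exon", str(start + 1), str(end),
                    ".", tx.strand, ".", attrs,
                ]) + "\n")


# ---------------------------------------------------------------------------
# Motif planting


def plant_motifs(genome: dict[str, str], regions: list[FlankRegion],
                 motif: MotifPattern | str, target_density: float,
                 seed: int = 1, max_iter: int = 100_000) -> dict[str, str]:
    """Rewrite the genome so the motif's total count over `regions`
    (scanned in sense orientation) equals round(density * length / 1000).

    Chance occurrences count toward the target; when the random background
    already exceeds it, occurrences are scrubbed by point mutation.  Region
    coordinates and sequence lengths are preserved.
    """
    if isinstance(motif, str):
        motif = MotifPattern(motif, motif)
    rng = np.random.default_rng(seed)
    chroms = {c: bytearray(s, "ascii") for c, s in genome.items()}
    total_len = sum(r.end - r.start for r in regions)
    target = round(target_density * total_len / 1000.0)
    m = len(motif)
    if any(r.end - r.start < m for r in regions) and target > 0:
        raise ValueError("a region is shorter than the motif")
    max_possible = sum((r.end - r.start) // m for r in regions)
    if target > max_possible:
        raise ValueError(
            f"target count {target} infeasible over {total_len} nt"
        )

    def sense_seq(r: FlankRegion) -> str:
        raw = chroms[r.chrom][r.start:r.end].decode()
        return reverse_complement(raw) if r.strand == "-" else raw

    def write_sense(r: FlankRegion, pos: int, text: str) -> None:
        # position `pos` is in sense orientation; map back to genomic
        if r.strand == "-":
            text = reverse_complement(text)
            gpos = r.end - pos - len(text)
        else:
            gpos = r.start + pos
        chroms[r.chrom][gpos:gpos + len(text)] = text.encode()

    def instance() -> str:
        return "".join(
            c if c != "N" else str(rng.choice(_BASES))
            for c in motif.pattern
        )

    lengths = np.array([r.end - r.start for r in regions], dtype=float)
    weights = lengths / lengths.sum()
    for _ in range(max_iter):
        counts = [count_motif(sense_seq(r), motif) for r in regions]
        total = sum(counts)
        if total == target:
            return {c: b.decode() for c, b in chroms.items()}
        if total < target:
            ridx = int(rng.choice(len(regions), p=weights))
            r = regions[ridx]
            pos = int(rng.integers(0, r.end - r.start - m + 1))
            write_sense(r, pos, instance())
        else:
            # scrub a random occurrence: mutate one non-N motif position
            occupied = [i for i, c in enumerate(counts) if c > 0]
            ridx = int(rng.choice(occupied))
            r = regions[ridx]
            starts = occurrence_starts(sense_seq(r), motif)
            start = int(rng.choice(starts))
            fixed = [j for j, c in enumerate(motif.pattern) if c != "N"]
            j = int(rng.choice(fixed))
            cur = sense_seq(r)[start + j]
            alt = rng.choice([b for b in "ACGT" if b != cur])
            write_sense(r, start + j, str(alt))
    raise RuntimeError("motif planting did not converge")


def make_intersecting_sets(source_sizes: list[int], core_size: int,
                           prefix: str = "G") -> list[set[str]]:
    """Gene sets with prescribed per-source sizes whose common intersection
    is exactly `core_size` genes.

    The shared core appears in every set; the remaining genes of each set are
    pairwise disjoint across sources, so any intersection of two or more sets
    equals the core exactly.
    """
    if core_size > min(source_sizes, default=0):
        raise ValueError("core larger than the smallest source set")
    core = {f"{prefix}CORE{i + 1:06d}" for i in range(core_size)}
    sets = []
    for s, size in enumerate(source_sizes):
        filler = {f"{prefix}S{s + 1}X{i + 1:06d}"
                  for i in range(size - core_size)}
        sets.append(core | filler)
    return sets


# ---------------------------------------------------------------------------
# Quantification simulation


def _logit(p):
    return np.log(p / (1.0 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def simulate_quant(transcripts: list[TranscriptModel], truth: pd.DataFrame,
                   cfg: SimulationConfig, seed: int | None = None
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample isoform TPM table + condition map.

    Event genes: gene TPM log-normal per sample; replicate psi logit-normal
    around the condition mean (control_psi, or control_psi + delta_psi for
    the mutant, clamped to (0.01, 0.99)); inclusion isoform gets
    TPM * psi, exclusion isoform TPM * (1 - psi).  With psi_noise_sd = 0 the
    replicate psi equals the condition mean exactly.
    """
    rng = np.random.default_rng((cfg.seed + 1) if seed is None else seed)
    samples = ([f"control_{i + 1}" for i in range(cfg.n_replicates)]
               + [f"mutant_{i + 1}" for i in range(cfg.n_replicates)])
    conditions = (["control"] * cfg.n_replicates
                  + ["mutant"] * cfg.n_replicates)
    truth_by_gene = truth.set_index("gene_id") if len(truth) else truth

    by_gene: dict[str, list[TranscriptModel]] = {}
    for tx in transcripts:
        by_gene.setdefault(tx.gene_id, []).append(tx)

    rows: dict[str, list[float]] = {}
    for gene_id in sorted(by_gene):
        txs = sorted(by_gene[gene_id], key=lambda t: t.transcript_id)
        tpms = rng.lognormal(cfg.gene_tpm_log_mean, cfg.gene_tpm_log_sd,
                             size=len(samples))
        is_event_gene = len(truth) and gene_id in truth_by_gene.index
        if is_event_gene:
            rec = truth_by_gene.loc[gene_id]
            incl, excl = rec["inclusion_tx"], rec["exclusion_tx"]
            for tx in txs:
                rows[tx.transcript_id] = []
            for j, cond in enumerate(conditions):
                mean = rec["control_psi"] + (
                    rec["delta_psi"] if cond == "mutant" else 0.0
                )
                mean = min(max(mean, 0.01), 0.99)
                if cfg.psi_noise_sd > 0:
                    psi = float(_expit(_logit(mean)
                                       + rng.normal(0.0, cfg.psi_noise_sd)))
                else:
                    psi = mean
                rows[incl].append(tpms[j] * psi)
                rows[excl].append(tpms[j] * (1.0 - psi))
        else:
            share = rng.dirichlet(np.ones(len(txs))) if len(txs) > 1 \
                else np.array([1.0])
            for tx, frac in zip(txs, share):
                rows[tx.transcript_id] = list(tpms * frac)

    quant = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    quant.index.name = "transcript_id"
    quant = quant.sort_index()
    condition_map = pd.DataFrame({"sample": samples, "condition": conditions})
    return quant, condition_map


# ---------------------------------------------------------------------------
# Support tables (differential expression + immunoprecipitation)


def simulate_support_tables(cfg: SimulationConfig, seed: int | None = None
                            ) -> tuple[dict[str, pd.DataFrame],
                                       dict[str, pd.DataFrame],
                                       dict[str, set[str]]]:
    """Pseudo-pipeline DE tables and two-line RIP tables with planted sets.

    Planted genes receive fold changes at or above the planted fold (small
    multiplicative noise, one-sided) and small significance values; null
    genes get fold ~ 1 and uniform significance.  `concordance` is the
    per-source probability that a planted gene shows its effect in that
    source (dropout emulates pipeline disagreement).
    """
    rng = np.random.default_rng((cfg.seed + 2) if seed is None else seed)
    de_genes = [f"GDE{i + 1:05d}" for i in range(cfg.de_n_genes)]
    up = set(de_genes[:cfg.de_n_up])
    down = set(de_genes[cfg.de_n_up:cfg.de_n_up + cfg.de_n_down])

    def null_row():
        return (float(np.exp(rng.normal(0.0, 0.15))),
                float(rng.uniform(0.0, 1.0)))

    def planted_row(fold: float, direction: int):
        fc = fold * float(np.exp(abs(rng.normal(0.0, cfg.fold_noise_sd))))
        if direction < 0:
            fc = 1.0 / fc
        return fc, float(rng.uniform(0.0, 0.01))

    de_tables: dict[str, pd.DataFrame] = {}
    for s in range(cfg.de_n_sources):
        recs = []
        for g in de_genes:
            if g in up and rng.uniform() < cfg.concordance:
                fc, sig = planted_row(cfg.de_fold, +1)
            elif g in down and rng.uniform() < cfg.concordance:
                fc, sig = planted_row(cfg.de_fold, -1)
            else:
                fc, sig = null_row()
            recs.append({"gene_id": g, "fold_change": fc,
                         "significance": sig})
        de_tables[f"pipeline{s + 1}"] = pd.DataFrame(recs)

    rip_genes = [f"GRP{i + 1:05d}" for i in range(cfg.rip_n_genes)]
    planted_rip = set(rip_genes[:cfg.rip_n_planted])
    rip_tables: dict[str, pd.DataFrame] = {}
    for mth in range(cfg.rip_n_methods):
        recs = []
        for g in rip_genes:
            hit = g in planted_rip and rng.uniform() < cfg.concordance
            for line in ("line1", "line2"):
                if hit:
                    fc, sig = planted_row(cfg.rip_fold, +1)
                else:
                    fc, sig = null_row()
                recs.append({"gene_id": g, "line": line,
                             "fold_change": fc, "significance": sig})
        rip_tables[f"method{mth + 1}"] = pd.DataFrame(recs)

    return de_tables, rip_tables, {"de_up": up, "de_down": down,
                                   "rip": planted_rip}
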