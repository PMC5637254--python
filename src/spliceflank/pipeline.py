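"""End-to-end orchestration of the two headline analyses.

`run_sas_motif_pipeline` chains annotation -> event catalogue -> psi/delta-psi
calling -> flank-region extraction (stratified by delta-psi sign) -> motif
density/enrichment statistics against the whole-catalogue background.

`run_set_pipeline` chains differential-expression filtering -> cross-pipeline
consensus, immunoprecipitation two-line selection -> cross-method
intersection, set-overlap Fisher tests and hypergeometric term enrichment.

Each run directory gets a JSON manifest (tool version, input checksums,
parameters, seed) and a run.log recording every filter with before/after
counts. Data outputs are deterministic functions of inputs + seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from datetime import datetime, timezone

import pandas as pd

from . import __version__
from .events import build_events, gene_bounds, parse_gtf, write_events
from .motifs import DEFAULT_MOTIFS, MotifPattern, motif_enrichment_table
from .psi import call_sas, read_condition_map, read_quant, results_to_frame
from .regions import (extract_regions, fetch_sequences, write_bed,
                      write_region_fasta)
from .sets import (consensus, filter_de, fisher_overlap, select_sars,
                   term_enrichment, write_gene_list)

log = logging.getLogger("spliceflank")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _setup_run_logging(outdir: str) -> logging.Handler:
    handler = logging.FileHandler(os.path.join(outdir, "run.log"), mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    return handler


def _write_manifest(outdir: str, inputs: dict[str, str], params: dict,
                    seed: int) -> None:
    manifest = {
        "tool": "spliceflank",
        "version": __version__,
        "inputs": {name: _sha256(path) for name, path in inputs.items()},
        "parameters": params,
        "seed": seed,
        "created": datetime.now(timezone.utc).isoformat(),
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_sas_motif_pipeline(gtf: str, genome: str, quant: str,
                           conditions: str, outdir: str,
                           motifs: dict[str, str] | None = None,
                           alpha: float = 0.05, min_tpm: float = 10.0,
                           window: int = 50, test: str = "auto",
                           n_perm: int = 10_000, seed: int = 1) -> str:
    """Event calling, delta-psi filtering and flank-motif statistics.

    Writes events.tsv, sas.tsv, regions_{all,dpsi_pos,dpsi_neg}.{bed,fa},
    motif_stats.tsv and manifest.json under `outdir`; returns `outdir`.
    """
    os.makedirs(outdir, exist_ok=True)
    handler = _setup_run_logging(outdir)
    try:
        motif_set = motifs if motifs is not None else DEFAULT_MOTIFS
        patterns = [MotifPattern(n, p) for n, p in motif_set.items()]

        def stage(name):
            log.info("stage: %s", name)

        stage("events")
        transcripts = parse_gtf(gtf)
        events = build_events(transcripts)
        bounds = gene_bounds(transcripts)
        write_events(events, os.path.join(outdir, "events.tsv"))
        log.info("events: %d transcripts -> %d events",
                 len(transcripts), len(events))

        stage("sas")
        quant_df = read_quant(quant)
        cond = read_condition_map(conditions)
        missing = [s for s in cond["sample"] if s not in quant_df.columns]
        if missing:
            raise ValueError(
                f"stage sas: samples in condition map absent from "
                f"quantification table: {', '.join(missing)}"
            )
        results = call_sas(events, quant_df, cond, alpha=alpha,
                           min_tpm=min_tpm, test=test, n_perm=n_perm,
                           seed=seed)
        sas_frame = results_to_frame(results)
        sas_frame.to_csv(os.path.join(outdir, "sas.tsv"), sep="\t",
                         index=False, float_format="%.6g")
        n_sas = int(sas_frame["is_sas"].sum())
        log.info("sas filter (p < %g, total mean TPM >= %g): %d -> %d events",
                 alpha, min_tpm, len(events), n_sas)

        stage("regions")
        by_id = {ev.event_id: ev for ev in events}
        strata: dict[str, list] = {"dpsi_pos": [], "dpsi_neg": []}
        all_regions = []
        for r in results:
            ev = by_id[r.event_id]
            regions = extract_regions(ev, bounds[ev.gene_id], window=window)
            all_regions.extend(regions)
            if r.is_sas and r.delta_psi is not None:
                key = "dpsi_pos" if r.delta_psi > 0 else "dpsi_neg"
                strata[key].extend(regions)
        from pyfaidx import Fasta
        fa = Fasta(genome)
        for name, regs in [("all", all_regions)] + list(strata.items()):
            fetch_sequences(regs, fa)
            write_bed(regs, os.path.join(outdir, f"regions_{name}.bed"))
            write_region_fasta(regs, os.path.join(outdir, f"regions_{name}.fa"))
            log.info("regions_%s: %d windows", name, len(regs))

        stage("motifs")
        stats = motif_enrichment_table(strata, all_regions, patterns)
        stats.to_csv(os.path.join(outdir, "motif_stats.tsv"), sep="\t",
                     index=False, float_format="%.6g")

        _write_manifest(
            outdir,
            {"gtf": gtf, "genome": genome, "quant": quant,
             "conditions": conditions},
            {"alpha": alpha, "min_tpm": min_tpm, "window": window,
             "test": test, "n_perm": n_perm,
             "motifs": dict(sorted(motif_set.items()))},
            seed,
        )
    finally:
        log.removeHandler(handler)
        handler.close()
    return outdir


def run_set_pipeline(de_tables: dict[str, str] | None,
                     rip_tables: dict[str, str] | None,
                     outdir: str,
                     term_map: str | None = None,
                     universe: str | None = None,
                     overlap_set: str | None = None,
                     min_fc: float = 2.0, max_sig: float = 0.1,
                     seed: int = 1) -> str:
    """Consensus differential-expression sets, bound-transcript selection,
    term enrichment and overlap tests; writes gene lists and TSVs to outdir.
    """
    os.makedirs(outdir, exist_ok=True)
    handler = _setup_run_logging(outdir)
    inputs: dict[str, str] = {}
    try:
        universe_genes: set[str] = set()
        consensus_genes: set[str] = set()

        if de_tables:
            pairs = []
            for name, path in sorted(de_tables.items()):
                inputs[f"de:{name}"] = path
                table = pd.read_csv(path, sep="\t")
                up, down = filter_de(table, min_fc=min_fc, max_sig=max_sig,
                                     label=name)
                log.info("filter_de %s (fc >= %g, sig < %g): %d rows -> "
                         "%d up / %d down", name, min_fc, max_sig,
                         len(table), len(up), len(down))
                pairs.append((up, down))
                universe_genes |= set(table["gene_id"])
            up_common, down_common = consensus(pairs)
            log.info("consensus over %d sources: %d up / %d down",
                     len(pairs), len(up_common), len(down_common))
            write_gene_list(up_common, os.path.join(outdir, "consensus_up.txt"))
            write_gene_list(down_common,
                            os.path.join(outdir, "consensus_down.txt"))
            consensus_genes = up_common | down_common

        if rip_tables:
            frames = {}
            for name, path in sorted(rip_tables.items()):
                inputs[f"rip:{name}"] = path
                frames[name] = pd.read_csv(path, sep="\t")
            sars = select_sars(frames, min_fc=min_fc, max_sig=max_sig)
            log.info("rip selection (fc >= %g, sig < %g in both lines): "
                     "per-method %s -> %d common", min_fc, max_sig,
                     sars.provenance["per_method_sizes"], len(sars))
            write_gene_list(set(sars.genes),
                            os.path.join(outdir, "bound_transcripts.txt"))
            consensus_genes = consensus_genes or set(sars.genes)
            universe_genes |= {
                g for f in frames.values() for g in f["gene_id"]
            }

        if universe:
            inputs["universe"] = universe
            with open(universe) as fh:
                universe_genes = {line.strip() for line in fh if line.strip()}

        if term_map and consensus_genes and universe_genes:
            inputs["term_map"] = term_map
            tm = pd.read_csv(term_map, sep="\t")
            enr = term_enrichment(consensus_genes, tm, universe_genes)
            enr.to_csv(os.path.join(outdir, "term_enrichment.tsv"), sep="\t",
                       index=False, float_format="%.6g")
            log.info("term enrichment: %d terms tested", len(enr))

        if overlap_set and consensus_genes and universe_genes:
            inputs["overlap_set"] = overlap_set
            with open(overlap_set) as fh:
                other = {line.strip() for line in fh if line.strip()}
            odds, p = fisher_overlap(consensus_genes, other, universe_genes)
            with open(os.path.join(outdir, "overlap.tsv"), "w") as fh:
                fh.write("n_a\tn_b\tn_overlap\todds_ratio\tp_value\n")
                fh.write(f"{len(consensus_genes)}\t{len(other)}\t"
                         f"{len(consensus_genes & other)}\t{odds:.6g}\t"
                         f"{p:.6g}\n")
            log.info("overlap test: odds %.3g p %.3g", odds, p)

        _write_manifest(outdir, inputs,
                        {"min_fc": min_fc, "max_sig": max_sig}, seed)
    finally:
        log.removeHandler(handler)
        handler.close()
    return outdir
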