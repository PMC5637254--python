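"""Measure motif enrichment in the sequence windows flanking splicing events.

Half of the simulated retained-intron events play the role of a regulated
subset (in real data: events with a significant inclusion-level shift).  We
plant a GG-rich motif (GGNGG) at 15 occurrences/kb inside the retained
introns of that subset only — all other windows stay at the chance level of
random sequence (~3.9/kb) — and ask whether the stratified enrichment table
flags the planted (event type, region) cell against the whole-catalogue
background.
"""

from spliceflank.events import build_events, gene_bounds
from spliceflank.motifs import motif_enrichment_table
from spliceflank.regions import extract_regions, reverse_complement
from spliceflank.simulate import (SimulationConfig, make_genome_annotation,
                                  plant_motifs)

cfg = SimulationConfig(seed=42)
genome, transcripts, _ = make_genome_annotation(cfg)
events = build_events(transcripts)
bounds = gene_bounds(transcripts)

regions_of = {ev.event_id: extract_regions(ev, bounds[ev.gene_id])
              for ev in events}
ri_events = [ev for ev in events if ev.event_type == "RI"]
subset = ri_events[::2]  # every other retained-intron event
planted_windows = [r for ev in subset for r in regions_of[ev.event_id]
                   if r.region_label == "ASE"]
genome = plant_motifs(genome, planted_windows, "GGNGG", 15.0, seed=7)

# attach sense-strand sequences from the modified genome
background = [r for regs in regions_of.values() for r in regs]
for r in background:
    raw = genome[r.chrom][r.start:r.end]
    r.sequence = reverse_complement(raw) if r.strand == "-" else raw

stratum = [r for ev in subset for r in regions_of[ev.event_id]]
table = motif_enrichment_table({"regulated": stratum}, background, ["GGNGG"])
table = table[table["event_type"] == "RI"]
cols = ["event_type", "region", "density_per_kb",
        "background_density_per_kb", "enrichment", "p_value"]
print(table[cols].to_string(index=False, float_format="%.3g"))
top = table.sort_values("p_value").iloc[0]
print(f"\nthe planted cell (RI {top['region']}) stands out: "
      f"{top['density_per_kb']:.1f}/kb vs "
      f"{top['background_density_per_kb']:.1f}/kb background "
      f"({top['enrichment']:.2f}-fold, p = {top['p_value']:.2e})")
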