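"""Degenerate-motif counting, per-kilobase densities, enrichment ratios with
chi-squared significance, positional occurrence profiles, k-mer
over-representation, and the W-box promoter scan.

Motifs are fixed-length IUPAC patterns (e.g. GGNGG).  All start positions
are counted, including overlapping occurrences — the only self-consistent
convention for degenerate repeats such as GGNGGNGG.  An N in the scanned
sequence matches nothing.  Densities are per 1000 nt of scanned sequence;
chi-squared 2x2 tests use scan positions (sum of L-m+1) as the opportunity
denominator so motif length is handled correctly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .regions import FlankRegion, dedupe_regions

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]",
    "B": "[CGT]", "D": "[AGT]", "H": "[ACT]", "V": "[ACG]",
    "N": "[ACGT]",
}

#: The six fixed degenerate patterns scanned around splicing events, plus the
#: WRKY-binding W-box variants scanned in promoters.
DEFAULT_MOTIFS = {
    "GGNNNNGGNGG": "GGNNNNGGNGG",
    "GGNGGNGG": "GGNGGNGG",
    "GGNGG": "GGNGG",
    "CNNCNNCNNCNNC": "CNNCNNCNNCNNC",
    "CNCCNNCNCC": "CNCCNNCNCC",
    "CGNCGNCG": "CGNCGNCG",
}
WBOX_MOTIFS = ("TTTGAC", "TTGACC", "TTGACT")


@dataclass(frozen=True)
class MotifPattern:
    name: str
    pattern: str

    def __post_init__(self) -> None:
        pat = self.pattern.upper()
        if len(pat) < 2:
            raise ValueError(f"motif {self.name}: length must be >= 2")
        bad = set(pat) - set(IUPAC)
        if bad:
            raise ValueError(
                f"motif {self.name}: non-IUPAC characters {sorted(bad)}"
            )
        object.__setattr__(self, "pattern", pat)

    @property
    def regex(self) -> re.Pattern:
        return re.compile(
            "(?=" + "".join(IUPAC[c] for c in self.pattern) + ")"
        )

    def __len__(self) -> int:
        return len(self.pattern)


def _as_pattern(motif: MotifPattern | str) -> MotifPattern:
    if isinstance(motif, MotifPattern):
        return motif
    return MotifPattern(name=motif, pattern=motif)


def count_motif(sequence: str, motif: MotifPattern | str) -> int:
    """Number of (possibly overlapping) occurrence start positions."""
    m = _as_pattern(motif)
    if len(m) > len(sequence):
        return 0
    return len(m.regex.findall(sequence.upper()))


def occurrence_starts(sequence: str, motif: MotifPattern | str) -> list[int]:
    m = _as_pattern(motif)
    return [mm.start() for mm in m.regex.finditer(sequence.upper())]


def scan_positions(lengths: list[int], m: int) -> int:
    """Total motif-start opportunities: sum of max(L - m + 1, 0)."""
    return int(sum(max(L - m + 1, 0) for L in lengths))


def density_per_kb(total_count: int, total_length: int) -> float:
    """Occurrences per 1000 nt of sequence."""
    if total_length <= 0:
        raise ValueError("density undefined for zero scanned length")
    return total_count / total_length * 1000.0


def enrichment_ratio(test_density: float, background_density: float) -> float:
    """Ratio of test to background per-kb densities."""
    if background_density <= 0:
        raise ValueError("enrichment undefined for zero background density")
    return test_density / background_density


def chisq_motif_test(test_count: int, test_scan_positions: int,
                     bg_count: int, bg_scan_positions: int
                     ) -> tuple[float, float, bool]:
    """Pearson chi-squared (1 df, no continuity correction) on the 2x2 table
    of (occurrence, non-occurrence) positions in test vs background.
    Returns (statistic, p, degenerate); degenerate tables (a zero row or
    column total) yield (0, 1, True) rather than an error."""
    a, b = test_count, test_scan_positions - test_count
    c, d = bg_count, bg_scan_positions - bg_count
    if min(a, b, c, d) < 0:
        raise ValueError("counts exceed scan positions or are negative")
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 0.0, 1.0, True
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p), False


def _group_stats(regions: list[FlankRegion], motif: MotifPattern):
    seqs = [r.sequence for r in regions]
    if any(s is None for s in seqs):
        raise ValueError("regions must have sequences fetched")
    count = sum(count_motif(s, motif) for s in seqs)
    total_len = sum(len(s) for s in seqs)
    positions = scan_positions([len(s) for s in seqs], len(motif))
    return count, total_len, positions


def motif_enrichment_table(
    strata: dict[str, list[FlankRegion]],
    background: list[FlankRegion],
    motifs: list[MotifPattern | str],
) -> pd.DataFrame:
    """Per (motif, event type, region label, stratum) density/enrichment table.

    `strata` maps stratum names (e.g. "dpsi_pos"/"dpsi_neg") to the flank
    regions of the selected events; `background` holds the same region
    classes extracted over the full event catalogue.  Regions are
    deduplicated by genomic identity before counting.  Rows with an empty
    stratum or zero-background density are flagged degenerate and carry no
    test.
    """
    motifs = [_as_pattern(m) for m in motifs]
    bg = dedupe_regions(background)
    bg_groups: dict[tuple[str, str], list[FlankRegion]] = {}
    for r in bg:
        bg_groups.setdefault((r.event_type, r.region_label), []).append(r)

    rows = []
    for stratum in sorted(strata):
        groups: dict[tuple[str, str], list[FlankRegion]] = {}
        for r in dedupe_regions(strata[stratum]):
            groups.setdefault((r.event_type, r.region_label), []).append(r)
        for (etype, label) in sorted(set(groups) | set(bg_groups)):
            test_regions = groups.get((etype, label), [])
            bg_regions = bg_groups.get((etype, label), [])
            for motif in motifs:
                row = {
                    "motif": motif.name, "event_type": etype,
                    "region": label, "stratum": stratum,
                    "n_regions": len(test_regions),
                }
                if not test_regions or not bg_regions:
                    row.update(count=0, total_length=0, density_per_kb=np.nan,
                               background_density_per_kb=np.nan,
                               enrichment=np.nan, chi2=np.nan, p_value=np.nan,
                               degenerate=True)
                    rows.append(row)
                    continue
                tc, tl, tp = _group_stats(test_regions, motif)
                bc, bl, bp = _group_stats(bg_regions, motif)
                dens = density_per_kb(tc, tl) if tl else np.nan
                bdens = density_per_kb(bc, bl) if bl else np.nan
                enr = dens / bdens if bdens and bdens > 0 else (
                    0.0 if dens == 0 else np.nan)
                stat, p, degen = chisq_motif_test(tc, tp, bc, bp)
                row.update(count=tc, total_length=tl, density_per_kb=dens,
                           background_density_per_kb=bdens, enrichment=enr,
                           chi2=stat, p_value=p, degenerate=degen)
                rows.append(row)
    return pd.DataFrame(rows)


def positional_profile(
    anchored_sequences: list[tuple[str, int]],
    motifs: list[MotifPattern | str],
) -> pd.DataFrame:
    """Per-offset motif composition around a shared anchor.

    `anchored_sequences` is a list of (sequence, anchor_index) pairs; a motif
    occurrence starting at index i contributes at offset i - anchor_index.
    At each offset the returned fractions over the profiled motifs sum to 1
    (the share of each motif among all profiled-motif starts there).
    """
    motifs = [_as_pattern(m) for m in motifs]
    counts: dict[int, dict[str, int]] = {}
    for seq, anchor in anchored_sequences:
        for motif in motifs:
            for start in occurrence_starts(seq, motif):
                off = start - anchor
                counts.setdefault(off, {})[motif.name] = (
                    counts.get(off, {}).get(motif.name, 0) + 1
                )
    rows = []
    for off in sorted(counts):
        total = sum(counts[off].values())
        for motif in motifs:
            c = counts[off].get(motif.name, 0)
            rows.append({"offset": off, "motif": motif.name,
                         "count": c, "fraction": c / total})
    return pd.DataFrame(rows, columns=["offset", "motif", "count", "fraction"])


def kmer_overrepresentation(test_seqs: list[str], background_seqs: list[str],
                            k: int) -> pd.DataFrame:
    """One-sided binomial over-representation of every k-mer seen in the test
    set, against per-position background match frequency (with a +1
    pseudocount on background counts for k-mers unseen there)."""
    def kmer_counts(seqs):
        counts: dict[str, int] = {}
        positions = 0
        for s in seqs:
            s = s.upper()
            positions += max(len(s) - k + 1, 0)
            for i in range(len(s) - k + 1):
                km = s[i:i + k]
                if "N" in km:
                    continue
                counts[km] = counts.get(km, 0) + 1
        return counts, positions

    if not test_seqs:
        return pd.DataFrame(
            columns=["kmer", "test_count", "test_density_per_kb",
                     "bg_density_per_kb", "p_value"]
        )
    tc, tpos = kmer_counts(test_seqs)
    bc, bpos = kmer_counts(background_seqs)
    tlen = sum(len(s) for s in test_seqs)
    blen = sum(len(s) for s in background_seqs)
    rows = []
    for km in sorted(tc):
        bcount = bc.get(km, 0)
        if bcount == 0:
            bcount = 1  # pseudocount for unseen background k-mers
        p0 = min(bcount / bpos, 1.0) if bpos else 1.0
        p = float(stats.binom.sf(tc[km] - 1, tpos, p0))
        rows.append({
            "kmer": km, "test_count": tc[km],
            "test_density_per_kb": tc[km] / tlen * 1000 if tlen else np.nan,
            "bg_density_per_kb": bc.get(km, 0) / blen * 1000 if blen else np.nan,
            "p_value": p,
        })
    df = pd.DataFrame(rows)
    return df.sort_values("p_value", kind="stable").reset_index(drop=True)


def wbox_scan(upstream_seqs: dict[str, str],
              background_freqs: dict[str, float],
              motifs: tuple[str, ...] = WBOX_MOTIFS
              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scan gene-upstream (promoter) sequences for W-box variants.

    `upstream_seqs` maps gene id to its upstream sense-strand sequence
    (conventionally the 500 nt preceding the annotated gene start);
    `background_freqs` gives each motif's genome-background per-position
    match probability.  Returns (per-gene presence table, per-motif summary
    with occurrence counts and one-sided binomial p vs background).
    """
    motif_objs = [_as_pattern(m) for m in motifs]
    presence_rows = []
    totals = {m.name: 0 for m in motif_objs}
    positions = {m.name: 0 for m in motif_objs}
    for gene in sorted(upstream_seqs):
        seq = upstream_seqs[gene]
        row = {"gene_id": gene}
        for m in motif_objs:
            c = count_motif(seq, m)
            row[m.name] = c > 0
            totals[m.name] += c
            positions[m.name] += max(len(seq) - len(m) + 1, 0)
        presence_rows.append(row)
    summary_rows = []
    for m in motif_objs:
        if m.name not in background_freqs:
            raise KeyError(f"no background frequency for motif {m.name}")
        p0 = background_freqs[m.name]
        n = positions[m.name]
        p = float(stats.binom.sf(totals[m.name] - 1, n, p0)) if n else 1.0
        summary_rows.append({
            "motif": m.name, "occurrences": totals[m.name],
            "scan_positions": n, "background_freq": p0, "p_value": p,
        })
    return pd.DataFrame(presence_rows), pd.DataFrame(summary_rows)
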