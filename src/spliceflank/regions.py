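"""Extraction of the labeled sequence windows flanking each splicing event.

Each event type defines a fixed set of regions in transcript (5'->3')
orientation: exon windows abutting the relevant splice sites (UE, DE), the
alternatively spliced span itself (ASE; the retained intron for RI, the
skipped exon for SE, the span between the alternative sites for A5/A3), and
intron-end windows (UI5/UI3 for the upstream intron, DI5/DI3 for the
downstream intron).  Fixed windows are 50 nt by default; windows are clipped
at the gene span, and the two end-windows of one intron are truncated at the
intron midpoint when the intron is shorter than two window lengths, so no
nucleotide is counted twice within an intron.

Sequences are returned in sense (transcript) orientation: minus-strand
intervals are reverse-complemented.
"""

from __future__ import annotations

from dataclasses import dataclass

from pyfaidx import Fasta

from .events import SpliceEvent

REGION_LABELS = {
    "A5": ("UE", "ASE", "DI5", "DI3", "DE"),
    "A3": ("UE", "UI5", "UI3", "ASE", "DE"),
    "RI": ("UE", "ASE", "DE"),
    "SE": ("UE", "UI5", "UI3", "ASE", "DI5", "DI3", "DE"),
}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class FlankRegion:
    event_id: str
    event_type: str
    region_label: str
    chrom: str
    strand: str
    start: int
    end: int
    clipped: bool = False
    sequence: str | None = None

    @property
    def label(self) -> str:
        return f"{self.event_type}_{self.region_label}"

    @property
    def length(self) -> int:
        return self.end - self.start


class RegionError(ValueError):
    pass


def _upstream(pos: int, w: int, strand: str) -> tuple[int, int]:
    """Window of length w on the transcript-upstream side of boundary pos."""
    return (pos - w, pos) if strand == "+" else (pos, pos + w)


def _downstream(pos: int, w: int, strand: str) -> tuple[int, int]:
    return (pos, pos + w) if strand == "+" else (pos - w, pos)


def _intron_end_windows(i0: int, i1: int, w: int) -> tuple[tuple[int, int],
                                                           tuple[int, int]]:
    """Genomic-left and genomic-right end windows of intron [i0,i1),
    truncated at the midpoint when they would overlap."""
    if i1 - i0 >= 2 * w:
        return (i0, i0 + w), (i1 - w, i1)
    mid = i0 + (i1 - i0) // 2
    return (i0, mid), (mid, i1)


def extract_regions(event: SpliceEvent, gene_bounds: tuple[int, int],
                    window: int = 50) -> list[FlankRegion]:
    """Compute all labeled windows for one event, clipped to the gene span."""
    a = event.anchor_dict
    strand = event.strand
    gb_lo, gb_hi = gene_bounds
    for name, pos in event.anchors:
        if not (gb_lo <= pos <= gb_hi):
            raise RegionError(
                f"{event.event_id}: anchor {name}={pos} outside gene bounds "
                f"[{gb_lo},{gb_hi})"
            )

    raw: dict[str, tuple[int, int]] = {}

    if event.event_type == "RI":
        s, e = a["intron_start"], a["intron_end"]
        raw["UE"] = _upstream(s if strand == "+" else e, window, strand)
        raw["ASE"] = (s, e)
        raw["DE"] = _downstream(e if strand == "+" else s, window, strand)

    elif event.event_type in ("A5", "A3"):
        lo, hi, shared = a["alt_site_1"], a["alt_site_2"], a["shared_site"]
        # Geometry in genomic coordinates: the alternative sites sit at one
        # intron boundary, the shared site at the other.  The residual intron
        # (between the innermost alternative site and the shared site) hosts
        # the two intron-end windows.
        if shared > hi:  # alt sites on the genomic-left intron boundary
            intron = (hi, shared)
            outer_alt, shared_pos = lo, shared
        else:  # shared < lo: alt sites on the genomic-right boundary
            intron = (shared, lo)
            outer_alt, shared_pos = hi, shared
        left_w, right_w = _intron_end_windows(*intron, window)
        raw["ASE"] = (min(lo, hi), max(lo, hi))
        if event.event_type == "A5":
            # UE upstream of the more upstream donor; DI5 leads the residual
            # intron; DI3 trails it at the shared acceptor; DE follows.
            raw["UE"] = _upstream(outer_alt, window, strand)
            raw["DI5"], raw["DI3"] = (
                (left_w, right_w) if strand == "+" else (right_w, left_w)
            )
            raw["DE"] = _downstream(shared_pos, window, strand)
        else:
            # A3: UE precedes the shared donor; UI5/UI3 are the residual
            # intron ends; DE follows the more downstream acceptor.
            raw["UE"] = _upstream(shared_pos, window, strand)
            raw["UI5"], raw["UI3"] = (
                (left_w, right_w) if strand == "+" else (right_w, left_w)
            )
            raw["DE"] = _downstream(outer_alt, window, strand)

    elif event.event_type == "SE":
        x, astart = a["flank_left_end"], a["exon_start"]
        aend, y = a["exon_end"], a["flank_right_start"]
        up_intron, down_intron = (x, astart), (aend, y)
        ul, ur = _intron_end_windows(*up_intron, window)
        dl, dr = _intron_end_windows(*down_intron, window)
        raw["ASE"] = (astart, aend)
        if strand == "+":
            raw["UE"] = _upstream(x, window, strand)
            raw["UI5"], raw["UI3"] = ul, ur
            raw["DI5"], raw["DI3"] = dl, dr
            raw["DE"] = _downstream(y, window, strand)
        else:
            # transcript order reversed: the genomic-right intron is upstream
            raw["UE"] = _upstream(y, window, strand)
            raw["UI5"], raw["UI3"] = dr, dl
            raw["DI5"], raw["DI3"] = ur, ul
            raw["DE"] = _downstream(x, window, strand)
    else:  # pragma: no cover - SpliceEvent validates types
        raise RegionError(f"unknown event type {event.event_type}")

    regions = []
    for label in REGION_LABELS[event.event_type]:
        start, end = raw[label]
        cstart, cend = max(start, gb_lo), min(end, gb_hi)
        fixed = label not in ("ASE",)
        expected = window if fixed else end - start
        regions.append(FlankRegion(
            event_id=event.event_id, event_type=event.event_type,
            region_label=label, chrom=event.chrom, strand=event.strand,
            start=cstart, end=cend,
            clipped=(cend - cstart) < expected,
        ))
    return regions


def fetch_sequences(regions: list[FlankRegion], genome: str | Fasta) -> list[FlankRegion]:
    """Populate each region's sense-strand sequence from an indexed FASTA."""
    fa = genome if isinstance(genome, Fasta) else Fasta(genome)
    for r in regions:
        if r.chrom not in fa:
            raise RegionError(f"chromosome {r.chrom!r} absent from genome")
        chrom_len = len(fa[r.chrom])
        if r.start < 0 or r.end > chrom_len:
            raise RegionError(
                f"{r.event_id}|{r.label}: interval [{r.start},{r.end}) outside "
                f"chromosome {r.chrom} (length {chrom_len})"
            )
        seq = str(fa[r.chrom][r.start:r.end]).upper()
        r.sequence = reverse_complement(seq) if r.strand == "-" else seq
    return regions


def dedupe_regions(regions: list[FlankRegion]) -> list[FlankRegion]:
    """Drop duplicate windows arising from merged/overlapping events before
    density statistics (keyed on chrom, interval, strand, label)."""
    seen: set[tuple] = set()
    out = []
    for r in regions:
        key = (r.chrom, r.start, r.end, r.strand, r.label)
        if key not in seen:
            seen.add(key)
            out.append(r)
    return out


def write_bed(regions: list[FlankRegion], path: str) -> None:
    """BED6; name field is event_id|TYPE_LABEL."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.event_id}|{r.label}\t0\t"
                f"{r.strand}\n"
            )


def write_region_fasta(regions: list[FlankRegion], path: str) -> None:
    with open(path, "w") as fh:
        for r in regions:
            if r.sequence is None:
                raise RegionError(
                    f"{r.event_id}|{r.label}: sequence not fetched"
                )
            fh.write(f">{r.event_id}|{r.label}\n{r.sequence}\n")
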