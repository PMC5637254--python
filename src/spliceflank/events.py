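"""Alternative-splicing event catalogue construction from transcript annotation.

Events of four classes are generated from pairs of same-gene transcript
isoforms, SUPPA-ioe style:

* RI — retained intron: one splicing form splices an intron that the other
  carries inside a single exon with matching outer boundaries.
* SE — skipped exon: an internal exon present in one form is absent from the
  other, with identical flanking splice sites.
* A5 — alternative 5' (donor) splice site: two introns sharing their 3' end.
* A3 — alternative 3' (acceptor) splice site: two introns sharing their 5' end.

All internal coordinates are 0-based half-open on the genomic forward strand;
GTF I/O converts from/to 1-based inclusive.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import gffutils

EVENT_TYPES = ("A3", "A5", "RI", "SE")


class GtfParseError(ValueError):
    """Raised for malformed GTF input, naming the offending line."""


class EventFileError(ValueError):
    """Raised for malformed event TSV input."""


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript isoform: ordered, non-overlapping exon intervals."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        exons = tuple(sorted(tuple(e) for e in self.exons))
        object.__setattr__(self, "exons", exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 <= e1:
                raise ValueError(
                    f"transcript {self.transcript_id}: exons [{s1},{e1}) and "
                    f"[{s2},{e2}) overlap or are adjacent"
                )
        for s, e in exons:
            if e <= s:
                raise ValueError(
                    f"transcript {self.transcript_id}: empty exon [{s},{e})"
                )

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        )

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass(frozen=True)
class SpliceEvent:
    """One A3/A5/RI/SE event with its inclusion and exclusion isoform sets.

    ``anchors`` maps coordinate names to genomic positions (0-based
    boundaries).  The inclusion form is the one whose transcripts include
    the alternatively spliced span as exonic sequence (RI: the intron is
    retained; SE: the exon is included; A5/A3: the shorter intron is used, so
    the span between the two alternative sites stays exonic).  With this
    orientation a positive condition difference in psi means the span is
    included at a higher rate in the test (mutant) condition.
    """

    event_id: str
    event_type: str
    gene_id: str
    chrom: str
    strand: str
    anchors: tuple[tuple[str, int], ...]
    inclusion_transcripts: frozenset[str]
    exclusion_transcripts: frozenset[str]

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        if not self.inclusion_transcripts or not self.exclusion_transcripts:
            raise ValueError(f"{self.event_id}: empty transcript set")
        if self.inclusion_transcripts & self.exclusion_transcripts:
            raise ValueError(
                f"{self.event_id}: inclusion/exclusion sets overlap"
            )

    @property
    def anchor_dict(self) -> dict[str, int]:
        return dict(self.anchors)

    @property
    def transcripts(self) -> frozenset[str]:
        return self.inclusion_transcripts | self.exclusion_transcripts


def _event_id(gene_id: str, etype: str, chrom: str, strand: str,
              anchors: tuple[tuple[str, int], ...]) -> str:
    coords = "-".join(str(p) for _, p in sorted(anchors, key=lambda kv: kv[1]))
    return f"{gene_id};{etype}:{chrom}:{coords}:{strand}"


def _make_event(gene_id, etype, chrom, strand, anchors, incl, excl):
    anchors = tuple(sorted(anchors.items(), key=lambda kv: kv[1]))
    return SpliceEvent(
        event_id=_event_id(gene_id, etype, chrom, strand, anchors),
        event_type=etype,
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        anchors=anchors,
        inclusion_transcripts=frozenset(incl),
        exclusion_transcripts=frozenset(excl),
    )


# ---------------------------------------------------------------------------
# GTF parsing


def _prevalidate_gtf(gtf_path: str) -> None:
    # gffutils reports attribute problems but not tab-structure ones with a
    # line number; do that pass ourselves.
    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{gtf_path}: line {lineno}: expected 9 tab-separated "
                    f"fields, got {len(fields)}"
                )
            if fields[2] == "exon":
                try:
                    start, end = int(fields[3]), int(fields[4])
                except ValueError as exc:
                    raise GtfParseError(
                        f"{gtf_path}: line {lineno}: non-numeric coordinates"
                    ) from exc
                if start < 1 or end < start:
                    raise GtfParseError(
                        f"{gtf_path}: line {lineno}: bad coordinates "
                        f"{start}..{end}"
                    )
                if fields[6] not in ("+", "-"):
                    raise GtfParseError(
                        f"{gtf_path}: line {lineno}: bad strand {fields[6]!r}"
                    )


def parse_gtf(gtf_path: str) -> list[TranscriptModel]:
    """Read exon features from a GTF file into transcript models.

    GTF 1-based inclusive coordinates become 0-based half-open. Transcripts
    are returned sorted by (gene_id, transcript_id); exons sorted ascending.
    """
    _prevalidate_gtf(gtf_path)
    db = gffutils.create_db(
        gtf_path,
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    by_tx: dict[str, dict] = {}
    for feat in db.features_of_type("exon"):
        try:
            tx_id = feat.attributes["transcript_id"][0]
            gene_id = feat.attributes["gene_id"][0]
        except KeyError as exc:
            raise GtfParseError(
                f"{gtf_path}: exon feature at {feat.seqid}:{feat.start} "
                f"missing {exc} attribute"
            ) from exc
        rec = by_tx.setdefault(
            tx_id,
            {"gene_id": gene_id, "chrom": feat.seqid, "strand": feat.strand,
             "exons": []},
        )
        rec["exons"].append((feat.start - 1, feat.end))
    transcripts = []
    for tx_id in sorted(by_tx, key=lambda t: (by_tx[t]["gene_id"], t)):
        rec = by_tx[tx_id]
        transcripts.append(
            TranscriptModel(
                transcript_id=tx_id,
                gene_id=rec["gene_id"],
                chrom=rec["chrom"],
                strand=rec["strand"],
                exons=tuple(sorted(rec["exons"])),
            )
        )
    return transcripts


# ---------------------------------------------------------------------------
# Event construction


def _splice_forms(transcripts: list[TranscriptModel]):
    """Group same-gene transcripts by intron chain (identical chains are one
    splicing form); single-exon transcripts each keyed by their exon span."""
    forms: dict[tuple, dict] = {}
    for tx in transcripts:
        key = ("chain", tx.introns) if tx.introns else ("mono", tx.span)
        rec = forms.setdefault(key, {"tx": set(), "model": tx})
        rec["tx"].add(tx.transcript_id)
    return list(forms.values())


def _pair_events(form_a: dict, form_b: dict) -> list[dict]:
    """All events distinguishing two splicing forms of one gene."""
    a, b = form_a["model"], form_b["model"]
    out: list[dict] = []
    introns_a, introns_b = set(a.introns), set(b.introns)
    exons_a, exons_b = set(a.exons), set(b.exons)

    def emit(etype, anchors, incl_form, excl_form):
        out.append(
            {"etype": etype, "anchors": anchors,
             "incl": incl_form["tx"], "excl": excl_form["tx"]}
        )

    # RI: intron in one form, fully exonic in the other with matching outer
    # exon boundaries.
    for donor_form, keeper_form in ((form_a, form_b), (form_b, form_a)):
        dm, km = donor_form["model"], keeper_form["model"]
        k_exons = set(km.exons)
        for (x, s), (e, y) in zip(dm.exons, dm.exons[1:]):
            if (x, y) in k_exons:
                emit(
                    "RI",
                    {"exon_start": x, "intron_start": s,
                     "intron_end": e, "exon_end": y},
                    keeper_form, donor_form,
                )
    # SE: internal exon of one form absent from the other, identical
    # flanking splice sites (one intron (x,y) in the skipper spanning the
    # includer's two introns (x,a),(b,y) around exon [a,b)).
    for incl_form, skip_form in ((form_a, form_b), (form_b, form_a)):
        im, sm = incl_form["model"], skip_form["model"]
        s_introns = set(sm.introns)
        for i, (astart, aend) in enumerate(im.exons[1:-1], start=1):
            x = im.exons[i - 1][1]  # upstream intron donor boundary
            y = im.exons[i + 1][0]  # downstream intron acceptor boundary
            if (x, astart) in im.introns and (aend, y) in im.introns \
                    and (x, y) in s_introns:
                emit(
                    "SE",
                    {"flank_left_end": x, "exon_start": astart,
                     "exon_end": aend, "flank_right_start": y},
                    incl_form, skip_form,
                )
    # A5/A3: intron pairs sharing exactly one boundary. Which side is the
    # donor (5' splice site) depends on strand. Inclusion = shorter intron
    # (the span between the alternative sites stays exonic) — the span must
    # genuinely be exonic there, which excludes intron pairs that merely
    # bracket a skipped exon.
    def span_exonic(model: TranscriptModel, lo: int, hi: int) -> bool:
        return any(s <= lo and hi <= e for s, e in model.exons)

    for ia, ib in itertools.product(sorted(introns_a - introns_b),
                                    sorted(introns_b - introns_a)):
        shared_start = ia[0] == ib[0] and ia[1] != ib[1]
        shared_end = ia[1] == ib[1] and ia[0] != ib[0]
        if not (shared_start or shared_end):
            continue
        if shared_end:
            alt_lo, alt_hi = sorted((ia[0], ib[0]))
            shared = ia[1]
            etype = "A5" if a.strand == "+" else "A3"
            # shorter intron = the one starting at alt_hi
            short_form = form_a if ia[0] == alt_hi else form_b
            long_form = form_b if short_form is form_a else form_a
        else:
            alt_lo, alt_hi = sorted((ia[1], ib[1]))
            shared = ia[0]
            etype = "A3" if a.strand == "+" else "A5"
            short_form = form_a if ia[1] == alt_lo else form_b
            long_form = form_b if short_form is form_a else form_a
        if not span_exonic(short_form["model"], alt_lo, alt_hi):
            continue
        emit(
            etype,
            {"alt_site_1": alt_lo, "alt_site_2": alt_hi, "shared_site": shared},
            short_form, long_form,
        )
    return out


def build_events(transcripts: list[TranscriptModel]) -> list[SpliceEvent]:
    """Construct the deduplicated event catalogue from pairwise comparison of
    each gene's splicing forms. Events identical in (type, chrom, strand,
    anchors) merge their transcript sets."""
    by_gene: dict[str, list[TranscriptModel]] = {}
    for tx in transcripts:
        by_gene.setdefault(tx.gene_id, []).append(tx)

    merged: dict[tuple, dict] = {}
    for gene_id in sorted(by_gene):
        gene_tx = by_gene[gene_id]
        forms = _splice_forms(gene_tx)
        chrom, strand = gene_tx[0].chrom, gene_tx[0].strand
        for fa, fb in itertools.combinations(forms, 2):
            for raw in _pair_events(fa, fb):
                key = (
                    gene_id, raw["etype"], chrom, strand,
                    tuple(sorted(raw["anchors"].items())),
                )
                rec = merged.setdefault(key, {"incl": set(), "excl": set()})
                rec["incl"] |= raw["incl"]
                rec["excl"] |= raw["excl"]

    events = []
    for (gene_id, etype, chrom, strand, anchors), rec in sorted(merged.items()):
        events.append(
            _make_event(gene_id, etype, chrom, strand, dict(anchors),
                        rec["incl"], rec["excl"])
        )
    events.sort(key=lambda ev: ev.event_id)
    return events


# ---------------------------------------------------------------------------
# Event TSV I/O

_HEADER = ["event_id", "gene_id", "event_type", "chrom", "strand",
           "anchors", "inclusion_tx", "exclusion_tx"]


def write_events(events: list[SpliceEvent], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_HEADER) + "\n")
        for ev in events:
            anchors = ";".join(f"{k}={v}" for k, v in ev.anchors)
            fh.write("\t".join([
                ev.event_id, ev.gene_id, ev.event_type, ev.chrom, ev.strand,
                anchors,
                ",".join(sorted(ev.inclusion_transcripts)),
                ",".join(sorted(ev.exclusion_transcripts)),
            ]) + "\n")


def read_events(path: str) -> list[SpliceEvent]:
    events = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _HEADER:
            raise EventFileError(f"{path}: unexpected header {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(_HEADER):
                raise EventFileError(f"{path}: line {lineno}: wrong field count")
            (event_id, gene_id, etype, chrom, strand,
             anchors_s, incl_s, excl_s) = fields
            if etype not in EVENT_TYPES:
                raise EventFileError(
                    f"{path}: line {lineno}: unknown event_type {etype!r}"
                )
            anchors = tuple(
                (k, int(v))
                for k, v in (kv.split("=") for kv in anchors_s.split(";"))
            )
            events.append(SpliceEvent(
                event_id=event_id, event_type=etype, gene_id=gene_id,
                chrom=chrom, strand=strand,
                anchors=tuple(sorted(anchors, key=lambda kv: kv[1])),
                inclusion_transcripts=frozenset(incl_s.split(",")),
                exclusion_transcripts=frozenset(excl_s.split(",")),
            ))
    return events


def gene_bounds(transcripts: list[TranscriptModel]) -> dict[str, tuple[int, int]]:
    """Genomic span (min exon start, max exon end) of each gene."""
    bounds: dict[str, tuple[int, int]] = {}
    for tx in transcripts:
        s, e = tx.span
        if tx.gene_id in bounds:
            bs, be = bounds[tx.gene_id]
            bounds[tx.gene_id] = (min(bs, s), max(be, e))
        else:
            bounds[tx.gene_id] = (s, e)
    return bounds
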