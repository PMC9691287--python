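"""Protein-level consequences of splice events.

Given a transcript model (ordered exons on a genomic locus, an annotated
ORF, and the locus sequence) and a splice event, this module reconstructs
the variant isoform and calls its consequence:

* frame status -- a length change not divisible by 3 shifts the reading frame;
* the first in-frame stop codon of the variant (a PTC when upstream of the
  annotated one);
* NMD prediction by the 50-nt rule: a stop more than 50 nt upstream of the
  last exon-exon junction is predicted to trigger nonsense-mediated decay,
  while a stop in the last exon escapes;
* domain truncation: annotated protein domains that are removed by the event
  or left downstream of the new stop are reported lost.

All genomic coordinates are 0-based half-open; transcript coordinates run
5'->3' in transcript orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .splicing import SpliceEvent

STOP_CODONS = {"TAA", "TAG", "TGA"}
NMD_DISTANCE_NT = 50  # stop >= this far upstream of the last junction => NMD
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


class StructuralMismatchError(ValueError):
    """The splice event does not fit the transcript's exon/intron structure."""


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class TranscriptModel:
    """A transcript: ordered exons on a locus plus an annotated ORF.

    ``exons`` are locus-relative 0-based half-open intervals in genomic
    order; ``locus_seq`` is the plus-strand sequence of the locus, so intron
    sequence is available for intron-retention variants. ``cds_start`` /
    ``cds_end`` are transcript-relative (half-open, cds_end just past the
    stop codon).
    """

    transcript_id: str
    gene_id: str
    exons: list[tuple[int, int]]
    cds_start: int
    cds_end: int
    locus_seq: str
    chrom: str = "chr1"
    strand: str = "+"

    def __post_init__(self) -> None:
        ex = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if e1 > s2:
                raise ValueError(f"overlapping exons in {self.transcript_id}")
        self.exons = ex

    @property
    def spliced_seq(self) -> str:
        seq = "".join(self.locus_seq[s:e] for s, e in self.exons)
        return _revcomp(seq) if self.strand == "-" else seq

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def exon_lengths(self) -> list[int]:
        """Exon lengths in transcript (5'->3') order."""
        lens = [e - s for s, e in self.exons]
        return lens[::-1] if self.strand == "-" else lens

    def transcript_to_genomic(self, pos: int) -> int:
        """Map a transcript coordinate to a locus coordinate."""
        if not 0 <= pos < self.spliced_length:
            raise IndexError(f"transcript position {pos} out of range")
        if self.strand == "-":
            pos = self.spliced_length - 1 - pos
        for s, e in self.exons:
            if pos < e - s:
                return s + pos
            pos -= e - s
        raise AssertionError("unreachable")

    def genomic_to_transcript(self, gpos: int) -> int | None:
        """Map a locus coordinate into transcript space, None if intronic."""
        off = 0
        hit = None
        for s, e in self.exons:
            if s <= gpos < e:
                hit = off + (gpos - s)
                break
            off += e - s
        if hit is None:
            return None
        return self.spliced_length - 1 - hit if self.strand == "-" else hit


@dataclass
class IsoformVariant:
    """A transcript after one splice event has been applied."""

    base: TranscriptModel
    applied_event: SpliceEvent
    inclusion: bool
    exons: list[tuple[int, int]] = field(default_factory=list)
    seq: str = ""
    cds_start: int | None = None  # None when the start codon is destroyed
    delta_length: int = 0

    def as_model(self) -> TranscriptModel:
        """View the variant as a transcript model (for chained events)."""
        cds_start = self.cds_start if self.cds_start is not None else 0
        return TranscriptModel(
            transcript_id=f"{self.base.transcript_id}|{self.applied_event.event_id}"
            f"|{'inc' if self.inclusion else 'skip'}",
            gene_id=self.base.gene_id,
            exons=list(self.exons),
            cds_start=cds_start,
            cds_end=cds_start,
            locus_seq=self.base.locus_seq,
            chrom=self.base.chrom,
            strand=self.base.strand,
        )

    def exon_lengths(self) -> list[int]:
        lens = [e - s for s, e in self.exons]
        return lens[::-1] if self.base.strand == "-" else lens

    def transcript_to_genomic(self, pos: int) -> int:
        return self.as_model().transcript_to_genomic(pos)

    def genomic_to_transcript(self, gpos: int) -> int | None:
        return self.as_model().genomic_to_transcript(gpos)


@dataclass
class ConsequenceCall:
    """Protein-level consequence of one event-isoform."""

    transcript_id: str
    event_id: str
    inclusion: bool
    delta_length: int
    frame_preserving: bool
    stop_pos: int | None
    stop_in_last_exon: bool
    nmd_predicted: bool
    lost_domains: list[str]
    truncated_domains: list[str]
    category: str  # frame-preserving | frameshift-NMD | frameshift-escape-alt-terminus | no-ORF
    alt_start: bool = False  # True when called from a rescued downstream AUG


def _exon_spanning(exons: list[tuple[int, int]], seg: tuple[int, int]) -> int | None:
    for i, (s, e) in enumerate(exons):
        if s <= seg[0] and seg[1] <= e:
            return i
    return None


def apply_event(
    transcript: TranscriptModel, event: SpliceEvent, inclusion: bool
) -> IsoformVariant:
    """Splice one event into/out of a transcript model.

    ``inclusion=True`` produces the cassette-in / intron-retained /
    long-segment form; ``inclusion=False`` the complementary form. Applying
    the form the transcript already has returns an identical sequence with
    ``delta_length == 0``.
    """
    exons = list(transcript.exons)
    seg = event.segments
    try:
        if event.etype == "SE":
            cassette = seg["cassette"]
            present = cassette in exons
            if inclusion and not present:
                u = _exon_spanning(exons, seg["upstream"])
                d = _exon_spanning(exons, seg["downstream"])
                if u is None or d is None:
                    raise StructuralMismatchError(
                        f"flanking exons of {event.event_id} not found in "
                        f"{transcript.transcript_id}"
                    )
                exons.append(cassette)
                exons.sort()
            elif not inclusion and present:
                exons.remove(cassette)
            elif not inclusion and not present:
                # skipping form of a transcript that already skips: verify flanks
                if _exon_spanning(exons, seg["upstream"]) is None:
                    raise StructuralMismatchError(
                        f"{event.event_id} does not fit {transcript.transcript_id}"
                    )
        elif event.etype == "RI":
            intron = seg["intron"]
            merged = next(
                (i for i, (s, e) in enumerate(exons) if s < intron[0] and intron[1] < e),
                None,
            )
            if inclusion and merged is None:
                iu = next((i for i, (_, e) in enumerate(exons) if e == intron[0]), None)
                idn = next((i for i, (s, _) in enumerate(exons) if s == intron[1]), None)
                if iu is None or idn is None:
                    raise StructuralMismatchError(
                        f"intron of {event.event_id} has no flanking exons in "
                        f"{transcript.transcript_id}"
                    )
                new = (exons[iu][0], exons[idn][1])
                exons = [x for i, x in enumerate(exons) if i not in (iu, idn)]
                exons.append(new)
                exons.sort()
            elif not inclusion and merged is not None:
                s, e = exons.pop(merged)
                exons.extend([(s, intron[0]), (intron[1], e)])
                exons.sort()
        elif event.etype in ("A5SS", "A3SS"):
            long_, short = seg["long"], seg["short"]
            want, other = (long_, short) if inclusion else (short, long_)
            if want not in exons:
                if other in exons:
                    exons[exons.index(other)] = want
                    exons.sort()
                else:
                    raise StructuralMismatchError(
                        f"neither splice-site form of {event.event_id} matches "
                        f"an exon of {transcript.transcript_id}"
                    )
        else:  # pragma: no cover - guarded by SpliceEvent
            raise StructuralMismatchError(f"unknown event type {event.etype}")
    except KeyError as exc:
        raise StructuralMismatchError(
            f"event {event.event_id} lacks segment {exc} required for {event.etype}"
        ) from exc

    variant = IsoformVariant(
        base=transcript, applied_event=event, inclusion=inclusion, exons=exons
    )
    seq = "".join(transcript.locus_seq[s:e] for s, e in exons)
    variant.seq = _revcomp(seq) if transcript.strand == "-" else seq
    variant.delta_length = len(variant.seq) - transcript.spliced_length

    # carry the annotated start over, if its genomic position survived
    g_start = transcript.transcript_to_genomic(transcript.cds_start)
    variant.cds_start = variant.genomic_to_transcript(g_start)
    return variant


def apply_events(
    transcript: TranscriptModel, events: list[tuple[SpliceEvent, bool]]
) -> IsoformVariant:
    """Apply several events in order; delta and start are vs the original.

    Used for co-occurring events such as a skipped cassette-exon pair.
    """
    if not events:
        raise ValueError("at least one event is required")
    model = transcript
    variant = None
    for ev, incl in events:
        variant = apply_event(model, ev, incl)
        model = variant.as_model()
    variant.base = transcript
    variant.delta_length = len(variant.seq) - transcript.spliced_length
    g_start = transcript.transcript_to_genomic(transcript.cds_start)
    variant.cds_start = variant.genomic_to_transcript(g_start)
    return variant


def frame_status(delta_length: int) -> bool:
    """True iff the length change preserves the reading frame."""
    return delta_length % 3 == 0


def scan_orf(seq: str, cds_start: int | None) -> int | None:
    """Position of the first in-frame stop codon from ``cds_start``.

    Returns the transcript coordinate of the stop codon's first base, or
    None when no stop occurs before the transcript end (or the start was
    destroyed by the event).
    """
    if cds_start is None:
        return None
    for i in range(cds_start, len(seq) - 2, 3):
        if seq[i : i + 3].upper() in STOP_CODONS:
            return i
    return None


def _last_junction(exon_lengths: list[int]) -> int | None:
    """Transcript coordinate of the last exon-exon junction, None if single-exon."""
    if len(exon_lengths) < 2:
        return None
    return sum(exon_lengths[:-1])


def nmd_predict(variant: IsoformVariant, stop_pos: int) -> tuple[bool, bool]:
    """Apply the 50-nt rule to a stop codon position.

    Returns ``(nmd_predicted, stop_in_last_exon)``. NMD is predicted iff the
    stop lies at least 50 nt upstream of the last exon-exon junction; a stop
    in the last exon (or a single-exon variant) escapes.
    """
    if not 0 <= stop_pos <= len(variant.seq) - 3:
        raise ValueError(f"stop position {stop_pos} outside variant")
    lj = _last_junction(variant.exon_lengths())
    if lj is None:
        return (False, True)
    in_last = stop_pos >= lj
    nmd = (not in_last) and (lj - stop_pos >= NMD_DISTANCE_NT)
    return (nmd, in_last)


def find_alt_start(variant: IsoformVariant, min_codons: int = 30) -> int | None:
    """First AUG downstream of the event's disruption with a usable frame.

    Used when the annotated ORF yields no stop (or no start): scans for the
    first ATG at or after the point where variant and reference sequences
    diverge whose open reading frame reaches a stop codon after at least
    ``min_codons`` codons. Calls made from such a start are flagged
    low-confidence.
    """
    ref = variant.base.spliced_seq
    var = variant.seq
    div = 0
    for div in range(min(len(ref), len(var))):
        if ref[div] != var[div]:
            break
    else:
        div = min(len(ref), len(var))
    pos = var.find("ATG", div)
    while pos != -1:
        stop = scan_orf(var, pos)
        if stop is not None and (stop - pos) // 3 >= min_codons:
            return pos
        pos = var.find("ATG", pos + 1)
    return None


def domain_truncation(
    variant: IsoformVariant,
    domains: pd.DataFrame,
    stop_pos: int | None = None,
) -> tuple[list[str], list[str]]:
    """Domains lost or truncated by a splice event.

    ``domains`` has columns domain_id, start, end in *reference transcript*
    coordinates and must lie within the reference CDS. A domain is **lost**
    when its coding bases are entirely absent from the variant or when it
    maps downstream of the variant's stop codon; a domain only partially
    removed is reported as **truncated**. Returns ``(lost_ids, truncated_ids)``.
    """
    base = variant.base
    if stop_pos is None:
        stop_pos = scan_orf(variant.seq, variant.cds_start)
    lost, truncated = [], []
    for _, row in domains.iterrows():
        d0, d1 = int(row["start"]), int(row["end"])
        if d0 < base.cds_start or d1 > base.cds_end:
            raise ValueError(
                f"domain {row['domain_id']} [{d0},{d1}) outside the CDS "
                f"[{base.cds_start},{base.cds_end}) of {base.transcript_id}"
            )
        mapped = [
            variant.genomic_to_transcript(base.transcript_to_genomic(p))
            for p in range(d0, d1)
        ]
        surviving = [m for m in mapped if m is not None]
        if not surviving:
            lost.append(row["domain_id"])
        elif len(surviving) < d1 - d0:
            truncated.append(row["domain_id"])
        elif stop_pos is None and variant.cds_start is None:
            lost.append(row["domain_id"])  # no ORF at all
        elif stop_pos is not None and min(surviving) >= stop_pos:
            lost.append(row["domain_id"])
    return lost, truncated


def classify_consequence(
    variant: IsoformVariant,
    domains: pd.DataFrame | None = None,
    allow_alt_start: bool = True,
) -> ConsequenceCall:
    """Full consequence call for one event-isoform.

    Categories:

    * ``frame-preserving`` -- length change divisible by 3;
    * ``frameshift-NMD`` -- frameshift whose PTC triggers the 50-nt rule;
    * ``frameshift-escape-alt-terminus`` -- frameshift whose stop escapes NMD
      (stop in the last exon, or rescued via a downstream AUG);
    * ``no-ORF`` -- no usable start or no stop codon reachable.
    """
    alt = False
    start = variant.cds_start
    stop = scan_orf(variant.seq, start)
    if (start is None or stop is None) and allow_alt_start:
        alt_start = find_alt_start(variant)
        if alt_start is not None:
            start, alt = alt_start, True
            stop = scan_orf(variant.seq, start)
    fp = frame_status(variant.delta_length)
    if stop is None:
        nmd, in_last = False, False
        category = "frame-preserving" if fp else "no-ORF"
        if start is None or stop is None:
            category = "no-ORF"
    else:
        nmd, in_last = nmd_predict(variant, stop)
        if fp:
            category = "frame-preserving"
        elif nmd:
            category = "frameshift-NMD"
        else:
            category = "frameshift-escape-alt-terminus"
    lost: list[str] = []
    trunc: list[str] = []
    if domains is not None and len(domains):
        dd = domains[domains["transcript_id"] == variant.base.transcript_id]
        if len(dd):
            lost, trunc = domain_truncation(variant, dd, stop_pos=stop)
    return ConsequenceCall(
        transcript_id=variant.base.transcript_id,
        event_id=variant.applied_event.event_id,
        inclusion=variant.inclusion,
        delta_length=variant.delta_length,
        frame_preserving=fp,
        stop_pos=stop,
        stop_in_last_exon=in_last,
        nmd_predicted=nmd,
        lost_domains=lost,
        truncated_domains=trunc,
        category=category,
        alt_start=alt,
    )


def calls_to_frame(calls: list[ConsequenceCall]) -> pd.DataFrame:
    """Tabulate consequence calls for TSV output."""
    rows = []
    for c in calls:
        rows.append(
            {
                "transcript_id": c.transcript_id,
                "event_id": c.event_id,
                "form": "inclusion" if c.inclusion else "skipping",
                "delta_length": c.delta_length,
                "frame_preserving": c.frame_preserving,
                "stop_pos": -1 if c.stop_pos is None else c.stop_pos,
                "stop_in_last_exon": c.stop_in_last_exon,
                "nmd_predicted": c.nmd_predicted,
                "lost_domains": ",".join(c.lost_domains),
                "truncated_domains": ",".join(c.truncated_domains),
                "category": c.category,
                "alt_start": c.alt_start,
            }
        )
    return pd.DataFrame(rows)
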