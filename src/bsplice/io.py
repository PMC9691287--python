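"""Reading and writing the pipeline's plain-text formats.

Counts and metadata are TSV; gene sets are two-column TSV (set_id, gene_id)
or GMT; splice events and junction counts are TSV; transcript fixtures are
written as GTF (1-based, closed -- converted at the boundary from the
package's 0-based half-open convention) plus a locus FASTA and a
transcript-space domain BED.
"""

from __future__ import annotations

import json
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import CountMatrix
from .consequence import TranscriptModel
from .splicing import SpliceEvent
from .synthetic import SimulationTruth


# ---------------------------------------------------------------- counts TSV

def write_counts(cm: CountMatrix, counts_path, metadata_path) -> None:
    df = cm.counts.copy()
    df.index.name = "gene_id"
    df.to_csv(counts_path, sep="\t")
    meta = pd.DataFrame(
        {"sample": cm.sample_ids, "condition": [cm.condition_of[s] for s in cm.sample_ids]}
    )
    meta.to_csv(metadata_path, sep="\t", index=False)


def read_counts(counts_path, metadata_path) -> CountMatrix:
    df = pd.read_csv(counts_path, sep="\t", index_col="gene_id")
    meta = pd.read_csv(metadata_path, sep="\t")
    cond = dict(zip(meta["sample"].astype(str), meta["condition"].astype(str)))
    return CountMatrix(df, cond)


# ------------------------------------------------------------------ gene sets

def read_genesets(path) -> dict[str, set[str]]:
    """Two-column TSV (set_id, gene_id) or GMT, decided by extension."""
    path = Path(path)
    sets: dict[str, set[str]] = {}
    if path.suffix.lower() == ".gmt":
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    continue
                sets[parts[0]] = set(g for g in parts[2:] if g)
    else:
        df = pd.read_csv(path, sep="\t")
        for sid, grp in df.groupby(df.columns[0]):
            sets[str(sid)] = set(grp[df.columns[1]].astype(str))
    return sets


def write_genesets(sets: dict[str, set[str]], path) -> None:
    rows = [
        {"set_id": sid, "gene_id": g} for sid in sorted(sets) for g in sorted(sets[sid])
    ]
    pd.DataFrame(rows, columns=["set_id", "gene_id"]).to_csv(path, sep="\t", index=False)


# -------------------------------------------------------- events & junctions

def write_events(events: list[SpliceEvent], path) -> None:
    rows = []
    for e in events:
        segs = ";".join(f"{k}:{s}-{t}" for k, (s, t) in sorted(e.segments.items()))
        rows.append(
            {
                "event_id": e.event_id,
                "gene_id": e.gene_id,
                "etype": e.etype,
                "chrom": e.chrom,
                "strand": e.strand,
                "segments": segs,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_events(path) -> list[SpliceEvent]:
    df = pd.read_csv(path, sep="\t")
    events = []
    for _, r in df.iterrows():
        segments = {}
        if isinstance(r["segments"], str) and r["segments"]:
            for part in r["segments"].split(";"):
                name, span = part.split(":")
                s, t = span.split("-")
                segments[name] = (int(s), int(t))
        events.append(
            SpliceEvent(
                event_id=str(r["event_id"]),
                gene_id=str(r["gene_id"]),
                etype=str(r["etype"]),
                chrom=str(r["chrom"]),
                strand=str(r["strand"]),
                segments=segments,
            )
        )
    return events


def write_junctions(junctions: pd.DataFrame, path) -> None:
    junctions.to_csv(path, sep="\t", index=False)


def read_junctions(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", dtype={"event_id": str, "sample": str, "inc_reads": int, "skip_reads": int}
    )


# ----------------------------------------------------------------- truth JSON

def write_truth(truth: SimulationTruth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1, sort_keys=True)


def read_truth(path) -> SimulationTruth:
    with open(path) as fh:
        d = json.load(fh)
    psi = None
    if d.get("true_psi") is not None:
        psi = pd.DataFrame.from_dict(d["true_psi"], orient="index")
    return SimulationTruth(
        de_genes={k: float(v) for k, v in d["de_genes"].items()},
        true_psi=psi,
        planted_tf=d["planted_tf"],
        planted_targets=tuple(d["planted_targets"]),
    )


# --------------------------------------------------------- GTF / FASTA / BED

def write_gtf(transcripts: list[TranscriptModel], path) -> None:
    """GTF (1-based, closed intervals) with exon and CDS features."""
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            tx_exons = sorted(t.exons)
            for s, e in tx_exons:
                fh.write(
                    f"{t.chrom}\tbsplice\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
                )
            # CDS: map the transcript-space ORF to genomic intervals
            g = sorted(
                t.transcript_to_genomic(p) for p in range(t.cds_start, t.cds_end)
            )
            # collapse consecutive positions into intervals
            blocks: list[list[int]] = []
            for p in g:
                if blocks and p == blocks[-1][1]:
                    blocks[-1][1] = p + 1
                else:
                    blocks.append([p, p + 1])
            for s, e in blocks:
                fh.write(
                    f"{t.chrom}\tbsplice\tCDS\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
                )


def write_locus_fasta(transcripts: list[TranscriptModel], path) -> None:
    """One FASTA record per locus (chromosome)."""
    seen: dict[str, str] = {}
    for t in transcripts:
        seen.setdefault(t.chrom, t.locus_seq)
    records = [SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in seen.items()]
    SeqIO.write(records, str(path), "fasta")


def read_gtf(gtf_path, fasta_path) -> list[TranscriptModel]:
    """Reconstruct transcript models from GTF + locus FASTA."""
    db = gffutils.create_db(
        str(gtf_path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    loci = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    by_tx: dict[str, dict] = {}
    for feat in db.all_features():
        tid = feat.attributes["transcript_id"][0]
        entry = by_tx.setdefault(
            tid,
            {
                "gene_id": feat.attributes["gene_id"][0],
                "chrom": feat.seqid,
                "strand": feat.strand,
                "exons": [],
                "cds": [],
            },
        )
        iv = (feat.start - 1, feat.end)  # back to 0-based half-open
        if feat.featuretype == "exon":
            entry["exons"].append(iv)
        elif feat.featuretype == "CDS":
            entry["cds"].append(iv)
    out = []
    for tid, entry in by_tx.items():
        model = TranscriptModel(
            transcript_id=tid,
            gene_id=entry["gene_id"],
            exons=sorted(entry["exons"]),
            cds_start=0,
            cds_end=0,
            locus_seq=loci[entry["chrom"]],
            chrom=entry["chrom"],
            strand=entry["strand"],
        )
        cds = sorted(entry["cds"])
        if cds:
            tx_positions = []
            for s, e in cds:
                tx_positions.append(model.genomic_to_transcript(s))
                tx_positions.append(model.genomic_to_transcript(e - 1))
            lo = min(p for p in tx_positions if p is not None)
            hi = max(p for p in tx_positions if p is not None)
            model.cds_start, model.cds_end = lo, hi + 1
        out.append(model)
    return out


def write_domain_bed(domains: pd.DataFrame, path) -> None:
    """Domain intervals in transcript space as BED (chrom = transcript id)."""
    bed = domains[["transcript_id", "start", "end", "domain_id"]]
    bed.to_csv(path, sep="\t", index=False, header=False)


def read_domain_bed(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["transcript_id", "start", "end", "domain_id"]
    )
    return df[["transcript_id", "domain_id", "start", "end"]]
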