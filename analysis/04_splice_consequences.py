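#!/usr/bin/env python
"""Protein-level consequence calls for the exemplar splice events: frame
status, PTC position, NMD prediction by the 50-nt rule, and kelch-repeat
loss on the KLHL12-like fixture."""

from pathlib import Path

from bsplice import io
from bsplice.consequence import (
    apply_event,
    apply_events,
    calls_to_frame,
    classify_consequence,
)
from bsplice.synthetic import build_toy_annotation, toy_events

OUT = Path("results/consequence")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    transcripts, domains = build_toy_annotation()
    by_id = {t.transcript_id: t for t in transcripts}
    ev = toy_events()

    calls = []
    # each exemplar in its biologically interesting (non-reference) form
    singles = [
        ("SEC24C_t1", "SE_SEC24C_e11", False),   # 116-nt exon skipped
        ("SEC24D_t1", "SE_SEC24D_poison", True),  # 296-nt poison exon included
        ("KLHL12_t1", "SE_KLHL12_e10", False),    # 99 nt, frame-preserving
        ("KLHL12_t1", "SE_KLHL12_e11", False),    # 187 nt, frameshift
        ("SEC31A_t1", "SE_SEC31A_alt", True),     # 50-nt exon, alt-start rescue
        ("PICALM_t1", "SE_PICALM_e13", False),    # delta-13 isoform
        ("PICALM_t1", "SE_PICALM_e17", False),    # delta-17 isoform
        ("NERF2_t1", "A3SS_NERF_e7", False),      # exon-7 proximal 3'SS lost
    ]
    for tid, eid, flag in singles:
        v = apply_event(by_id[tid], ev[eid], inclusion=flag)
        calls.append(classify_consequence(v, domains))
    # the joint cassette-pair skip (delta-10,11)
    v = apply_events(
        by_id["KLHL12_t1"],
        [(ev["SE_KLHL12_e10"], False), (ev["SE_KLHL12_e11"], False)],
    )
    calls.append(classify_consequence(v, domains))

    frame = calls_to_frame(calls)
    frame.to_csv(OUT / "consequences.tsv", sep="\t", index=False)
    for _, row in frame.iterrows():
        extra = f", lost domains: {row.lost_domains}" if row.lost_domains else ""
        alt = " (alt-start, low confidence)" if row.alt_start else ""
        print(f"{row.transcript_id} {row.event_id} [{row.form}] "
              f"delta={row.delta_length:+d} -> {row.category}{alt}{extra}")
    print(f"written to {OUT / 'consequences.tsv'}")


if __name__ == "__main__":
    main()
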