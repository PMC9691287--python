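#!/usr/bin/env python
"""Generate the full synthetic study: a 4-stage x 3-replicate B-cell panel
with planted differential expression and a TF->targets co-regulation
structure, a 17-tissue validation panel, junction counts at planted true
PSI, and the toy transcript annotation. Everything downstream reads from
results/sim/."""

from pathlib import Path

from bsplice import io
from bsplice.synthetic import (
    SimulationConfig,
    build_toy_annotation,
    generate_counts,
    generate_junction_counts,
    generate_tissue_panel,
    plant_true_psi,
    synthetic_event_set,
)

SEED = 1
OUT = Path("results/sim")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimulationConfig(seed=SEED)
    panel, truth = generate_counts(cfg)
    tissue = generate_tissue_panel(cfg, truth)
    events = synthetic_event_set(200, seed=SEED)
    truth.true_psi = plant_true_psi(events, cfg.conditions, seed=SEED)
    junctions = generate_junction_counts(cfg, events, truth.true_psi)

    io.write_counts(panel, OUT / "counts.tsv", OUT / "samples.tsv")
    io.write_counts(tissue, OUT / "tissue_counts.tsv", OUT / "tissue_samples.tsv")
    io.write_events(events, OUT / "events.tsv")
    io.write_junctions(junctions, OUT / "junctions.tsv")
    io.write_truth(truth, OUT / "truth.json")

    transcripts, domains = build_toy_annotation()
    io.write_gtf(transcripts, OUT / "toy_annotation.gtf")
    io.write_locus_fasta(transcripts, OUT / "toy_loci.fa")
    io.write_domain_bed(domains, OUT / "toy_domains.bed")

    tf_ids = {g for g in panel.gene_ids if g.startswith("TF")}
    genesets = {
        "GO:0008134": tf_ids,
        "GO:0000981": tf_ids,
        "planted_de": set(truth.de_genes),
    }
    io.write_genesets(genesets, OUT / "genesets.tsv")

    print(f"B-cell panel: {panel.counts.shape[0]} genes x {len(panel.sample_ids)} samples")
    print(f"tissue panel: {len(tissue.sample_ids)} tissues")
    print(f"planted DE genes: {len(truth.de_genes)} at |log2FC| = {cfg.de_log2fc}")
    print(f"planted TF: {truth.planted_tf} -> targets {', '.join(truth.planted_targets)}")
    print(f"splice events: {len(events)} "
          f"({len(truth.true_psi.attrs['differential_events'])} with a planted MBC shift)")
    print(f"all inputs written to {OUT}/")


if __name__ == "__main__":
    main()
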