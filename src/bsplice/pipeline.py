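"""End-to-end orchestration: simulate -> de -> splice -> consequence -> tfscreen.

A flat :class:`RunConfig` carries every stage parameter, defaulting to the
study's thresholds (Padj < 0.001, |log2FC| > 0.5; p < 0.001, |dPSI| > 0.4;
FDR < 0.05; r > 0.9). :func:`run_pipeline` executes the toggled stages,
writes per-stage TSVs plus a machine-readable summary JSON, and logs to
stderr and a run log file with ISO-8601 timestamps.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, io
from .consequence import apply_event, calls_to_frame, classify_consequence
from .expression import de_test, go_enrichment
from .screen import (
    ScreenConfig,
    candidate_tfs,
    discovery_screen,
    rank_tfs,
    validate_in_tissues,
)
from .splicing import differential_psi, direction_summary, event_breakdown, psi_matrix
from .synthetic import (
    PLANTED_TF_ID,
    SimulationConfig,
    build_toy_annotation,
    generate_counts,
    generate_junction_counts,
    generate_tissue_panel,
    plant_true_psi,
    synthetic_event_set,
    toy_events,
)


class ConfigError(ValueError):
    """One or more invalid configuration entries, reported together."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


@dataclass
class RunConfig:
    """Flat configuration for a full pipeline run."""

    outdir: str = "results/run"
    seed: int = 0
    # stage toggles
    run_simulate: bool = True
    run_de: bool = True
    run_enrich: bool = True
    run_splice: bool = True
    run_consequence: bool = True
    run_tfscreen: bool = True
    # stage parameters, defaults = the study's cut-offs
    alpha: float = 0.001
    lfc_cut: float = 0.5
    p_cut: float = 0.001
    dpsi_cut: float = 0.4
    fdr_cut: float = 0.05
    r_threshold: float = 0.9
    # comparison and simulation sizing
    group_a: str = "PC"
    group_b: str = "MBC"
    n_genes: int = 2000
    n_events: int = 200
    junction_depth: int = 1000
    # optional pre-existing inputs (used when run_simulate is off)
    counts_tsv: str | None = None
    metadata_tsv: str | None = None
    junctions_tsv: str | None = None
    events_tsv: str | None = None
    genesets_tsv: str | None = None


_UNIT_INTERVAL_KEYS = ("alpha", "p_cut", "fdr_cut", "dpsi_cut", "r_threshold")


def validate_config(raw: dict | RunConfig) -> RunConfig:
    """Range-check every parameter, fill defaults, reject unknown keys.

    All problems are collected and reported in a single :class:`ConfigError`.
    """
    if isinstance(raw, RunConfig):
        d = dataclasses.asdict(raw)
    else:
        d = dict(raw)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    errors = [f"unknown config key: {k!r}" for k in d if k not in known]
    cfg_dict = {k: v for k, v in d.items() if k in known}
    cfg = RunConfig(**cfg_dict)
    for key in _UNIT_INTERVAL_KEYS:
        v = getattr(cfg, key)
        if not 0.0 < v <= 1.0:
            errors.append(f"{key}={v} outside (0, 1]")
    if cfg.lfc_cut < 0:
        errors.append(f"lfc_cut={cfg.lfc_cut} must be non-negative")
    if cfg.n_genes < 0:
        errors.append(f"n_genes={cfg.n_genes} must be non-negative")
    if cfg.n_events < 0:
        errors.append(f"n_events={cfg.n_events} must be non-negative")
    if cfg.junction_depth < 1:
        errors.append(f"junction_depth={cfg.junction_depth} must be positive")
    if errors:
        raise ConfigError(sorted(set(errors)))
    return cfg


def _logger(outdir: Path, verbose: bool) -> logging.Logger:
    log = logging.getLogger(f"bsplice.run.{outdir}")
    log.setLevel(logging.DEBUG)
    log.handlers.clear()
    fmt = logging.Formatter(
        "%(asctime)s %(levelname)s %(message)s", datefmt="%Y-%m-%dT%H:%M:%S%z"
    )
    fh = logging.FileHandler(outdir / "run.log", mode="w")
    fh.setFormatter(fmt)
    log.addHandler(fh)
    sh = logging.StreamHandler(sys.stderr)
    sh.setFormatter(fmt)
    sh.setLevel(logging.INFO if verbose else logging.WARNING)
    log.addHandler(sh)
    return log


def run_pipeline(config: RunConfig, verbose: bool = False) -> dict:
    """Execute the toggled stages and return the summary dict.

    The summary (also written as ``summary.json``) holds the counts a reader
    would quote: DE genes per direction, significant splice events per type,
    the fraction less included in the focal group, consequence categories,
    and the top-ranked TF.
    """
    cfg = validate_config(config)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = _logger(outdir, verbose)
    log.info("bsplice %s, seed %d, outdir %s", __version__, cfg.seed, outdir)
    log.info(
        "thresholds: alpha=%g lfc=%g p=%g dpsi=%g fdr=%g r=%g",
        cfg.alpha, cfg.lfc_cut, cfg.p_cut, cfg.dpsi_cut, cfg.fdr_cut, cfg.r_threshold,
    )
    summary: dict = {"seed": cfg.seed, "version": __version__}

    sim = SimulationConfig(
        n_genes=cfg.n_genes, junction_depth=cfg.junction_depth, seed=cfg.seed
    )
    events = None
    junctions = None
    genesets = None

    if cfg.run_simulate:
        log.info("stage simulate: %d genes, %d events", cfg.n_genes, cfg.n_events)
        panel, truth = generate_counts(sim)
        tissue = generate_tissue_panel(sim, truth)
        events = synthetic_event_set(cfg.n_events, seed=cfg.seed)
        true_psi = plant_true_psi(events, sim.conditions, seed=cfg.seed)
        truth.true_psi = true_psi
        junctions = generate_junction_counts(sim, events, true_psi)
        io.write_counts(panel, outdir / "counts.tsv", outdir / "samples.tsv")
        io.write_counts(tissue, outdir / "tissue_counts.tsv", outdir / "tissue_samples.tsv")
        io.write_events(events, outdir / "events.tsv")
        io.write_junctions(junctions, outdir / "junctions.tsv")
        io.write_truth(truth, outdir / "truth.json")
        # gene sets: TF candidates (decoys + planted TF) and a planted DE set
        tf_ids = {g for g in panel.gene_ids if g.startswith("TF")}
        genesets = {
            "GO:0008134": tf_ids,
            "GO:0000981": tf_ids,
            "planted_de": set(truth.de_genes),
        }
        io.write_genesets(genesets, outdir / "genesets.tsv")
    else:
        missing = [
            name
            for name, p in [
                ("counts_tsv", cfg.counts_tsv),
                ("metadata_tsv", cfg.metadata_tsv),
            ]
            if p is None or not Path(p).exists()
        ]
        if missing:
            raise FileNotFoundError(
                f"stage simulate disabled and required inputs missing: {missing}"
            )
        panel = io.read_counts(cfg.counts_tsv, cfg.metadata_tsv)
        tissue = None
        if cfg.events_tsv and cfg.junctions_tsv:
            events = io.read_events(cfg.events_tsv)
            junctions = io.read_junctions(cfg.junctions_tsv)
        if cfg.genesets_tsv:
            genesets = io.read_genesets(cfg.genesets_tsv)

    if cfg.run_de:
        log.info("stage de: %s vs %s", cfg.group_a, cfg.group_b)
        de = de_test(panel, cfg.group_a, cfg.group_b, cfg.alpha, cfg.lfc_cut)
        de.to_csv(outdir / "de_results.tsv", sep="\t", index_label="gene_id")
        summary["n_de_up"] = int((de["status"] == "up").sum())
        summary["n_de_down"] = int((de["status"] == "down").sum())
        summary["n_de"] = summary["n_de_up"] + summary["n_de_down"]

        if cfg.run_enrich and genesets:
            hits = set(de.index[de["status"] != "ns"])
            enr = go_enrichment(hits, set(de.index), genesets, cfg.fdr_cut)
            enr.to_csv(outdir / "enrichment.tsv", sep="\t")
            summary["n_enriched_sets"] = int(enr["reportable"].sum()) if len(enr) else 0

    if cfg.run_splice and events is not None:
        log.info("stage splice: %d events", len(events))
        psi = psi_matrix(junctions, events)
        psi.to_csv(outdir / "psi.tsv", sep="\t")
        cond_of = dict(
            (s, s.rsplit("_", 1)[0]) for s in psi.columns
        ) if cfg.run_simulate else {
            s: panel.condition_of.get(s, s.rsplit("_", 1)[0]) for s in psi.columns
        }
        ds = differential_psi(psi, cond_of, cfg.group_a, cfg.group_b, cfg.p_cut, cfg.dpsi_cut)
        ds.to_csv(outdir / "diff_splice.tsv", sep="\t", index_label="event_id")
        bd = event_breakdown(ds, events)
        bd.to_csv(outdir / "event_breakdown.tsv", sep="\t")
        summary["n_sig_events"] = int(ds["significant"].sum())
        summary["events_per_type"] = bd["n_significant"].to_dict()
        frac = direction_summary(ds, cfg.group_b)
        summary["fraction_less_included_in_focal"] = None if pd.isna(frac) else frac

    if cfg.run_consequence:
        log.info("stage consequence: toy annotation exemplars")
        transcripts, domains = build_toy_annotation()
        tev = toy_events()
        by_gene = {t.gene_id: t for t in transcripts}
        calls = []
        for eid, ev in tev.items():
            tr = by_gene.get(ev.gene_id)
            if tr is None:
                continue
            # call the non-reference form of each event
            ref_has = ev.etype != "SE" or ev.segments["cassette"] in tr.exons
            variant = apply_event(tr, ev, inclusion=not ref_has)
            calls.append(classify_consequence(variant, domains))
        frame = calls_to_frame(calls)
        frame.to_csv(outdir / "consequences.tsv", sep="\t", index=False)
        summary["consequence_categories"] = (
            frame["category"].value_counts().to_dict()
        )

    if cfg.run_tfscreen and genesets:
        log.info("stage tfscreen: threshold r > %g", cfg.r_threshold)
        scfg = ScreenConfig(r_threshold=cfg.r_threshold)
        cands = candidate_tfs(genesets, set(panel.gene_ids), scfg)
        disc = discovery_screen(panel, cands, scfg)
        disc.records.to_csv(outdir / "screen_records.tsv", sep="\t", index=False)
        summary["venn"] = disc.venn_counts
        if tissue is not None and disc.all_pass:
            val = validate_in_tissues(tissue, disc.all_pass, scfg)
            ranked = rank_tfs(val)
            ranked.to_csv(outdir / "screen_ranked.tsv", sep="\t", index_label="tf")
            summary["top_tf"] = ranked.index[0]
            summary["top_tf_mean_r"] = float(ranked["mean_r"].iloc[0])
            summary["planted_tf_recovered"] = ranked.index[0] == PLANTED_TF_ID

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    log.info("done: %s", outdir / "summary.json")
    return summary
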