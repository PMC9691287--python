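"""Synthetic data with the statistical structure of the study design.

The generator emulates a 4-condition (prePB, PB, PC, MBC) x 3-replicate
bulk RNA-seq count design, a 17-sample human-tissue panel with a planted
TF -> targets co-regulation structure, and junction count tables at
configurable true PSI per condition, plus a toy transcript annotation whose
exon lengths reproduce the splice-consequence exemplars (SEC24C, SEC24D,
KLHL12, SEC31A, PICALM, NERF/ELF2).

Counts are negative binomial with a common dispersion; the planted TF and
its targets share a log-normal latent activity per sample and are sampled
Poisson around the latent-modulated mean, so the co-regulation noise
standard deviation is the only noise dial for that structure. A single
top-level seed deterministically derives per-stage substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CountMatrix, SizingError
from .consequence import TranscriptModel
from .splicing import SpliceEvent

# substream labels for per-stage RNGs derived from the top-level seed
_STAGE_MEANS, _STAGE_COUNTS, _STAGE_TISSUE, _STAGE_JUNC, _STAGE_EVENTS = range(5)


@dataclass
class TFNetworkConfig:
    """Planted TF -> targets co-regulation structure."""

    n_decoy_tfs: int = 200
    n_targets: int = 3
    coregulation_noise_sd: float = 0.1  # log2 units around the shared latent
    latent_sd: float = 1.5  # log2 sd of the shared activity across samples
    enabled: bool = True


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study design.

    Defaults emulate the study: four B-cell differentiation stages in
    triplicate, a 17-sample tissue panel, library sizes giving a mean
    per-gene depth near 1e4, planted differential expression at |log2FC| = 2
    in the final condition (MBC).
    """

    conditions: tuple[str, ...] = ("prePB", "PB", "PC", "MBC")
    replicates_per_condition: int = 3
    n_genes: int = 2000
    nb_dispersion: float = 0.001
    library_size_range: tuple[int, int] = (18_000_000, 22_000_000)
    de_fraction: float = 0.05
    de_log2fc: float = 2.0
    tf_network: TFNetworkConfig = field(default_factory=TFNetworkConfig)
    tissue_panel_size: int = 17
    junction_depth: int = 1000
    seed: int = 0

    def validate(self, for_de_test: bool = False) -> None:
        if self.n_genes < 0:
            raise SizingError("n_genes must be non-negative")
        if self.replicates_per_condition < 1:
            raise SizingError("replicates_per_condition must be positive")
        if for_de_test and self.replicates_per_condition < 2:
            raise SizingError("differential testing needs >= 2 replicates per condition")
        if not self.conditions:
            raise SizingError("at least one condition is required")
        lo, hi = self.library_size_range
        if lo <= 0 or hi < lo:
            raise SizingError("library_size_range must be a positive (low, high) pair")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise SizingError("de_fraction must lie in [0, 1]")
        if self.nb_dispersion <= 0:
            raise SizingError("nb_dispersion must be positive")
        if self.tissue_panel_size < 1:
            raise SizingError("tissue_panel_size must be positive")
        if self.junction_depth < 1:
            raise SizingError("junction_depth must be positive")
        n_special = 1 + self.tf_network.n_targets + self.tf_network.n_decoy_tfs
        if 0 < self.n_genes < n_special:
            raise SizingError(
                f"n_genes={self.n_genes} too small for the TF network "
                f"({n_special} reserved genes)"
            )

    @property
    def n_de_genes(self) -> int:
        return int(round(self.de_fraction * self.n_genes))


_DEFAULT_TARGET_IDS = ("SEC24B", "CUL3", "CSNK1D")
PLANTED_TF_ID = "TF0000"


@dataclass
class SimulationTruth:
    """Ground truth recorded for recovery tests."""

    de_genes: dict[str, float] = field(default_factory=dict)  # gene -> signed log2FC in MBC
    true_psi: pd.DataFrame | None = None  # event x condition
    planted_tf: str | None = None
    planted_targets: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "de_genes": self.de_genes,
            "planted_tf": self.planted_tf,
            "planted_targets": list(self.planted_targets),
            "true_psi": None
            if self.true_psi is None
            else self.true_psi.to_dict(orient="index"),
        }


def _gene_ids(config: SimulationConfig) -> tuple[list[str], list[str], str, list[str]]:
    """(all ids, target ids, planted tf id, decoy tf ids)."""
    net = config.tf_network
    if net.n_targets == len(_DEFAULT_TARGET_IDS):
        targets = list(_DEFAULT_TARGET_IDS)
    else:
        targets = [f"TGT{i + 1:02d}" for i in range(net.n_targets)]
    decoys = [f"TF{i + 1:04d}" for i in range(net.n_decoy_tfs)]
    n_rest = config.n_genes - 1 - len(targets) - len(decoys)
    rest = [f"G{i + 1:05d}" for i in range(n_rest)]
    return targets + [PLANTED_TF_ID] + decoys + rest, targets, PLANTED_TF_ID, decoys


def _base_fractions(config: SimulationConfig) -> np.ndarray:
    """Relative abundance per gene (sums to 1), seed-stable across panels."""
    rng = np.random.default_rng([config.seed, _STAGE_MEANS])
    w = np.exp2(rng.normal(0.0, 0.5, size=config.n_genes))
    return w / w.sum()


def _sample_counts(
    config: SimulationConfig,
    rng: np.random.Generator,
    sample_names: list[str],
    latent: np.ndarray,
    mbc_mask: np.ndarray,
    lfc: np.ndarray,
    coexpr_rows: np.ndarray,
) -> pd.DataFrame:
    """Draw one panel of counts. ``latent`` is per-sample shared activity."""
    n_s = len(sample_names)
    frac = _base_fractions(config)
    lo, hi = config.library_size_range
    libs = rng.integers(lo, hi + 1, size=n_s)
    mu = frac[:, None] * libs[None, :]
    # planted differential expression in the focal (last) condition
    mu *= np.exp2(lfc[:, None] * mbc_mask[None, :])
    net = config.tf_network
    if net.enabled and coexpr_rows.size:
        eps = rng.normal(0.0, net.coregulation_noise_sd, size=(coexpr_rows.size, n_s))
        mu[coexpr_rows] *= np.exp2(latent[None, :] + eps)
    counts = np.empty_like(mu, dtype=np.int64)
    disp = config.nb_dispersion
    lam = rng.gamma(1.0 / disp, mu * disp)
    counts[:] = rng.poisson(lam)
    if net.enabled and coexpr_rows.size:
        # co-regulated genes: Poisson only, so the noise dial is the sole
        # stochastic term of the co-regulation structure beyond counting
        counts[coexpr_rows] = rng.poisson(mu[coexpr_rows])
    return pd.DataFrame(counts, index=_gene_ids(config)[0], columns=sample_names)


def generate_counts(config: SimulationConfig) -> tuple[CountMatrix, SimulationTruth]:
    """The B-cell differentiation panel: conditions x replicates NB counts.

    Plants ``de_fraction * n_genes`` genes at +/- ``de_log2fc`` in the final
    condition and a TF -> targets co-regulation structure shared with the
    tissue panel. Identical config and seed give bitwise-identical output.
    """
    config.validate()
    if config.n_genes == 0:
        return (
            CountMatrix(pd.DataFrame(dtype=np.int64), {}),
            SimulationTruth(),
        )
    ids, targets, tf, _ = _gene_ids(config)
    rng = np.random.default_rng([config.seed, _STAGE_COUNTS])
    samples, cond_of = [], {}
    for cond in config.conditions:
        for r in range(config.replicates_per_condition):
            s = f"{cond}_{r + 1}"
            samples.append(s)
            cond_of[s] = cond
    mbc = config.conditions[-1]
    mbc_mask = np.array([cond_of[s] == mbc for s in samples], dtype=float)

    # choose planted DE genes from the non-reserved pool, alternate signs
    reserved = set(targets) | {tf}
    pool = [g for g in ids if g not in reserved]
    n_de = min(config.n_de_genes, len(pool))
    de_idx = rng.choice(len(pool), size=n_de, replace=False)
    lfc_of = {pool[i]: (config.de_log2fc if k % 2 == 0 else -config.de_log2fc)
              for k, i in enumerate(sorted(de_idx))}
    lfc = np.array([lfc_of.get(g, 0.0) for g in ids])

    latent = rng.normal(0.0, config.tf_network.latent_sd, size=len(samples))
    coexpr_rows = np.array([ids.index(g) for g in (*targets, tf)], dtype=int)
    counts = _sample_counts(config, rng, samples, latent, mbc_mask, lfc, coexpr_rows)
    truth = SimulationTruth(
        de_genes=lfc_of, planted_tf=tf, planted_targets=tuple(targets)
    )
    return CountMatrix(counts, cond_of), truth


def generate_tissue_panel(config: SimulationConfig, truth: SimulationTruth) -> CountMatrix:
    """A panel with one sample per tissue sharing the planted TF structure."""
    config.validate()
    if truth.planted_tf is None:
        raise ValueError("truth does not record a planted TF")
    ids, targets, tf, _ = _gene_ids(config)
    rng = np.random.default_rng([config.seed, _STAGE_TISSUE])
    samples = [f"tissue{i + 1:02d}" for i in range(config.tissue_panel_size)]
    cond_of = {s: s for s in samples}
    latent = rng.normal(0.0, config.tf_network.latent_sd, size=len(samples))
    coexpr_rows = np.array([ids.index(g) for g in (*targets, tf)], dtype=int)
    counts = _sample_counts(
        config,
        rng,
        samples,
        latent,
        np.zeros(len(samples)),
        np.zeros(len(ids)),
        coexpr_rows,
    )
    return CountMatrix(counts, cond_of)


def inclusion_read_probability(psi: float, len_inc: int, len_skip: int) -> float:
    """Probability that a junction read supports inclusion, given true PSI.

    Inverse of the length-normalized PSI estimator: with this read-level
    probability, the estimator applied to *expected* counts returns PSI
    exactly.
    """
    if not 0.0 <= psi <= 1.0:
        raise ValueError(f"true PSI must lie in [0, 1], got {psi}")
    num = psi * len_inc
    return num / (num + (1.0 - psi) * len_skip)


def generate_junction_counts(
    config: SimulationConfig,
    events: list[SpliceEvent],
    true_psi: pd.DataFrame,
) -> pd.DataFrame:
    """Junction read counts per (event, sample) at the configured true PSI.

    ``true_psi`` is events x conditions with values in [0, 1]. Per event and
    sample, total reads are Poisson around ``junction_depth`` and inclusion
    reads binomial with the estimator-inverting success probability.
    Returns a long table (event_id, sample, inc_reads, skip_reads).
    """
    config.validate()
    vals = true_psi.to_numpy(dtype=float)
    if np.any((vals < 0) | (vals > 1)):
        raise ValueError("true PSI values must lie in [0, 1]")
    rng = np.random.default_rng([config.seed, _STAGE_JUNC])
    by_id = {e.event_id: e for e in events}
    rows = []
    for event_id in true_psi.index:
        ev = by_id[event_id]
        for cond in true_psi.columns:
            q = inclusion_read_probability(
                float(true_psi.loc[event_id, cond]), ev.len_inc, ev.len_skip
            )
            for r in range(config.replicates_per_condition):
                total = rng.poisson(config.junction_depth)
                inc = rng.binomial(total, q) if total else 0
                rows.append(
                    {
                        "event_id": event_id,
                        "sample": f"{cond}_{r + 1}",
                        "inc_reads": int(inc),
                        "skip_reads": int(total - inc),
                    }
                )
    return pd.DataFrame(rows)


def synthetic_event_set(n_events: int, seed: int = 0) -> list[SpliceEvent]:
    """Abstract splice events across the four types, SE-dominated.

    Event-type proportions follow the study's significant-event breakdown
    (~80% SE, ~2% RI, ~8% A5SS, ~10% A3SS). Coordinates are placed on a
    virtual chromosome and are internally consistent per type.
    """
    rng = np.random.default_rng([seed, _STAGE_EVENTS])
    props = {"SE": 0.80, "RI": 0.02, "A5SS": 0.08, "A3SS": 0.10}
    types = rng.choice(list(props), size=n_events, p=list(props.values()))
    events = []
    for i, t in enumerate(types):
        base = 10_000 * (i + 1)
        if t == "SE":
            segments = {
                "upstream": (base, base + 100),
                "cassette": (base + 200, base + 300),
                "downstream": (base + 400, base + 500),
            }
        elif t == "RI":
            segments = {
                "upstream": (base, base + 100),
                "intron": (base + 100, base + 250),
                "downstream": (base + 250, base + 350),
            }
        else:
            segments = {"long": (base, base + 150), "short": (base + 60, base + 150)}
            if t == "A5SS":
                segments = {"long": (base, base + 150), "short": (base, base + 90)}
        events.append(
            SpliceEvent(
                event_id=f"EV{i + 1:05d}",
                gene_id=f"G{i + 1:05d}",
                etype=str(t),
                chrom="chrSim",
                segments=segments,
            )
        )
    return events


def plant_true_psi(
    events: list[SpliceEvent],
    conditions: tuple[str, ...],
    seed: int = 0,
    frac_differential: float = 0.2,
    dpsi: float = 0.5,
) -> pd.DataFrame:
    """True PSI per event x condition with a planted shift in the last condition.

    Baseline PSI is uniform in [0.15, 0.85]; a ``frac_differential`` subset
    shifts by +/- ``dpsi`` in the final condition (clipped to [0.02, 0.98]),
    mirroring the MBC-specific splicing changes of the study.
    """
    rng = np.random.default_rng([seed, _STAGE_EVENTS, 1])
    base = rng.uniform(0.15, 0.85, size=len(events))
    psi = np.tile(base[:, None], (1, len(conditions)))
    n_diff = int(round(frac_differential * len(events)))
    diff_idx = rng.choice(len(events), size=n_diff, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_diff)
    psi[diff_idx, -1] = np.clip(base[diff_idx] + signs * dpsi, 0.02, 0.98)
    df = pd.DataFrame(psi, index=[e.event_id for e in events], columns=list(conditions))
    df.attrs["differential_events"] = [events[i].event_id for i in sorted(diff_idx)]
    return df


# --------------------------------------------------------------------------
# toy annotation: transcripts whose exon lengths reproduce the splice-
# consequence exemplars.  Background sequence uses only A/C/G (no T), so the
# only stop codons anywhere are the ones placed explicitly; each placed
# start/stop is positioned so that it is read only in the intended frame.
# --------------------------------------------------------------------------

_FIXTURE_SEED = 20240717


def _bg(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.choice(np.array(list("ACG")), size=n)


def _build_locus(
    rng: np.random.Generator,
    exon_lengths: list[int],
    intron_length: int,
    codons: dict[int, str],
    extra_genomic: dict[int, str] | None = None,
) -> tuple[str, list[tuple[int, int]]]:
    """Locus sequence + exon intervals from exon lengths and placed codons.

    ``codons`` maps transcript coordinates to short motifs written into the
    spliced sequence; ``extra_genomic`` maps locus coordinates directly
    (used for poison-exon content that is intronic in the reference).
    """
    exons, pos = [], 0
    for i, ln in enumerate(exon_lengths):
        start = pos + (intron_length if i else 0)
        exons.append((start, start + ln))
        pos = start + ln
    locus = _bg(rng, pos)
    tx2g = np.concatenate([np.arange(s, e) for s, e in exons])
    for tpos, motif in codons.items():
        for k, ch in enumerate(motif):
            locus[tx2g[tpos + k]] = ch
    for gpos, motif in (extra_genomic or {}).items():
        for k, ch in enumerate(motif):
            locus[gpos + k] = ch
    return "".join(locus), exons


def build_toy_annotation() -> tuple[list[TranscriptModel], pd.DataFrame]:
    """Fixture transcripts for the splice-consequence exemplars.

    Returns transcripts (SEC24C-, SEC24D-, KLHL12-, SEC31A-, PICALM- and
    NERF/ELF2-like, the last as two alternative-start transcripts sharing a
    locus) plus a domain table in which the KLHL12-like transcript carries
    six kelch-repeat intervals, three of them downstream of the cassette
    pair. Deterministic: repeated calls return identical fixtures.
    """
    rng = np.random.default_rng(_FIXTURE_SEED)
    transcripts: list[TranscriptModel] = []

    # SEC24C-like: skipping the 116-nt exon 11 shifts the frame; the PTC sits
    # 129 nt upstream of the last junction -> NMD.
    locus, exons = _build_locus(
        rng, [250, 200, 116, 180, 300], 100,
        codons={60: "ATGC", 617: "TGA", 981: "TAA"},
    )
    transcripts.append(
        TranscriptModel("SEC24C_t1", "SEC24C", exons, 60, 984, locus, chrom="chr_SEC24C")
    )

    # SEC24D-like: a 296-nt poison exon (intronic in the reference) whose
    # inclusion shifts the frame and carries an in-frame PTC.
    locus, exons = _build_locus(
        rng, [200, 250, 220, 350], 400,
        codons={50: "ATGC", 950: "TAA"},
        extra_genomic={950: "TAA"},  # PTC at offset 50 of the poison exon
    )
    transcripts.append(
        TranscriptModel(
            "SEC24D_t1", "SEC24D", exons, 50, 953, locus, chrom="chr_SEC24D"
        )
    )

    # KLHL12-like: cassette pair of 99 nt (frame-preserving alone) and 187 nt
    # (frameshift); joint skipping (-286 nt) puts the new stop in the last
    # exon -> NMD escape with a short C-terminus lacking 3 of 6 repeats.
    locus, exons = _build_locus(
        rng, [150, 300, 99, 187, 120, 400], 100,
        codons={30: "ATGC", 886: "TGA", 999: "TAA"},
    )
    transcripts.append(
        TranscriptModel("KLHL12_t1", "KLHL12", exons, 30, 1002, locus, chrom="chr_KLHL12")
    )

    # SEC31A-like: a 50-nt cassette (intronic in the reference) whose
    # inclusion shifts the frame with no reachable stop from the annotated
    # start; a downstream AUG restores an open frame (alt-start rescue).
    locus, exons = _build_locus(
        rng, [180, 240, 300, 260], 150,
        codons={90: "ATGC", 450: "ATGC", 930: "TAA"},
    )
    transcripts.append(
        TranscriptModel("SEC31A_t1", "SEC31A", exons, 90, 933, locus, chrom="chr_SEC31A")
    )

    # PICALM-like: exon 13 (141 nt) and exon 17 (114 nt) cassettes, both
    # frame-preserving, yielding distinct C-terminal segments.
    locus, exons = _build_locus(
        rng, [210, 141, 90, 114, 330], 100,
        codons={45: "ATGC", 840: "TAA"},
    )
    transcripts.append(
        TranscriptModel("PICALM_t1", "PICALM", exons, 45, 843, locus, chrom="chr_PICALM")
    )

    # NERF/ELF2-like: two alternative starts (exon 1 vs exon 5) and one
    # alternative 3' splice site in exon 7 (45 nt, frame-preserving).
    locus, exons = _build_locus(
        rng, [150, 120, 100, 130, 200], 100,
        codons={30: "ATGC", 660: "TAA"},
    )
    # second start codon for the short-N-terminus isoform, placed so that
    # both transcripts read the shared stop in the same genomic frame
    e5_start = exons[1][0]
    locus_list = list(locus)
    for k, ch in enumerate("ATGC"):
        locus_list[e5_start + 21 + k] = ch
    locus = "".join(locus_list)
    transcripts.append(
        TranscriptModel("NERF2_t1", "ELF2", exons, 30, 663, locus, chrom="chr_ELF2")
    )
    transcripts.append(
        TranscriptModel("NERF1_t1", "ELF2", exons[1:], 21, 513, locus, chrom="chr_ELF2")
    )

    domains = pd.DataFrame(
        [
            {"transcript_id": "KLHL12_t1", "domain_id": f"kelch_{i + 1}", "start": s, "end": e}
            for i, (s, e) in enumerate(
                [(171, 231), (231, 291), (291, 351), (900, 930), (930, 960), (960, 990)]
            )
        ]
    )
    return transcripts, domains


def toy_events() -> dict[str, SpliceEvent]:
    """Splice events matching :func:`build_toy_annotation` fixtures."""
    tr = {t.transcript_id: t for t in build_toy_annotation()[0]}

    def ev(eid, gene, etype, chrom, segments):
        return SpliceEvent(eid, gene, etype, chrom=chrom, segments=segments)

    sec24c = tr["SEC24C_t1"].exons
    sec24d = tr["SEC24D_t1"].exons
    klhl12 = tr["KLHL12_t1"].exons
    sec31a = tr["SEC31A_t1"].exons
    picalm = tr["PICALM_t1"].exons
    nerf = tr["NERF2_t1"].exons
    events = {
        "SE_SEC24C_e11": ev(
            "SE_SEC24C_e11", "SEC24C", "SE", "chr_SEC24C",
            {"upstream": sec24c[1], "cassette": sec24c[2], "downstream": sec24c[3]},
        ),
        "SE_SEC24D_poison": ev(
            "SE_SEC24D_poison", "SEC24D", "SE", "chr_SEC24D",
            {"upstream": sec24d[1], "cassette": (900, 1196), "downstream": sec24d[2]},
        ),
        "SE_KLHL12_e10": ev(
            "SE_KLHL12_e10", "KLHL12", "SE", "chr_KLHL12",
            {"upstream": klhl12[1], "cassette": klhl12[2], "downstream": klhl12[3]},
        ),
        "SE_KLHL12_e11": ev(
            "SE_KLHL12_e11", "KLHL12", "SE", "chr_KLHL12",
            {"upstream": klhl12[2], "cassette": klhl12[3], "downstream": klhl12[4]},
        ),
        "SE_SEC31A_alt": ev(
            "SE_SEC31A_alt", "SEC31A", "SE", "chr_SEC31A",
            {"upstream": sec31a[1], "cassette": (620, 670), "downstream": sec31a[2]},
        ),
        "SE_PICALM_e13": ev(
            "SE_PICALM_e13", "PICALM", "SE", "chr_PICALM",
            {"upstream": picalm[0], "cassette": picalm[1], "downstream": picalm[2]},
        ),
        "SE_PICALM_e17": ev(
            "SE_PICALM_e17", "PICALM", "SE", "chr_PICALM",
            {"upstream": picalm[2], "cassette": picalm[3], "downstream": picalm[4]},
        ),
        "A3SS_NERF_e7": ev(
            "A3SS_NERF_e7", "ELF2", "A3SS", "chr_ELF2",
            {"long": nerf[3], "short": (nerf[3][0] + 45, nerf[3][1])},
        ),
    }
    return events
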