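"""PSI quantification and differential splicing.

PSI (percent spliced in) is estimated from junction-spanning read counts
with effective-length normalization:

    PSI = (inc / len_inc) / (inc / len_inc + skip / len_skip)

where ``len_inc``/``len_skip`` are the number of junctions supporting the
inclusion and skipping forms (2 vs 1 for exon skipping, 1 vs 1 for intron
retention and alternative splice sites). Differential splicing between two
sample groups uses a Welch t test on replicate PSI values with the study's
gates: p < 0.001 and |dPSI| > 0.4.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import LookupError_

EVENT_TYPES = ("SE", "RI", "A5SS", "A3SS")

#: effective junction counts (inclusion form, skipping form) per event type
EFFECTIVE_LENGTHS: dict[str, tuple[int, int]] = {
    "SE": (2, 1),
    "RI": (1, 1),
    "A5SS": (1, 1),
    "A3SS": (1, 1),
}


@dataclass
class SpliceEvent:
    """One alternative-splicing event with its genomic segments.

    ``segments`` holds 0-based half-open intervals keyed by role:

    * SE   -- ``upstream``, ``cassette``, ``downstream`` exons
    * RI   -- ``upstream``, ``intron``, ``downstream``
    * A5SS -- ``long`` and ``short`` versions of the alternative-donor exon
    * A3SS -- ``long`` and ``short`` versions of the alternative-acceptor exon

    The inclusion form is the cassette-in / intron-retained / long-segment
    isoform, following the usual junction-count convention.
    """

    event_id: str
    gene_id: str
    etype: str
    chrom: str = "chr1"
    strand: str = "+"
    segments: dict[str, tuple[int, int]] = field(default_factory=dict)
    len_inc: int = 0
    len_skip: int = 0

    def __post_init__(self) -> None:
        if self.etype not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.etype!r}")
        li, ls = EFFECTIVE_LENGTHS[self.etype]
        if self.len_inc == 0:
            self.len_inc = li
        if self.len_skip == 0:
            self.len_skip = ls
        if (self.len_inc, self.len_skip) != (li, ls):
            raise ValueError(
                f"{self.etype} events have effective lengths {li}/{ls}, "
                f"got {self.len_inc}/{self.len_skip}"
            )
        self._check_segments()

    def _check_segments(self) -> None:
        if not self.segments:
            return
        for name, (s, e) in self.segments.items():
            if e <= s:
                raise ValueError(f"empty segment {name!r} in {self.event_id}")
        if self.etype == "SE" and all(
            k in self.segments for k in ("upstream", "cassette", "downstream")
        ):
            u, c, d = (self.segments[k] for k in ("upstream", "cassette", "downstream"))
            if not (u[1] <= c[0] and c[1] <= d[0]):
                raise ValueError(
                    f"cassette exon of {self.event_id} must lie strictly "
                    "between its flanking exons"
                )


def compute_psi(
    inc_reads: int, skip_reads: int, len_inc: int = 2, len_skip: int = 1
) -> float:
    """Length-normalized PSI from one inclusion/skipping read-count pair.

    Returns NaN when the event has no junction coverage at all.
    """
    if inc_reads < 0 or skip_reads < 0:
        raise ValueError("junction read counts must be non-negative")
    if len_inc <= 0 or len_skip <= 0:
        raise ValueError("effective lengths must be positive")
    if inc_reads == 0 and skip_reads == 0:
        return float("nan")
    i = inc_reads / len_inc
    s = skip_reads / len_skip
    return i / (i + s)


def psi_matrix(junctions: pd.DataFrame, events: list[SpliceEvent]) -> pd.DataFrame:
    """PSI per (event, sample) from a long-format junction count table.

    ``junctions`` needs columns event_id, sample, inc_reads, skip_reads.
    Returns an events x samples DataFrame with NaN for zero-coverage cells.
    """
    lens = {e.event_id: (e.len_inc, e.len_skip) for e in events}
    unknown = set(junctions["event_id"]) - set(lens)
    if unknown:
        raise LookupError_(f"junction table references undefined events: {sorted(unknown)[:5]}")
    rows = []
    for _, r in junctions.iterrows():
        li, ls = lens[r["event_id"]]
        rows.append(compute_psi(int(r["inc_reads"]), int(r["skip_reads"]), li, ls))
    long = junctions[["event_id", "sample"]].copy()
    long["psi"] = rows
    wide = long.pivot(index="event_id", columns="sample", values="psi")
    order = [e.event_id for e in events if e.event_id in wide.index]
    return wide.loc[order]


def _welch_rows(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Welch t test, NaN-aware. Returns (diff of means, p)."""
    na = np.sum(~np.isnan(a), axis=1)
    nb = np.sum(~np.isnan(b), axis=1)
    with np.errstate(invalid="ignore"):
        ma = np.nanmean(a, axis=1)
        mb = np.nanmean(b, axis=1)
        va = np.nanvar(a, axis=1, ddof=1)
        vb = np.nanvar(b, axis=1, ddof=1)
    diff = mb - ma
    p = np.ones_like(diff)
    sa = va / na
    sb = vb / nb
    denom = sa + sb
    nonzero = denom > 0
    t = np.zeros_like(diff)
    t[nonzero] = diff[nonzero] / np.sqrt(denom[nonzero])
    # Welch-Satterthwaite degrees of freedom
    df = np.full_like(diff, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        df[nonzero] = denom[nonzero] ** 2 / (
            sa[nonzero] ** 2 / (na[nonzero] - 1) + sb[nonzero] ** 2 / (nb[nonzero] - 1)
        )
    ok = nonzero & np.isfinite(df)
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df[ok])
    # identical-variance-zero rows keep p = 1, diff as computed
    return diff, p


def differential_psi(
    psi: pd.DataFrame,
    condition_of: dict[str, str],
    group_a: str,
    group_b: str,
    p_cut: float = 0.001,
    dpsi_cut: float = 0.4,
) -> pd.DataFrame:
    """Differential PSI between two conditions.

    Welch t on replicate PSI values; ``dpsi`` = mean PSI(group_b) - mean
    PSI(group_a); an event is significant iff p < ``p_cut`` and |dpsi| >
    ``dpsi_cut``. Events with fewer than two covered replicates in either
    group are reported with ``tested = False`` and NaN statistics.
    """
    for g in (group_a, group_b):
        if g not in set(condition_of.values()):
            raise LookupError_(f"unknown condition label: {g!r}")
    cols_a = [s for s in psi.columns if condition_of.get(s) == group_a]
    cols_b = [s for s in psi.columns if condition_of.get(s) == group_b]
    a = psi[cols_a].to_numpy(dtype=float)
    b = psi[cols_b].to_numpy(dtype=float)
    na = np.sum(~np.isnan(a), axis=1)
    nb = np.sum(~np.isnan(b), axis=1)
    tested = (na >= 2) & (nb >= 2)
    dpsi = np.full(len(psi), np.nan)
    pval = np.full(len(psi), np.nan)
    if tested.any():
        d, p = _welch_rows(a[tested], b[tested])
        dpsi[tested] = d
        pval[tested] = p
    significant = tested & (pval < p_cut) & (np.abs(dpsi) > dpsi_cut)
    out = pd.DataFrame(
        {
            "dpsi": dpsi,
            "pvalue": pval,
            "tested": tested,
            "significant": significant,
        },
        index=psi.index,
    )
    out.attrs["group_a"] = group_a
    out.attrs["group_b"] = group_b
    return out


def event_breakdown(
    results: pd.DataFrame, events: list[SpliceEvent]
) -> pd.DataFrame:
    """Counts and percentages of significant events per event type.

    Percentages are over the total number of significant events; with no
    significant events all percentages are zero.
    """
    etype_of = {e.event_id: e.etype for e in events}
    sig = results.index[results["significant"]]
    counts = {t: 0 for t in EVENT_TYPES}
    for ev in sig:
        counts[etype_of[ev]] += 1
    total = sum(counts.values())
    rows = []
    for t in EVENT_TYPES:
        pct = 100.0 * counts[t] / total if total else 0.0
        rows.append({"etype": t, "n_significant": counts[t], "percent": pct})
    return pd.DataFrame(rows).set_index("etype")


def direction_summary(results: pd.DataFrame, focal_group: str) -> float:
    """Fraction of significant events with *lower* inclusion in the focal group.

    Returns NaN when no event is significant. The focal group must be one of
    the two groups the differential test compared.
    """
    ga = results.attrs.get("group_a")
    gb = results.attrs.get("group_b")
    if focal_group not in (ga, gb):
        raise LookupError_(
            f"focal group {focal_group!r} was not part of the comparison ({ga!r} vs {gb!r})"
        )
    sig = results[results["significant"]]
    if len(sig) == 0:
        return float("nan")
    if focal_group == gb:
        lower = (sig["dpsi"] < 0).sum()
    else:
        lower = (sig["dpsi"] > 0).sum()
    return float(lower) / len(sig)


def isoform_fractions_from_junctions(
    start_inc: int, start_alt: int, ss3_proximal: int, ss3_distal: int
) -> dict[str, float]:
    """Four-isoform fractions from two independent junction choices.

    Models a transcript with an alternative start (short-N-terminus "1"
    isoforms vs long "2" isoforms) and an alternative 3' splice site ("a"
    distal vs "b" proximal), as in NERF/ELF2. Under independence of the two
    choices the fraction of each isoform is the product of the two marginal
    junction-usage frequencies; the four fractions sum to one.

    Returns a dict keyed ``1a, 1b, 2a, 2b`` where "1" uses ``start_inc``
    reads and "a" uses ``ss3_proximal`` reads.
    """
    for v in (start_inc, start_alt, ss3_proximal, ss3_distal):
        if v < 0:
            raise ValueError("junction read counts must be non-negative")
    n_start = start_inc + start_alt
    n_ss3 = ss3_proximal + ss3_distal
    if n_start == 0 or n_ss3 == 0:
        raise ValueError("each junction pair needs at least one read")
    p1 = start_inc / n_start
    pa = ss3_proximal / n_ss3
    return {
        "1a": p1 * pa,
        "1b": p1 * (1 - pa),
        "2a": (1 - p1) * pa,
        "2b": (1 - p1) * (1 - pa),
    }
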