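"""Two-stage TF-target co-expression screen.

Stage 1 (discovery): on the B-cell panel, Pearson-correlate every candidate
TF with each target gene on log2-normalized expression; a TF passes for a
target when r exceeds the threshold (default 0.9). TFs passing for at least
one target and for all targets form the Venn sets of the screen. Stage 2
(validation): recompute the correlations across a multi-tissue panel,
average r and p over the targets per TF, and rank by mean r (ties broken by
mean p, then id). Rank 1 is the reported top hit.

p-values here are descriptive, mirroring the screen's usage; a BH-adjusted
column is emitted alongside for convenience.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CountMatrix, LookupError_
from .expression import bh_adjust, normalized_log2


@dataclass
class ScreenConfig:
    r_threshold: float = 0.9
    candidate_set_ids: tuple[str, ...] = ("GO:0008134", "GO:0000981")
    targets: tuple[str, ...] = ("SEC24B", "CUL3", "CSNK1D")

    def __post_init__(self) -> None:
        if not 0.0 < self.r_threshold < 1.0:
            raise ValueError("r_threshold must lie in (0, 1)")
        if not self.targets:
            raise ValueError("at least one target gene is required")


def pearson_with_p(x, y) -> tuple[float, float]:
    """Sample Pearson r with a two-sided p from the t-transform.

    t = r * sqrt((n - 2) / (1 - r^2)) on n - 2 degrees of freedom; |r| = 1
    gives p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length vectors")
    n = x.size
    if n < 3:
        raise ValueError("correlation needs at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(np.dot(xc, xc))
    sy = np.sqrt(np.dot(yc, yc))
    if sx == 0.0 or sy == 0.0:
        raise ValueError("correlation undefined for a zero-variance vector")
    r = float(np.clip(np.dot(xc, yc) / (sx * sy), -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(stats.t.sf(abs(t), n - 2))
    return r, min(p, 1.0)


def candidate_tfs(
    genesets: dict[str, set[str]],
    expressed: set[str],
    config: ScreenConfig,
) -> list[str]:
    """Union of the configured TF sets, restricted to expressed genes.

    Target genes are excluded so a target never correlates with itself.
    """
    missing = [s for s in config.candidate_set_ids if s not in genesets]
    if missing:
        raise LookupError_(f"unknown gene set id(s): {missing}")
    union: set[str] = set()
    for sid in config.candidate_set_ids:
        union |= genesets[sid]
    return sorted((union & expressed) - set(config.targets))


def _correlation_records(
    log2: pd.DataFrame, candidates: list[str], targets: tuple[str, ...]
) -> pd.DataFrame:
    """Vectorized candidate x target Pearson r and t-transform p."""
    missing = [t for t in targets if t not in log2.index]
    if missing:
        raise LookupError_(f"target gene(s) absent from panel: {missing}")
    missing_c = [c for c in candidates if c not in log2.index]
    if missing_c:
        raise LookupError_(f"candidate gene(s) absent from panel: {missing_c[:5]}")
    n = log2.shape[1]
    if n < 3:
        raise ValueError("the panel needs at least 3 samples")
    x = log2.loc[candidates].to_numpy()
    y = log2.loc[list(targets)].to_numpy()
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    xn = np.sqrt((xc**2).sum(axis=1))
    yn = np.sqrt((yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc.T) / np.outer(xn, yn)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = np.where(np.abs(r) >= 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), n - 2))
    rows = []
    for i, tf in enumerate(candidates):
        for j, tg in enumerate(targets):
            rows.append(
                {"tf": tf, "target": tg, "r": r[i, j], "p": p[i, j], "n": n}
            )
    rec = pd.DataFrame(rows, columns=["tf", "target", "r", "p", "n"])
    if len(rec):
        rec["p_bh"] = bh_adjust(rec["p"].to_numpy())
    return rec


@dataclass
class ScreenResult:
    """Discovery-stage output: records, pass sets and Venn counts."""

    records: pd.DataFrame
    pass_sets: dict[str, set[str]]  # target -> TFs with r > threshold
    any_pass: set[str] = field(default_factory=set)
    all_pass: set[str] = field(default_factory=set)

    @property
    def venn_counts(self) -> dict[str, int]:
        out = {f"pass_{t}": len(s) for t, s in self.pass_sets.items()}
        out["any_pass"] = len(self.any_pass)
        out["all_pass"] = len(self.all_pass)
        return out


def discovery_screen(
    panel: CountMatrix, candidates: list[str], config: ScreenConfig
) -> ScreenResult:
    """Stage 1: per-candidate correlations on the discovery panel.

    Correlations are computed across all panel samples on log2-normalized
    expression; a candidate passes for a target iff r > ``r_threshold``.
    """
    if not candidates:
        return ScreenResult(
            records=pd.DataFrame(columns=["tf", "target", "r", "p", "n", "p_bh"]),
            pass_sets={t: set() for t in config.targets},
        )
    log2 = normalized_log2(panel)
    rec = _correlation_records(log2, candidates, config.targets)
    pass_sets = {
        t: set(rec.loc[(rec["target"] == t) & (rec["r"] > config.r_threshold), "tf"])
        for t in config.targets
    }
    any_pass = set().union(*pass_sets.values())
    all_pass = set.intersection(*pass_sets.values()) if pass_sets else set()
    return ScreenResult(rec, pass_sets, any_pass, all_pass)


def validate_in_tissues(
    tissue_panel: CountMatrix, tfs: set[str], config: ScreenConfig
) -> pd.DataFrame:
    """Stage 2: mean correlation statistics per TF across the tissue panel.

    One correlation per TF-target pair across all tissues, then arithmetic
    means of r and of p over the targets. Returns a DataFrame indexed by TF
    with columns mean_r and mean_p.
    """
    if not tfs:
        return pd.DataFrame(columns=["mean_r", "mean_p"])
    log2 = normalized_log2(tissue_panel)
    rec = _correlation_records(log2, sorted(tfs), config.targets)
    g = rec.groupby("tf")
    return pd.DataFrame({"mean_r": g["r"].mean(), "mean_p": g["p"].mean()})


def rank_tfs(validated: pd.DataFrame) -> pd.DataFrame:
    """Rank validated TFs: mean_r descending, ties by mean_p then id.

    Rank 1 is the screen's reported top hit.
    """
    if len(validated) == 0:
        out = validated.copy()
        out["rank"] = pd.Series(dtype=int)
        return out
    out = validated.copy()
    out["_id"] = out.index
    out = out.sort_values(
        by=["mean_r", "mean_p", "_id"], ascending=[False, True, True]
    ).drop(columns="_id")
    out["rank"] = np.arange(1, len(out) + 1)
    return out
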