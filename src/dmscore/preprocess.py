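"""Count preprocessing: filtering, imputation, normalization and mappings.

The pipeline mirrors the standard growth-screen contract: drop variants with
too many missing cells, impute the rest, transform raw counts to aligned
log-counts ``m`` centered on the synonymous (null) variants, then build the
position map ``p(v)`` and the mean-group map ``g(v)`` used for
heteroscedastic error pooling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Assay, DELETION, INSERTION, SYNONYMOUS

logger = logging.getLogger(__name__)


class EmptyAssayError(ValueError):
    pass


class NormalizationError(ValueError):
    pass


@dataclass
class PreprocessConfig:
    """Tunable preprocessing knobs.

    max_missing_frac : variants missing more than this fraction of count
        cells are removed (default 0.5).
    impute_strategy : ``position_mean`` fills a missing cell with the mean of
        observed counts at the same (position, round, replicate), falling back
        to ``pseudocount``; ``pseudocount`` fills with the pseudocount alone.
    min_pos_variants : positions with fewer variants are merged into the next
        position until every group reaches this size (default 5).
    n_mean_groups : equal-frequency bins of the naive per-variant score used
        to pool error scales (default 5).
    """

    max_missing_frac: float = 0.5
    impute_strategy: str = "position_mean"
    pseudocount: float = 0.5
    min_pos_variants: int = 5
    n_mean_groups: int = 5

    def __post_init__(self):
        if not 0.0 <= self.max_missing_frac <= 1.0:
            raise ValueError("max_missing_frac must be in [0, 1]")
        if self.impute_strategy not in {"position_mean", "pseudocount"}:
            raise ValueError(f"unknown impute strategy {self.impute_strategy!r}")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if self.min_pos_variants < 1 or self.n_mean_groups < 1:
            raise ValueError("min_pos_variants and n_mean_groups must be >= 1")


def filter_variants(assay: Assay, cfg: PreprocessConfig | None = None) -> Assay:
    """Remove variants whose missing-cell fraction exceeds the threshold."""
    cfg = cfg or PreprocessConfig()
    n_cells = (assay.T + 1) * assay.R
    missing_frac = np.isnan(assay.counts).reshape(assay.n_variants, n_cells).mean(axis=1)
    keep = np.flatnonzero(missing_frac <= cfg.max_missing_frac)
    n_removed = assay.n_variants - keep.size
    if keep.size == 0:
        raise EmptyAssayError("all variants removed by missing-data filter")
    if n_removed:
        logger.info("filtered %d variants exceeding missing fraction %.2f",
                    n_removed, cfg.max_missing_frac)
    out = assay.subset(keep)
    out.meta["n_filtered_missing"] = n_removed
    return out


def impute_counts(assay: Assay, cfg: PreprocessConfig | None = None) -> Assay:
    """Fill missing count cells; observed cells are never altered."""
    cfg = cfg or PreprocessConfig()
    out = assay.copy()
    counts = out.counts
    mask = np.isnan(counts)
    if not mask.any():
        return out
    if cfg.impute_strategy == "position_mean":
        positions = out.variants["position"].to_numpy()
        fill = np.full_like(counts, cfg.pseudocount)
        for pos in np.unique(positions):
            rows = positions == pos
            block = counts[rows]  # (n_pos, T+1, R)
            with np.errstate(invalid="ignore"):
                col_mean = np.nanmean(block, axis=0)  # NaN when nothing observed
            col_mean = np.where(np.isnan(col_mean), cfg.pseudocount, col_mean)
            fill[rows] = col_mean[None, :, :]
        counts[mask] = fill[mask]
    else:
        counts[mask] = cfg.pseudocount
    return out


def normalize_counts(assay: Assay, cfg: PreprocessConfig | None = None) -> Assay:
    """Transform imputed counts to aligned log-counts ``m``.

    ``m[v,t,r] = log(c + pc) - log(colsum) - center[t,r]`` where ``center`` is
    the per-column median over synonymous variants (total-count median when
    the screen has no synonymous variants), so synonymous scores sit at zero
    in every column.
    """
    cfg = cfg or PreprocessConfig()
    if np.isnan(assay.counts).any():
        raise ValueError("normalize_counts requires imputed counts")
    out = assay.copy()
    lib = out.counts.sum(axis=0)  # (T+1, R)
    if np.any(lib <= 0):
        raise NormalizationError("column total is zero; cannot normalize")
    logc = np.log(out.counts + cfg.pseudocount) - np.log(lib)[None, :, :]
    syn = (out.variants["mclass"] == SYNONYMOUS).to_numpy()
    if syn.any():
        center = np.median(logc[syn], axis=0)
    else:
        center = np.median(logc, axis=0)
    out.m = logc - center[None, :, :]
    return out


def build_position_map(assay: Assay, cfg: PreprocessConfig | None = None) -> Assay:
    """Construct ``p(v)``: control group for synonymous variants,
    pseudo-positions for indels, and forward merging of sparse positions.

    A real position with fewer than ``min_pos_variants`` variants is merged
    into the next larger position, cascading until every group is large
    enough; a sparse terminal group merges backward into the previous group.
    """
    cfg = cfg or PreprocessConfig()
    variants = assay.variants
    mclass = variants["mclass"].to_numpy()
    positions = variants["position"].to_numpy()

    is_syn = mclass == SYNONYMOUS
    is_del = mclass == DELETION
    is_ins = mclass == INSERTION
    is_real = ~(is_syn | is_del | is_ins)

    real_pos = np.unique(positions[is_real])
    merged: list[list[int]] = []
    pending: list[int] = []
    pending_n = 0
    for pos in real_pos:
        pending.append(int(pos))
        pending_n += int((is_real & (positions == pos)).sum())
        if pending_n >= cfg.min_pos_variants:
            merged.append(pending)
            pending, pending_n = [], 0
    if pending:
        if merged:
            merged[-1].extend(pending)  # sparse terminal group merges backward
        else:
            merged.append(pending)

    labels: list[str] = []
    group_of_pos: dict[int, int] = {}
    for group in merged:
        idx = len(labels)
        labels.append(str(group[0]) if len(group) == 1
                      else f"{group[0]}-{group[-1]}")
        for pos in group:
            group_of_pos[pos] = idx

    pmap = np.full(len(variants), -1, dtype=int)
    for i in np.flatnonzero(is_real):
        pmap[i] = group_of_pos[int(positions[i])]

    pseudo_groups: list[int] = []
    if is_del.any():
        idx = len(labels)
        labels.append("del")
        pmap[is_del] = idx
        pseudo_groups.append(idx)
    if is_ins.any():
        idx = len(labels)
        labels.append("ins")
        pmap[is_ins] = idx
        pseudo_groups.append(idx)

    control_group = None
    if is_syn.any():
        control_group = len(labels)
        labels.append("control")
        pmap[is_syn] = control_group

    out = assay.copy()
    out.pmap = pmap
    out.position_labels = labels
    out.control_group = control_group
    out.pseudo_groups = pseudo_groups
    return out


def naive_scores(assay: Assay) -> np.ndarray:
    """Per-variant ordinary least-squares slope of ``m`` on ``t / T``.

    A cheap deterministic point estimate of the functional score, used for
    mean-group assignment and as an independent reference in tests.
    """
    if assay.m is None:
        raise ValueError("aligned counts m not computed; run normalize_counts")
    x = np.arange(assay.T + 1) / assay.T  # (T+1,)
    xc = x - x.mean()
    y = assay.m.mean(axis=2)  # average replicates -> (V, T+1)
    return (y * xc).sum(axis=1) / (xc ** 2).sum()


def assign_mean_groups(assay: Assay, cfg: PreprocessConfig | None = None) -> Assay:
    """Split variants into equal-frequency bins of the naive score -> g(v)."""
    cfg = cfg or PreprocessConfig()
    if cfg.n_mean_groups > assay.n_variants:
        raise ValueError("n_mean_groups exceeds the number of variants")
    scores = naive_scores(assay)
    out = assay.copy()
    if cfg.n_mean_groups == 1:
        out.gmap = np.zeros(assay.n_variants, dtype=int)
        return out
    ranks = pd.Series(scores).rank(method="first").to_numpy()
    out.gmap = np.minimum(
        (cfg.n_mean_groups * (ranks - 1) / len(ranks)).astype(int),
        cfg.n_mean_groups - 1,
    )
    return out


def preprocess(assay: Assay, cfg: PreprocessConfig | None = None) -> Assay:
    """Run the full pipeline: filter, impute, normalize, p(v), g(v)."""
    cfg = cfg or PreprocessConfig()
    out = filter_variants(assay, cfg)
    out = impute_counts(out, cfg)
    out = normalize_counts(out, cfg)
    out = build_position_map(out, cfg)
    out = assign_mean_groups(out, cfg)
    return out
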