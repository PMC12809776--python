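"""Prediction-difficulty analysis and variance-guided subsampling.

Two questions for experiment design: (i) which positions are intrinsically
hard to predict from position and substitution effects alone — answered by
binning positions on the activation score rho or the residual variance
sigma2 and computing the within-bin R-squared of scores against the model's
prior-mean prediction (or an external predictor such as a pathogenicity
score); and (ii) whether, when only part of a library can be assayed,
spending the second sampling round preferentially on high-sigma2 positions
beats uniform sampling — answered by a paired simulation experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Assay
from .model import McmcConfig, ModelSpec, PosteriorResult, fit
from .preprocess import naive_scores
from .substitution import build_groups


@dataclass
class SamplingScheme:
    """Two-round subsampling plan.

    Round 1 samples ``round1_frac`` of each position's variants uniformly.
    Round 2 either samples another ``round2_frac`` uniformly (``random``) or
    splits positions into ``n_bins`` quantile bins of the round-1 residual
    variance and samples ``guided_rates[bin]`` of each position's pool
    (``guided``), drawing only from not-yet-sampled variants.  The default
    guided schedule (10%..40% over quartiles) averages to the random rate,
    so the two modes draw the same expected total.
    """

    round1_frac: float = 0.2
    round2_mode: str = "guided"
    round2_frac: float = 0.25
    n_bins: int = 4
    guided_rates: tuple = (0.10, 0.20, 0.30, 0.40)

    def __post_init__(self):
        for name in ("round1_frac", "round2_frac"):
            if not 0 < getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if len(self.guided_rates) != self.n_bins:
            raise ValueError("guided_rates length must equal n_bins")
        if self.round2_mode not in {"random", "guided"}:
            raise ValueError(f"unknown round2_mode {self.round2_mode!r}")


def _r2(y: np.ndarray, pred: np.ndarray) -> float:
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return np.nan
    return 1.0 - float(np.sum((y - pred) ** 2)) / ss_tot


def prediction_r2_by_bin(
    result: PosteriorResult,
    assay: Assay,
    bin_by: str = "sigma2",
    n_bins: int = 10,
    predictor: np.ndarray | None = None,
) -> pd.DataFrame:
    """Within-bin R-squared of scores against the prior-mean prediction.

    Real positions are split into ``n_bins`` quantile bins of the posterior
    mean of ``rho`` or ``sigma2``; variants inherit their position's bin.
    ``predictor`` replaces the model's prior mean with an external
    per-variant score (e.g. a pathogenicity predictor).
    """
    if bin_by not in {"rho", "sigma2"}:
        raise ValueError("bin_by must be 'rho' or 'sigma2'")
    if bin_by == "rho" and "rho" not in result.draws:
        raise ValueError("result has no rho draws; fit model 3")
    stat = result.mean(bin_by)
    n_pos = len(result.position_labels)
    exclude = {result.control_group} | set(result.pseudo_groups)
    real = np.array([g for g in range(n_pos) if g not in exclude])
    if n_bins > real.size:
        raise ValueError("n_bins exceeds the number of real positions")

    bins = pd.qcut(stat[real], n_bins, labels=False, duplicates="drop")
    bin_of_group = dict(zip(real, bins))

    beta = result.mean("beta")
    pred = result.prior_mean_per_variant() if predictor is None else np.asarray(predictor)
    rows = []
    for k in sorted(set(bins)):
        groups = [g for g, bk in bin_of_group.items() if bk == k]
        members = np.isin(result.pmap, groups)
        rows.append(
            {
                "bin": int(k),
                "stat_lo": float(stat[groups].min()),
                "stat_hi": float(stat[groups].max()),
                "n_positions": len(groups),
                "n_variants": int(members.sum()),
                "r2": _r2(beta[members], pred[members]),
            }
        )
    return pd.DataFrame(rows)


def _fit_subset(
    assay: Assay,
    rows: np.ndarray,
    mcmc: McmcConfig,
    min_pos_variants: int,
) -> PosteriorResult:
    """Preprocess and fit model 3 on a row subset of a full assay."""
    from .preprocess import PreprocessConfig, preprocess

    sub = assay.subset(np.sort(rows))
    cfg = PreprocessConfig(min_pos_variants=min_pos_variants)
    sub = preprocess(sub, cfg)
    scheme = build_groups(sub)
    return fit(sub, scheme, ModelSpec(3), mcmc)


@dataclass
class GuidedSamplingReport:
    per_repeat: pd.DataFrame
    mean_r2_random: float = field(init=False)
    mean_r2_guided: float = field(init=False)
    mean_delta_r2: float = field(init=False)

    def __post_init__(self):
        self.mean_r2_random = float(self.per_repeat["r2_random"].mean())
        self.mean_r2_guided = float(self.per_repeat["r2_guided"].mean())
        self.mean_delta_r2 = float(self.per_repeat["delta_r2"].mean())


def guided_sampling_experiment(
    assay: Assay,
    scheme: SamplingScheme | None = None,
    mcmc: McmcConfig | None = None,
    seed: int = 0,
    n_repeats: int = 20,
    min_pos_variants: int = 3,
) -> GuidedSamplingReport:
    """Paired comparison of random vs sigma2-guided second-round sampling.

    The full assay is the ground-truth pool; the held-out reference score of
    an unsampled variant is its per-variant least-squares slope from the full
    aligned counts.  Per repeat: sample round 1 uniformly per position, fit,
    then draw round 2 both ways, refit on each union, predict the still
    unsampled variants from the fitted prior mean, and report out-of-sample
    R-squared for both modes and their difference.  Synonymous (control)
    variants are always retained in full, since normalization centers on
    them.
    """
    scheme = scheme or SamplingScheme()
    if mcmc is None:
        mcmc = McmcConfig(seed=seed, chains=2, warmup=300, samples=300)
    if assay.m is None or assay.pmap is None:
        raise ValueError("assay must be preprocessed")

    pool_ref = naive_scores(assay)
    n_pos = len(assay.position_labels)
    exclude = {assay.control_group} | set(assay.pseudo_groups)
    always = np.flatnonzero(np.isin(assay.pmap, list(exclude)))
    real_groups = [g for g in range(n_pos) if g not in exclude]
    by_group = {g: np.flatnonzero(assay.pmap == g) for g in real_groups}
    for g, members in by_group.items():
        if members.size < 3:
            raise ValueError(f"position group {g} too small for subsampling")

    rng_master = np.random.default_rng(seed)
    rows = []
    for rep in range(n_repeats):
        rng = np.random.default_rng(rng_master.integers(2 ** 31))
        fit_seed = int(rng.integers(2 ** 31))
        mc = McmcConfig(seed=fit_seed, chains=mcmc.chains,
                       warmup=mcmc.warmup, samples=mcmc.samples)

        sampled = {
            g: rng.choice(m, size=max(1, round(scheme.round1_frac * m.size)),
                          replace=False)
            for g, m in by_group.items()
        }
        round1_rows = np.concatenate([always] + list(sampled.values()))
        res1 = _fit_subset(assay, round1_rows, mc, min_pos_variants)

        # map round-1 sigma2 back to the full assay's position groups
        sigma2 = dict(zip(res1.position_labels, res1.mean("sigma2")))
        stat = np.array(
            [sigma2.get(assay.position_labels[g], np.nan) for g in real_groups]
        )
        observed = ~np.isnan(stat)
        bins = np.zeros(len(real_groups), dtype=int)
        bins[observed] = pd.qcut(stat[observed], scheme.n_bins, labels=False,
                                 duplicates="drop")

        def round2(mode):
            chosen = []
            for i, g in enumerate(real_groups):
                pool = by_group[g]
                remaining = np.setdiff1d(pool, sampled[g])
                rate = (scheme.round2_frac if mode == "random"
                        else scheme.guided_rates[bins[i]])
                k = min(round(rate * pool.size), remaining.size)
                if k > 0:
                    chosen.append(rng.choice(remaining, size=k, replace=False))
            extra = np.concatenate(chosen) if chosen else np.array([], dtype=int)
            return np.concatenate([round1_rows, extra])

        out = {"repeat": rep}
        for mode in ("random", "guided"):
            union = round2(mode)
            res = _fit_subset(assay, union, mc, min_pos_variants)
            # predict the full-pool variants never sampled in this mode
            unsampled = np.setdiff1d(
                np.concatenate(list(by_group.values())), union
            )
            pred = _predict_unseen(assay, res, unsampled)
            ok = ~np.isnan(pred)
            out[f"r2_{mode}"] = _r2(pool_ref[unsampled[ok]], pred[ok])
            out[f"n_{mode}"] = int(union.size)
        out["delta_r2"] = out["r2_guided"] - out["r2_random"]
        rows.append(out)
    return GuidedSamplingReport(per_repeat=pd.DataFrame(rows))


def _predict_unseen(assay: Assay, result: PosteriorResult,
                    rows: np.ndarray) -> np.ndarray:
    """Prior-mean prediction for variants absent from a subset fit.

    Positions are matched by label; substitution groups by group label after
    rescoring the unseen variants against the subset fit's grouping.
    """
    from .substitution import blosum_score

    phi = dict(zip(result.position_labels, result.mean("phi")))
    rho = dict(zip(result.position_labels, result.mean("rho"))) \
        if "rho" in result.draws else None
    nu = result.mean("nu") if "nu" in result.draws else None

    # score range -> nu per fitted group, parsed from labels like
    # "blosum[-4,-1]"; an unseen score between ranges maps to the nearest
    ranges = []
    if nu is not None:
        for gi, lab in enumerate(result.group_labels):
            if lab.startswith("blosum["):
                body = lab[len("blosum["):-1]
                parts = [int(p) for p in body.split(",")]
                lo, hi = parts[0], parts[-1]
                ranges.append((lo, hi, nu[gi]))
    special = {lab: nu[gi] for gi, lab in enumerate(result.group_labels or [])
               if not lab.startswith("blosum[")} if nu is not None else {}

    preds = np.full(rows.size, np.nan)
    variants = assay.variants
    pos_label = [assay.position_labels[g] for g in assay.pmap]
    for j, row in enumerate(rows):
        lab = pos_label[row]
        if lab not in phi:
            continue
        base = phi[lab]
        nu_val = 0.0
        mclass = variants["mclass"].iat[row]
        if nu is not None:
            if mclass == "missense" and ranges:
                score = blosum_score(variants["wt"].iat[row],
                                     variants["mut"].iat[row])
                nu_val = min(
                    ranges,
                    key=lambda rg: min(abs(score - rg[0]), abs(score - rg[1]))
                    if not rg[0] <= score <= rg[1] else -1,
                )[2]
            elif mclass == "nonsense":
                nu_val = special.get("nonsense", 0.0)
            elif mclass == "deletion":
                nu_val = special.get("del", 0.0)
            elif mclass == "insertion":
                nu_val = special.get("ins", 0.0)
        r = rho.get(lab, 1.0) if rho is not None else 1.0
        preds[j] = base + nu_val * r
    return preds
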