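"""Synthetic growth screens drawn from the full generative model.

The simulator produces a variant roster (saturating missense coverage plus
synonymous controls and single-residue deletions), draws position effects,
substitution-group effects on the exact weighted sum-to-zero space,
per-position activation scores and residual variances, then variant scores,
aligned log-counts under the linear-growth likelihood, and finally raw
sequencing counts by inverting the normalization with per-column library
sizes.  Everything is deterministic given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import AA_CODES, Assay
from .preprocess import PreprocessConfig, build_position_map
from .substitution import GroupingScheme, build_groups

__all__ = ["SimConfig", "TrueParams", "simulate_truth", "simulate_assay",
           "simulate", "recovery_report"]


@dataclass
class SimConfig:
    """Study conditions for a synthetic screen.

    Defaults are a desk-scale saturating screen: 50 positions with all 19
    missense changes plus one synonymous control and one deletion per
    position (21 variants/position), three selection rounds after the input
    round, three replicates.  Truth distributions mirror the model priors
    (``phi ~ Normal(0,1)``, ``rho ~ Beta(1.5,1.5)``); residual variances are
    log-uniform on ``sigma2_range`` and replicate noise scales are spread
    linearly over ``eps_range`` across mean groups.  Library sizes per
    sequencing column are uniform on ``lib_size_range``.
    """

    n_positions: int = 50
    variants_per_position: int = 21
    frac_synonymous: float = 1 / 21
    frac_indel: float = 1 / 21
    T: int = 3
    R: int = 3
    phi_mean: float = 0.0
    phi_sd: float = 1.0
    rho_beta: tuple[float, float] | None = (1.5, 1.5)
    rho_fixed: float | None = None
    nu_sd: float = 1.0
    sigma2_range: tuple[float, float] = (0.1, 1.0)
    sigma2_levels: tuple[float, ...] | None = None
    eps_range: tuple[float, float] = (0.1, 0.3)
    n_mean_groups: int = 5
    b_sd: float = 0.3
    lib_size_range: tuple[float, float] = (3e5, 1e6)
    missing_frac: float = 0.0

    def __post_init__(self):
        if self.frac_synonymous + self.frac_indel > 1:
            raise ValueError("synonymous and indel fractions must sum to <= 1")
        for name in ("phi_sd", "b_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class TrueParams:
    """Ground-truth parameters stored for recovery scoring."""

    phi: np.ndarray            # per position group
    rho: np.ndarray
    sigma2: np.ndarray
    nu: np.ndarray             # per substitution group (length A)
    beta: np.ndarray           # per variant
    b: np.ndarray
    eps: np.ndarray            # per mean group
    pmap: np.ndarray
    amap: np.ndarray
    gmap: np.ndarray
    position_labels: list[str]
    group_labels: list[str]
    control_group: int | None
    pseudo_groups: list[int]
    scheme: GroupingScheme
    variants: pd.DataFrame
    m: np.ndarray | None = None
    meta: dict = field(default_factory=dict)


def _roster(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Variant roster: wt/mut per position with syn and deletion fractions."""
    vpp = cfg.variants_per_position
    n_syn = int(round(cfg.frac_synonymous * vpp))
    n_del = int(round(cfg.frac_indel * vpp))
    n_mis = min(vpp - n_syn - n_del, 19)
    rows = []
    for pos in range(1, cfg.n_positions + 1):
        wt = AA_CODES[rng.integers(len(AA_CODES))]
        muts = rng.choice([a for a in AA_CODES if a != wt], size=n_mis,
                          replace=False)
        for mut in muts:
            rows.append((f"{wt}{pos}{mut}", wt, pos, mut, "missense"))
        for _ in range(n_syn):
            rows.append((f"{wt}{pos}=", wt, pos, "syn", "synonymous"))
        for _ in range(n_del):
            rows.append((f"{wt}{pos}del", wt, pos, "del", "deletion"))
    return pd.DataFrame(
        rows, columns=["variant_id", "wt", "position", "mut", "mclass"]
    )


def simulate_truth(cfg: SimConfig | None = None, seed: int = 0) -> TrueParams:
    """Draw the ground-truth parameter set for one synthetic screen."""
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(seed)
    variants = _roster(cfg, rng)
    V = len(variants)

    skeleton = Assay(
        variants=variants,
        counts=np.zeros((V, cfg.T + 1, cfg.R)),
        T=cfg.T,
        R=cfg.R,
    )
    skeleton = build_position_map(
        skeleton, PreprocessConfig(min_pos_variants=1)
    )
    scheme = build_groups(skeleton)
    pmap = skeleton.pmap
    n_pos = len(skeleton.position_labels)

    phi = rng.normal(cfg.phi_mean, cfg.phi_sd, size=n_pos)
    if cfg.rho_fixed is not None:
        rho = np.full(n_pos, float(cfg.rho_fixed))
    else:
        rho = rng.beta(*cfg.rho_beta, size=n_pos)
    if cfg.sigma2_levels is not None:
        # discrete residual-variance classes (e.g. quiet vs noisy positions)
        sigma2 = rng.choice(np.asarray(cfg.sigma2_levels, float), size=n_pos)
    else:
        lo, hi = cfg.sigma2_range
        sigma2 = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_pos))
    if skeleton.control_group is not None:
        phi[skeleton.control_group] = 0.0
        sigma2[skeleton.control_group] = 0.01

    # substitution effects on the exact weighted sum-to-zero space
    nu = np.zeros(scheme.A)
    if cfg.nu_sd > 0:
        raw = rng.normal(0.0, cfg.nu_sd, size=scheme.n_free)
        w = scheme.w
        raw = raw - w * (w @ raw) / (w @ w)
        nu[scheme.free] = raw

    mu = phi[pmap] + nu[scheme.amap] * rho[pmap]
    beta = rng.normal(mu, np.sqrt(sigma2[pmap]))
    b = rng.normal(0.0, cfg.b_sd, size=V)

    # mean groups by quantile of the true score; noisier groups last
    ranks = pd.Series(beta).rank(method="first").to_numpy()
    gmap = np.minimum(
        (cfg.n_mean_groups * (ranks - 1) / V).astype(int),
        cfg.n_mean_groups - 1,
    )
    eps = np.linspace(*cfg.eps_range, cfg.n_mean_groups)

    return TrueParams(
        phi=phi, rho=rho, sigma2=sigma2, nu=nu, beta=beta, b=b, eps=eps,
        pmap=pmap, amap=scheme.amap, gmap=gmap,
        position_labels=list(skeleton.position_labels),
        group_labels=list(scheme.group_labels),
        control_group=skeleton.control_group,
        pseudo_groups=list(skeleton.pseudo_groups),
        scheme=scheme, variants=variants,
        meta={"seed": seed},
    )


def simulate_assay(truth: TrueParams, cfg: SimConfig | None = None,
                   seed: int = 1) -> Assay:
    """Raw counts for a ground-truth draw.

    Aligned log-counts follow the linear-growth likelihood; raw counts are
    the exponentiated values rescaled column-by-column to a random library
    size and rounded, so preprocessing approximately recovers ``m``.
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(seed)
    V = len(truth.variants)
    x = np.arange(cfg.T + 1) / cfg.T
    mean = truth.beta[:, None] * x[None, :] + truth.b[:, None]
    scale = truth.eps[truth.gmap]
    m = rng.normal(mean[:, :, None],
                   scale[:, None, None],
                   size=(V, cfg.T + 1, cfg.R))
    truth.m = m

    rel = np.exp(m)
    lib = rng.uniform(*cfg.lib_size_range, size=(cfg.T + 1, cfg.R))
    counts = np.round(rel / rel.sum(axis=0, keepdims=True) * lib[None, :, :])
    if cfg.missing_frac > 0:
        mask = rng.uniform(size=counts.shape) < cfg.missing_frac
        counts[mask] = np.nan
    return Assay(
        variants=truth.variants.copy(),
        counts=counts,
        T=cfg.T,
        R=cfg.R,
        meta={"simulated": True, "seed": seed},
    )


def simulate(cfg: SimConfig | None = None, seed: int = 0):
    """Convenience wrapper: ``(assay, truth)`` from one master seed."""
    cfg = cfg or SimConfig()
    ss = np.random.SeedSequence(seed).generate_state(2)
    truth = simulate_truth(cfg, seed=int(ss[0] % (2 ** 31)))
    assay = simulate_assay(truth, cfg, seed=int(ss[1] % (2 ** 31)))
    return assay, truth


def _align_by_label(truth_labels, truth_values, fit_labels, fit_values):
    common = [lab for lab in fit_labels if lab in set(truth_labels)]
    t_index = {lab: i for i, lab in enumerate(truth_labels)}
    f_index = {lab: i for i, lab in enumerate(fit_labels)}
    t = np.array([truth_values[t_index[lab]] for lab in common])
    f = np.array([fit_values[f_index[lab]] for lab in common])
    return t, f


def recovery_report(truth: TrueParams, result, assay: Assay | None = None) -> dict:
    """Score a fit against the generating truth.

    Per parameter family: Pearson and Spearman correlation, RMSE, and (for
    phi) empirical coverage of the central 90% credible interval.  Position
    and substitution families are aligned by group label; the control and
    pseudo-position groups are excluded from the position metrics.
    """
    report: dict = {}

    def metrics(true_vals, est, lo=None, hi=None):
        out = {
            "pearson": float(np.corrcoef(true_vals, est)[0, 1])
            if np.std(true_vals) > 0 and np.std(est) > 0 else np.nan,
            "spearman": float(sps.spearmanr(true_vals, est).statistic)
            if np.std(true_vals) > 0 else np.nan,
            "rmse": float(np.sqrt(np.mean((true_vals - est) ** 2))),
        }
        if lo is not None:
            out["coverage90"] = float(
                np.mean((true_vals >= lo) & (true_vals <= hi))
            )
        return out

    # variant scores: roster order is preserved through preprocessing only
    # if no variant was filtered, so align by variant_id
    ids_fit = result.variant_ids
    order = truth.variants.set_index("variant_id").index
    keep = [i for i, vid in enumerate(ids_fit) if vid in set(order)]
    truth_beta = truth.variants.assign(beta=truth.beta).set_index("variant_id")
    beta_true = truth_beta.loc[[ids_fit[i] for i in keep], "beta"].to_numpy()
    beta_draws = result.pooled("beta")[:, keep]
    lo, hi = np.quantile(beta_draws, [0.05, 0.95], axis=0)
    report["beta"] = metrics(beta_true, beta_draws.mean(axis=0), lo, hi)

    exclude = {truth.control_group} | set(truth.pseudo_groups)
    real = [lab for g, lab in enumerate(truth.position_labels)
            if g not in exclude]

    for name in ("phi", "rho", "sigma2"):
        if name not in result.draws:
            continue
        true_all = getattr(truth, name)
        est_all = result.mean(name)
        lo_all, hi_all = result.quantile(name, [0.05, 0.95])
        t, e = _align_by_label(truth.position_labels, true_all,
                               result.position_labels, est_all)
        _, lo_ = _align_by_label(truth.position_labels, true_all,
                                 result.position_labels, lo_all)
        _, hi_ = _align_by_label(truth.position_labels, true_all,
                                 result.position_labels, hi_all)
        mask = np.isin(
            [lab for lab in result.position_labels
             if lab in set(truth.position_labels)],
            real,
        )
        report[name] = metrics(t[mask], e[mask], lo_[mask], hi_[mask])

    if "nu" in result.draws and result.group_labels is not None:
        t, e = _align_by_label(truth.group_labels, truth.nu,
                               result.group_labels, result.mean("nu"))
        report["nu"] = metrics(t, e)
    return report
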