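"""Bayesian hierarchical scoring models for growth screens.

The observation model assumes linear growth of the aligned log-count with
selection round: ``m[v,t,r] ~ Normal(beta_v * t/T + b_v, eps_{g(v)}^2)``.
The functional score ``beta_v`` carries a hierarchical prior whose mean
decomposes into a position effect and a position-scaled substitution effect:

* model 1: ``beta_v ~ Normal(phi_{p(v)}, sigma2_{p(v)})``
* model 2: adds a global substitution effect, ``phi + nu_{a(v)}``
* model 3: scales it per position, ``phi + nu_{a(v)} * rho_{p(v)}``

Hyperpriors: ``phi ~ Normal(0, 1)``, ``sigma2 ~ InvGamma(1, 1)``,
``eps ~ InvGamma(1, 1)`` (on the scale), ``rho ~ Beta(1.5, 1.5)`` and the
substitution effects ``nu`` carry the degenerate weighted sum-to-zero prior
(see :mod:`dmscore.substitution`); the synonymous effect is a structural
zero.  Because every conditional except ``rho`` and ``eps`` is conjugate,
posterior sampling runs as a blocked Gibbs sampler with univariate
slice-sampling updates for the two non-conjugate families — so every draw
satisfies all support constraints (rho in [0,1], positive scales, exact
weighted sum-to-zero) by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import Assay
from .substitution import GroupingScheme

__all__ = [
    "ModelSpec",
    "McmcConfig",
    "PosteriorResult",
    "fit",
    "log_likelihood",
    "log_joint",
    "prior_mean_beta",
    "lfsr",
    "check_convergence",
]

SIGMA2_FLOOR = 1e-6
_RHO_PRIOR_A = 1.5
_RHO_PRIOR_B = 1.5


@dataclass
class ModelSpec:
    """Which nested model to fit.

    model_id 1 is position-only; 2 adds the global substitution effect
    (rho pinned at 1); 3 is the full position-scaled model.  ``b_sd`` is the
    standard deviation of the weak Normal prior on the round-0 intercept.
    """

    model_id: int = 3
    b_sd: float = 1.0

    def __post_init__(self):
        if self.model_id not in (1, 2, 3):
            raise ValueError("model_id must be 1, 2 or 3")


@dataclass
class McmcConfig:
    seed: int
    chains: int = 4
    warmup: int = 1000
    samples: int = 1000


def prior_mean_beta(
    phi: np.ndarray,
    nu: np.ndarray | None,
    rho: np.ndarray | None,
    pmap: np.ndarray,
    amap: np.ndarray,
    model_id: int,
) -> np.ndarray:
    """Per-variant prior mean of the functional score under each model."""
    phi = np.asarray(phi)
    mean = phi[..., pmap]
    if model_id == 1:
        return mean
    nu_v = np.asarray(nu)[..., amap]
    if model_id == 2:
        return mean + nu_v
    return mean + nu_v * np.asarray(rho)[..., pmap]


def log_likelihood(
    m: np.ndarray,
    beta: np.ndarray,
    b: np.ndarray,
    eps: np.ndarray,
    gmap: np.ndarray,
    T: int,
) -> float:
    """Gaussian log likelihood of aligned counts summed over (v, t, r)."""
    eps = np.asarray(eps, dtype=float)
    if np.any(eps <= 0):
        raise ValueError("error scales must be positive")
    x = np.arange(T + 1) / T
    mean = beta[:, None, None] * x[None, :, None] + b[:, None, None]
    scale = eps[gmap][:, None, None]
    return float(stats.norm.logpdf(m, loc=mean, scale=scale).sum())


def _slice_bounded(logf, x0, lo, hi, rng, max_iter=200):
    """Vectorized shrinkage slice sampler on a bounded interval."""
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    lo = np.broadcast_to(np.asarray(lo, dtype=float), x0.shape).copy()
    hi = np.broadcast_to(np.asarray(hi, dtype=float), x0.shape).copy()
    logy = logf(x0) - rng.exponential(size=x0.shape)
    out = x0.copy()
    done = np.zeros(x0.shape, dtype=bool)
    for _ in range(max_iter):
        prop = lo + rng.uniform(size=x0.shape) * (hi - lo)
        accept = (logf(prop) >= logy) & ~done
        out[accept] = prop[accept]
        done |= accept
        if done.all():
            break
        shrink = ~done
        left = shrink & (prop < x0)
        right = shrink & ~left
        lo[left] = prop[left]
        hi[right] = prop[right]
    return out


class _Sufficients:
    """Per-variant sufficient statistics of the balanced linear model."""

    def __init__(self, assay: Assay):
        if assay.m is None:
            raise ValueError("assay has no aligned counts; run preprocessing")
        if np.isnan(assay.m).any():
            raise ValueError("aligned counts contain missing values")
        T, R = assay.T, assay.R
        x = np.arange(T + 1) / T
        self.x = x
        self.n = (T + 1) * R
        self.Sx = R * x.sum()
        self.Sxx = R * (x ** 2).sum()
        m = assay.m
        self.Sm = m.sum(axis=(1, 2))
        self.Sxm = (m.sum(axis=2) * x[None, :]).sum(axis=1)
        self.Smm = (m ** 2).sum(axis=(1, 2))

    def rss(self, beta, b):
        """Residual sum of squares per variant for given coefficients."""
        return (
            self.Smm
            - 2 * beta * self.Sxm
            - 2 * b * self.Sm
            + beta ** 2 * self.Sxx
            + 2 * beta * b * self.Sx
            + b ** 2 * self.n
        )


@dataclass
class PosteriorResult:
    """Posterior draws and summaries for one fitted model.

    ``draws`` maps parameter names to arrays of shape (chains, samples, dim):
    ``beta``, ``b``, ``phi``, ``sigma2``, ``eps`` always; ``nu`` (length A)
    and, for model 3, ``rho`` for the substitution models.
    """

    draws: dict[str, np.ndarray]
    model_id: int
    pmap: np.ndarray
    amap: np.ndarray | None
    gmap: np.ndarray
    position_labels: list[str]
    group_labels: list[str] | None
    control_group: int | None
    pseudo_groups: list[int]
    variant_ids: list[str]
    provenance: dict = field(default_factory=dict)

    def pooled(self, name: str) -> np.ndarray:
        d = self.draws[name]
        return d.reshape(-1, d.shape[-1])

    def mean(self, name: str) -> np.ndarray:
        return self.pooled(name).mean(axis=0)

    def sd(self, name: str) -> np.ndarray:
        return self.pooled(name).std(axis=0)

    def quantile(self, name: str, q) -> np.ndarray:
        return np.quantile(self.pooled(name), q, axis=0)

    def score_table(self) -> pd.DataFrame:
        beta = self.pooled("beta")
        lo, hi = np.quantile(beta, [0.05, 0.95], axis=0)
        return pd.DataFrame(
            {
                "variant_id": self.variant_ids,
                "beta_mean": beta.mean(axis=0),
                "beta_sd": beta.std(axis=0),
                "beta_q05": lo,
                "beta_q95": hi,
                "lfsr": lfsr(beta),
            }
        )

    def position_table(self) -> pd.DataFrame:
        n_groups = len(self.position_labels)
        table = pd.DataFrame(
            {
                "position": self.position_labels,
                "phi_mean": self.mean("phi"),
                "phi_sd": self.sd("phi"),
                "sigma2_mean": self.mean("sigma2"),
                "sigma2_sd": self.sd("sigma2"),
                "n_variants": np.bincount(self.pmap, minlength=n_groups),
                "is_control": [g == self.control_group for g in range(n_groups)],
                "is_pseudo": [g in self.pseudo_groups for g in range(n_groups)],
            }
        )
        if "rho" in self.draws:
            table.insert(3, "rho_mean", self.mean("rho"))
            table.insert(4, "rho_sd", self.sd("rho"))
        return table

    def prior_mean_per_variant(self) -> np.ndarray:
        """Posterior-mean plug-in of the variant prior mean (the model's
        point prediction of a score from position and substitution alone)."""
        nu = self.mean("nu") if "nu" in self.draws else None
        rho = self.mean("rho") if "rho" in self.draws else None
        return prior_mean_beta(
            self.mean("phi"), nu, rho, self.pmap, self.amap, self.model_id
        )


def lfsr(beta_draws: np.ndarray) -> np.ndarray:
    """Local false sign rate: min(Pr[beta > 0], Pr[beta < 0]) per variant."""
    beta_draws = np.asarray(beta_draws)
    if beta_draws.ndim == 1:
        beta_draws = beta_draws[:, None]
    pos = (beta_draws > 0).mean(axis=0)
    neg = (beta_draws < 0).mean(axis=0)
    return np.minimum(pos, neg)


def _initial_values(assay, stats_, spec, scheme, rng):
    """OLS-based starting point, jittered per chain."""
    x = stats_.x
    xc = x - x.mean()
    y = assay.m.mean(axis=2)
    beta = (y * xc[None, :]).sum(axis=1) / (xc ** 2).sum()
    b = y.mean(axis=1) - beta * x.mean()
    n_pos = len(assay.position_labels)
    phi = np.zeros(n_pos)
    sigma2 = np.full(n_pos, 0.25)
    for p in range(n_pos):
        members = assay.pmap == p
        if members.any():
            phi[p] = beta[members].mean()
            sigma2[p] = max(float(beta[members].var()), 0.01)
    n_groups = int(assay.gmap.max()) + 1
    resid = stats_.rss(beta, b) / stats_.n
    eps = np.sqrt(
        np.maximum(np.bincount(assay.gmap, weights=resid, minlength=n_groups)
                   / np.maximum(np.bincount(assay.gmap, minlength=n_groups), 1),
                   1e-4)
    )
    state = {
        "beta": beta + 0.05 * rng.standard_normal(beta.shape),
        "b": b,
        "phi": phi + 0.05 * rng.standard_normal(phi.shape),
        "sigma2": sigma2,
        "eps": eps,
    }
    if spec.model_id >= 2:
        state["z"] = 0.1 * rng.standard_normal(scheme.n_free - 1)
    if spec.model_id == 3:
        state["rho"] = np.clip(
            0.5 + 0.05 * rng.standard_normal(n_pos), 0.05, 0.95
        )
    return state


def _run_chain(assay, scheme, spec, stats_, n_iter, n_keep, rng):
    V = assay.n_variants
    n_pos = len(assay.position_labels)
    pmap, gmap = assay.pmap, assay.gmap
    n_groups = int(gmap.max()) + 1
    n_pos_count = np.bincount(pmap, minlength=n_pos).astype(float)
    N_g = np.bincount(gmap, minlength=n_groups) * stats_.n

    state = _initial_values(assay, stats_, spec, scheme, rng)
    b_prec0 = 1.0 / spec.b_sd ** 2

    with_nu = spec.model_id >= 2
    with_rho = spec.model_id == 3
    if with_nu:
        amap = scheme.amap
        free_index = np.full(scheme.A, -1, dtype=int)
        free_index[scheme.free] = np.arange(scheme.n_free)
        v_free = free_index[amap] >= 0  # variants with an estimated nu
        fmap = free_index[amap[v_free]]  # free-group index per such variant
        p_free = pmap[v_free]
        C = scheme.B / scheme.w[:, None]  # (F, F-1); nu_free = C @ z
        dim_z = scheme.n_free - 1
        # positions carrying at least one constrained variant
        has_free = np.zeros(n_pos, dtype=bool)
        has_free[np.unique(p_free)] = True
        # free-variant counts per (position, free group), for the joint block
        counts_pa = np.zeros((n_pos, scheme.n_free))
        np.add.at(counts_pa, (p_free, fmap), 1.0)

    keep = {k: np.empty((n_keep,) + np.shape(v)) for k, v in state.items()}
    if with_nu:
        keep["nu"] = np.empty((n_keep, scheme.A))

    for it in range(n_iter):
        beta, b = state["beta"], state["b"]
        phi, sigma2, eps = state["phi"], state["sigma2"], state["eps"]

        if with_nu:
            nu = scheme.nu_from_z(state["z"])
        else:
            nu = None
        rho = state["rho"] if with_rho else None
        mu = prior_mean_beta(phi, nu, rho, pmap, amap if with_nu else None,
                             spec.model_id) if with_nu else phi[pmap]

        # --- (beta, b) joint conjugate update ---------------------------
        eps2_v = eps[gmap] ** 2
        s2_v = sigma2[pmap]
        P11 = stats_.Sxx / eps2_v + 1.0 / s2_v
        P12 = stats_.Sx / eps2_v
        P22 = stats_.n / eps2_v + b_prec0
        l1 = stats_.Sxm / eps2_v + mu / s2_v
        l2 = stats_.Sm / eps2_v
        det = P11 * P22 - P12 ** 2
        c11, c22, c12 = P22 / det, P11 / det, -P12 / det
        mean_beta = c11 * l1 + c12 * l2
        mean_b = c12 * l1 + c22 * l2
        L11 = np.sqrt(c11)
        L21 = c12 / L11
        L22 = np.sqrt(np.maximum(c22 - L21 ** 2, 1e-300))
        e1 = rng.standard_normal(V)
        e2 = rng.standard_normal(V)
        beta = mean_beta + L11 * e1
        b = mean_b + L21 * e1 + L22 * e2
        state["beta"], state["b"] = beta, b

        # --- (phi, z) joint conjugate block -----------------------------
        # sampling position effects and whitened substitution effects
        # together removes their posterior coupling (a substitution group
        # seen at few positions trades off against those positions' phi)
        if with_nu:
            rho_p = rho if with_rho else np.ones(n_pos)
            # per-position and per-group accumulations
            sa = np.bincount(fmap, weights=rho_p[p_free] ** 2 / sigma2[p_free],
                             minlength=scheme.n_free)
            prec_pp = 1.0 + n_pos_count / sigma2
            cross = (rho_p / sigma2)[:, None] * (counts_pa @ C)  # (P, K)
            prec_zz = np.eye(dim_z) + C.T @ (sa[:, None] * C)
            lin_p = np.bincount(pmap, weights=beta, minlength=n_pos) / sigma2
            tb = np.bincount(
                fmap,
                weights=rho_p[p_free] * beta[v_free] / sigma2[p_free],
                minlength=scheme.n_free,
            )
            lin_z = C.T @ tb
            prec = np.block(
                [[np.diag(prec_pp), cross], [cross.T, prec_zz]]
            )
            lin = np.concatenate([lin_p, lin_z])
            L = np.linalg.cholesky(prec)
            mean_j = np.linalg.solve(L.T, np.linalg.solve(L, lin))
            theta = mean_j + np.linalg.solve(
                L.T, rng.standard_normal(n_pos + dim_z)
            )
            phi, z = theta[:n_pos], theta[n_pos:]
            state["phi"], state["z"] = phi, z
            nu = scheme.nu_from_z(z)
        else:
            resid = beta
            prec_p = 1.0 + n_pos_count / sigma2
            mean_phi = (
                np.bincount(pmap, weights=resid, minlength=n_pos) / sigma2
            ) / prec_p
            phi = mean_phi + rng.standard_normal(n_pos) / np.sqrt(prec_p)
            state["phi"] = phi

        # --- rho slice update (model 3) ---------------------------------
        if with_rho:
            nu_f = nu[amap[v_free]]
            s2f = sigma2[p_free]
            S1 = np.bincount(
                p_free,
                weights=nu_f * (beta[v_free] - phi[p_free]) / s2f,
                minlength=n_pos,
            )
            S2 = np.bincount(
                p_free, weights=nu_f ** 2 / s2f, minlength=n_pos
            )

            def logf_rho(r):
                return (
                    (_RHO_PRIOR_A - 1) * np.log(r)
                    + (_RHO_PRIOR_B - 1) * np.log1p(-r)
                    + S1 * r
                    - 0.5 * S2 * r ** 2
                )

            rho = _slice_bounded(logf_rho, rho, 1e-9, 1 - 1e-9, rng)
            # uninformative positions: conditional reduces to the prior
            flat = ~has_free | (S2 == 0)
            if flat.any():
                rho[flat] = rng.beta(_RHO_PRIOR_A, _RHO_PRIOR_B, size=flat.sum())

            # joint scale move along the nu*rho ridge: nu -> c*nu,
            # rho -> rho/c leaves the score prior mean invariant, so only
            # the hyperpriors and the Jacobian enter the acceptance ratio
            z = state["z"]
            c = np.exp(0.2 * rng.standard_normal())
            rho_new = rho / c
            if rho_new.max() < 1 - 1e-9 and rho_new.min() > 1e-9:
                z_new = c * z

                def _log_rho_prior(r):
                    return float(
                        ((_RHO_PRIOR_A - 1) * np.log(r)
                         + (_RHO_PRIOR_B - 1) * np.log1p(-r)).sum()
                    )

                log_ratio = (
                    -0.5 * float(z_new @ z_new - z @ z)
                    + _log_rho_prior(rho_new) - _log_rho_prior(rho)
                    + (dim_z - n_pos) * np.log(c)
                )
                if np.log(rng.uniform()) < log_ratio:
                    state["z"] = z_new
                    nu = scheme.nu_from_z(z_new)
                    rho = rho_new
            state["rho"] = rho

        # --- sigma2 conjugate InvGamma update ---------------------------
        if with_nu:
            mu = prior_mean_beta(phi, nu, rho, pmap, amap, spec.model_id)
        else:
            mu = phi[pmap]
        ss = np.bincount(pmap, weights=(beta - mu) ** 2, minlength=n_pos)
        shape = 1.0 + n_pos_count / 2.0
        rate = 1.0 + ss / 2.0
        sigma2 = rate / rng.gamma(shape)
        sigma2 = np.maximum(sigma2, SIGMA2_FLOOR)
        state["sigma2"] = sigma2

        # --- eps slice update (InvGamma prior on the scale) -------------
        S_g = np.bincount(gmap, weights=stats_.rss(beta, b),
                          minlength=n_groups)

        def logf_eta(eta):
            return -(N_g + 1) * eta - np.exp(-eta) - 0.5 * S_g * np.exp(-2 * eta)

        eta = _slice_bounded(logf_eta, np.log(eps), np.log(1e-4), np.log(1e3), rng)
        eps = np.exp(eta)
        state["eps"] = eps

        j = it - (n_iter - n_keep)
        if j >= 0:
            for k in keep:
                if k == "nu":
                    keep[k][j] = scheme.nu_from_z(state["z"])
                else:
                    keep[k][j] = state[k]
    return keep


def fit(
    assay: Assay,
    scheme: GroupingScheme | None = None,
    spec: ModelSpec | None = None,
    mcmc: McmcConfig | None = None,
) -> PosteriorResult:
    """Sample the joint posterior of the chosen model by blocked Gibbs.

    All score, position and substitution parameters are estimated jointly.
    Substitution effects are parameterized in the whitened constraint space,
    so the variant-count-weighted sum-to-zero holds exactly on every draw.
    Convergence is summarized with split-R-hat; a warning (never silent
    success) is emitted when any R-hat exceeds 1.05.
    """
    spec = spec or ModelSpec()
    if mcmc is None:
        raise ValueError("an McmcConfig with an explicit seed is required")
    if spec.model_id >= 2:
        if scheme is None:
            raise ValueError("models 2 and 3 require a GroupingScheme")
        if scheme.n_free < 3:
            raise ValueError("grouping scheme has fewer than 3 free groups")
    if assay.pmap is None or assay.gmap is None:
        raise ValueError("assay must be preprocessed (pmap/gmap present)")

    stats_ = _Sufficients(assay)
    n_iter = mcmc.warmup + mcmc.samples
    seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.chains)
    chains = [
        _run_chain(assay, scheme, spec, stats_, n_iter, mcmc.samples,
                   np.random.default_rng(s))
        for s in seeds
    ]
    draws = {
        k: np.stack([c[k] for c in chains]) for k in chains[0]
    }
    result = PosteriorResult(
        draws=draws,
        model_id=spec.model_id,
        pmap=assay.pmap,
        amap=scheme.amap if scheme is not None else None,
        gmap=assay.gmap,
        position_labels=list(assay.position_labels),
        group_labels=list(scheme.group_labels) if scheme is not None else None,
        control_group=assay.control_group,
        pseudo_groups=list(assay.pseudo_groups),
        variant_ids=assay.variants["variant_id"].tolist(),
        provenance={
            "seed": mcmc.seed,
            "chains": mcmc.chains,
            "warmup": mcmc.warmup,
            "samples": mcmc.samples,
            "model_id": spec.model_id,
        },
    )
    report = check_convergence(result, warn=True)
    result.provenance["convergence"] = report
    return result


def _rhat_split(draws: np.ndarray) -> np.ndarray:
    """Split-R-hat per scalar parameter; draws shaped (chains, samples, dim)."""
    c, s, d = draws.shape
    half = s // 2
    if half < 2:
        return np.full(d, np.nan)
    splits = np.concatenate([draws[:, :half], draws[:, half:2 * half]], axis=0)
    m, n = splits.shape[0], half
    chain_mean = splits.mean(axis=1)
    chain_var = splits.var(axis=1, ddof=1)
    W = chain_var.mean(axis=0)
    B = n * chain_mean.var(axis=0, ddof=1)
    var_plus = (n - 1) / n * W + B / n
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(W > 0, np.sqrt(var_plus / W), 1.0)


def check_convergence(result: PosteriorResult, rhat_max: float = 1.05,
                      warn: bool = False, ess: bool = False,
                      ess_min: float = 100.0) -> dict:
    """Flag parameters whose split-R-hat exceeds the threshold.

    Returns a report mapping parameter family to flagged indices, plus the
    maximum R-hat observed.  With ``ess=True`` bulk effective sample sizes
    are also computed (via arviz) and parameters below ``ess_min`` flagged.
    With a single chain split-R-hat still works on the half-chains but a
    warning is attached to the report.
    """
    report: dict = {"flagged": {}, "max_rhat": 0.0}
    if result.draws["beta"].shape[0] < 2:
        report["note"] = "single chain: diagnostics use split halves only"
    for name in ("beta", "phi", "sigma2", "eps", "nu", "rho"):
        if name not in result.draws:
            continue
        rhat = _rhat_split(result.draws[name])
        good = np.isfinite(rhat)
        if good.any():
            report["max_rhat"] = max(report["max_rhat"], float(rhat[good].max()))
        bad = np.flatnonzero(good & (rhat > rhat_max))
        if bad.size:
            report["flagged"][name] = bad.tolist()
    if ess:
        import arviz as az

        report["low_ess"] = {}
        for name in ("beta", "phi", "sigma2", "eps", "nu", "rho"):
            if name not in result.draws:
                continue
            values = az.ess(az.convert_to_dataset(result.draws[name]))["x"].values
            low = np.flatnonzero(np.atleast_1d(values) < ess_min)
            if low.size:
                report["low_ess"][name] = low.tolist()
    if warn and report["flagged"]:
        warnings.warn(
            f"possible non-convergence: R-hat > {rhat_max} for "
            f"{sorted(report['flagged'])} (max {report['max_rhat']:.3f})",
            RuntimeWarning,
        )
    return report


def log_joint(
    assay: Assay,
    scheme: GroupingScheme | None,
    spec: ModelSpec,
    params: dict,
    include_hyperpriors: bool = True,
) -> float:
    """Log joint density of data and scores at fixed parameter values.

    Always includes the likelihood of ``m`` and the score prior
    ``p(beta | phi, nu, rho, sigma2)``.  With ``include_hyperpriors`` the
    hyperprior terms of the parameters present in the model are added
    (``z`` standard normal in the whitened constraint space, which is the
    proper density of the degenerate ``nu`` prior).
    """
    beta, b = params["beta"], params["b"]
    eps, sigma2, phi = params["eps"], params["sigma2"], params["phi"]
    ll = log_likelihood(assay.m, beta, b, eps, assay.gmap, assay.T)
    if spec.model_id >= 2:
        nu = scheme.nu_from_z(params["z"])
    else:
        nu = None
    rho = params.get("rho") if spec.model_id == 3 else None
    mu = prior_mean_beta(phi, nu, rho, assay.pmap,
                         scheme.amap if scheme is not None else None,
                         spec.model_id)
    lp = float(
        stats.norm.logpdf(beta, loc=mu, scale=np.sqrt(sigma2[assay.pmap])).sum()
    )
    total = ll + lp
    if include_hyperpriors:
        total += float(stats.norm.logpdf(phi).sum())
        total += float(stats.norm.logpdf(b, scale=spec.b_sd).sum())
        total += float(stats.invgamma.logpdf(sigma2, 1, scale=1).sum())
        total += float(stats.invgamma.logpdf(eps, 1, scale=1).sum())
        if spec.model_id >= 2:
            total += float(stats.norm.logpdf(params["z"]).sum())
        if spec.model_id == 3:
            total += float(
                stats.beta.logpdf(rho, _RHO_PRIOR_A, _RHO_PRIOR_B).sum()
            )
    return total
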