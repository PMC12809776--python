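"""Interpretive layer: variance decomposition, position summaries, shape
categories and cross-condition comparison.

Variance decomposition asks how much of the spread of variant scores across
a protein is carried by position effects, by (position-scaled) substitution
effects, by their covariance, and by residual local factors.  Shares are
computed from posterior-mean plug-ins over non-synonymous variants, so
``share_position + share_aa + share_cross + share_unexplained`` is close to
one on a self-consistent fit (the posterior-mean score is not exactly the
sum of its posterior-mean components, so the identity is approximate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Assay, SYNONYMOUS
from .model import PosteriorResult, prior_mean_beta


class DegenerateAssayError(ValueError):
    pass


class AlignmentError(ValueError):
    pass


@dataclass
class DecompositionSummary:
    shares: dict
    position_table: pd.DataFrame
    shape_category: str


def _components(result: PosteriorResult, assay: Assay):
    """Posterior-mean score and its position / substitution components for
    non-synonymous variants."""
    nonsyn = (assay.variants["mclass"] != SYNONYMOUS).to_numpy()
    beta = result.mean("beta")[nonsyn]
    phi_v = result.mean("phi")[result.pmap][nonsyn]
    if "nu" in result.draws:
        nu_v = result.mean("nu")[result.amap]
        if "rho" in result.draws:
            aa_v = (nu_v * result.mean("rho")[result.pmap])[nonsyn]
        else:
            aa_v = nu_v[nonsyn]
    else:
        aa_v = np.zeros(beta.size)
    return beta, phi_v, aa_v


def variance_decomposition(result: PosteriorResult, assay: Assay) -> dict:
    """Protein-level variance shares over non-synonymous variants.

    Returns ``share_position``, ``share_aa``, ``share_cross`` (twice the
    covariance between the two components, reported separately so the
    position and substitution shares stay additive) and
    ``share_unexplained``.  Population variances throughout.
    """
    beta, phi_v, aa_v = _components(result, assay)
    total = float(np.var(beta))
    if total < 1e-12:
        raise DegenerateAssayError("variant scores have zero variance")
    cross = 2.0 * float(np.cov(phi_v, aa_v, bias=True)[0, 1])
    return {
        "share_position": float(np.var(phi_v)) / total,
        "share_aa": float(np.var(aa_v)) / total,
        "share_cross": cross / total,
        "share_unexplained": float(np.var(beta - phi_v - aa_v)) / total,
        "total_variance": total,
    }


def position_summary(result: PosteriorResult) -> pd.DataFrame:
    """Per-position posterior means and sds of phi, rho and sigma2."""
    return result.position_table()


def classify_shape(
    position_table: pd.DataFrame,
    shares: dict | None = None,
    tau_phi: float = 0.5,
    tau_aa: float = 0.05,
    share_aa: float | None = None,
) -> str:
    """Classify a protein/domain by its position-effect spread and
    substitution share: ``no_effect``, ``position_only``, ``aa_only`` or
    ``both``.

    ``tau_phi`` thresholds the standard deviation of position effects across
    real positions; ``tau_aa`` thresholds the variance share attributable to
    substitution effects (from ``shares`` or passed directly).
    """
    real = position_table[
        ~position_table["is_control"] & ~position_table["is_pseudo"]
    ]
    spread_phi = float(real["phi_mean"].std(ddof=0))
    if share_aa is None:
        share_aa = float(shares["share_aa"]) if shares else 0.0
    pos_high = spread_phi >= tau_phi
    aa_high = share_aa >= tau_aa
    if pos_high and aa_high:
        return "both"
    if pos_high:
        return "position_only"
    if aa_high:
        return "aa_only"
    return "no_effect"


def decompose(result: PosteriorResult, assay: Assay, **thresholds) -> DecompositionSummary:
    """Full downstream summary of one fit."""
    shares = variance_decomposition(result, assay)
    table = position_summary(result)
    category = classify_shape(table, shares, **thresholds)
    return DecompositionSummary(
        shares=shares, position_table=table, shape_category=category
    )


def compare_conditions(
    results: dict[str, PosteriorResult],
    var_phi_threshold: float = 1.0,
    var_rho_threshold: float = 0.01,
) -> pd.DataFrame:
    """Cross-condition variance of position effects and activation scores.

    ``results`` maps condition name to a fitted model 3 on the same variant
    set.  Per position the population variance across conditions of the
    posterior means of phi and rho is computed and thresholded into
    ``consistent``, ``phi_variable``, ``rho_variable`` or ``both``.
    """
    if len(results) < 2:
        raise ValueError("need at least two conditions to compare")
    items = list(results.items())
    labels = items[0][1].position_labels
    for name, res in items[1:]:
        if res.position_labels != labels:
            raise AlignmentError(
                f"condition {name!r} has a different position map"
            )
    phi = np.stack([res.mean("phi") for _, res in items])
    var_phi = phi.var(axis=0)
    if all("rho" in res.draws for _, res in items):
        rho = np.stack([res.mean("rho") for _, res in items])
        var_rho = rho.var(axis=0)
    else:
        var_rho = np.zeros(len(labels))

    phi_var = var_phi >= var_phi_threshold
    rho_var = var_rho >= var_rho_threshold
    category = np.where(
        phi_var & rho_var, "both",
        np.where(phi_var, "phi_variable",
                 np.where(rho_var, "rho_variable", "consistent")),
    )
    return pd.DataFrame(
        {
            "position": labels,
            "var_phi": var_phi,
            "var_rho": var_rho,
            "category": category,
        }
    )
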