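"""Amino-acid substitution grouping and the weighted sum-to-zero prior.

Missense changes are scored with BLOSUM90 and binned into groups of similar
score so that each group is observed across a minimum fraction of positions.
Group-level effects carry a degenerate Gaussian prior constrained so that the
variant-count-weighted sum of all non-synonymous effects is exactly zero —
the constraint that makes position and substitution effects jointly
identifiable.  The synonymous group's effect is a structural zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import Assay, DELETION, INSERTION, MISSENSE, NONSENSE, SYNONYMOUS


class GroupingError(ValueError):
    pass


class ConstraintError(ValueError):
    pass


_DEFAULT_MATRIX = None


def load_matrix(path: str | None = None):
    """Load a substitution matrix (NCBI text format); default BLOSUM90."""
    global _DEFAULT_MATRIX
    from Bio.Align import substitution_matrices

    if path is None:
        if _DEFAULT_MATRIX is None:
            _DEFAULT_MATRIX = substitution_matrices.load("BLOSUM90")
        return _DEFAULT_MATRIX
    return substitution_matrices.read(path)


def blosum_score(wt: str, mut: str, matrix=None) -> int:
    """Substitution-matrix score of ``wt -> mut`` (symmetric)."""
    matrix = matrix if matrix is not None else load_matrix()
    try:
        return int(matrix[wt, mut])
    except (KeyError, IndexError) as err:
        raise ValueError(f"unknown residue in substitution {wt!r}->{mut!r}") from err


@dataclass
class GroupingScheme:
    """Assignment of variants to substitution groups a(v).

    Groups are ordered: missense score-bins ascending, then nonsense,
    deletion and insertion groups (when present), with the synonymous group
    last at index ``A - 1``.  ``free`` marks groups whose effect is estimated
    (synonymous — and optionally indel — groups are pinned to zero).  ``w``
    holds the mean-normalized variant counts of the free groups, and ``B``
    the factor of the rank-deficient correlation matrix M such that drawing
    ``nu_free = B z / w`` with standard-normal z satisfies
    ``sum(w * nu_free) == 0`` on every draw.
    """

    A: int
    group_labels: list[str]
    group_score_ranges: list[tuple[int, int] | None]
    n_per_group: np.ndarray
    amap: np.ndarray
    free: np.ndarray  # bool per group
    w: np.ndarray = field(default=None)
    B: np.ndarray = field(default=None)

    @property
    def syn_group(self) -> int:
        return self.A - 1

    @property
    def n_free(self) -> int:
        return int(self.free.sum())

    def nu_from_z(self, z: np.ndarray) -> np.ndarray:
        """Map whitened coordinates to the full length-A effect vector.

        ``z`` may be a single vector of length ``n_free - 1`` or a stack of
        draws ``(..., n_free - 1)``.
        """
        z = np.asarray(z)
        nu_free = z @ self.B.T / self.w
        nu = np.zeros(z.shape[:-1] + (self.A,))
        nu[..., self.free] = nu_free
        return nu


def correlation_matrix(k: int) -> np.ndarray:
    """The exchangeable degenerate correlation matrix for k constrained
    effects: ones on the diagonal, ``-1/(k-1)`` off-diagonal, rank ``k-1``
    with null space spanned by the all-ones vector."""
    if k < 2:
        raise ConstraintError("need at least two constrained groups")
    M = np.full((k, k), -1.0 / (k - 1))
    np.fill_diagonal(M, 1.0)
    return M


def build_constraint(w: np.ndarray) -> np.ndarray:
    """Factor B with ``M = B @ B.T`` restricted to positive eigenvalues.

    ``w`` are the mean-normalized counts of the A-1 free groups.  Requires
    A >= 4 so the constrained prior has at least two free dimensions.
    Sampling ``nu = B z / w`` guarantees the weighted sum-to-zero exactly
    (``B.T @ 1 = 0`` because the ones vector is the null eigenvector of M).
    """
    w = np.asarray(w, dtype=float)
    k = w.size  # = A - 1
    if k < 3:
        raise ConstraintError(
            "constrained prior needs at least 3 non-synonymous groups (A >= 4); "
            "use a coarser or finer substitution grouping"
        )
    M = correlation_matrix(k)
    eigval, eigvec = np.linalg.eigh(M)
    positive = eigval > 1e-10
    return eigvec[:, positive] * np.sqrt(eigval[positive])


def compute_weights(n_per_group: np.ndarray) -> np.ndarray:
    """Mean-normalized variant counts: ``w = n / mean(n)`` so mean(w) = 1."""
    n = np.asarray(n_per_group, dtype=float)
    if np.any(n <= 0):
        raise GroupingError("empty substitution group")
    return n / n.mean()


def build_groups(
    assay: Assay,
    min_coverage: float = 0.2,
    matrix=None,
    indel_effects: bool = True,
    coverage_mode: str = "positions",
) -> GroupingScheme:
    """Group observed substitutions by BLOSUM score similarity.

    Distinct observed missense scores (ascending) are greedily merged until
    each bin covers at least ``min_coverage`` of the real position groups
    (``coverage_mode='variants'`` instead requires each bin to hold that
    fraction of missense variants).  Nonsense mutations form one dedicated
    group; deletions and insertions one group each.  With
    ``indel_effects=False`` indel groups are pinned to a zero effect like the
    synonymous group.
    """
    if assay.pmap is None:
        raise ValueError("build_groups requires the position map")
    if coverage_mode not in {"positions", "variants"}:
        raise ValueError(f"unknown coverage_mode {coverage_mode!r}")
    matrix = matrix if matrix is not None else load_matrix()

    mclass = assay.variants["mclass"].to_numpy()
    is_mis = mclass == MISSENSE
    if not (~(mclass == SYNONYMOUS)).any():
        raise GroupingError("no non-synonymous variants to group")

    scores = np.full(assay.n_variants, np.iinfo(np.int32).min, dtype=int)
    for i in np.flatnonzero(is_mis):
        scores[i] = blosum_score(
            assay.variants["wt"].iat[i], assay.variants["mut"].iat[i], matrix
        )

    real_groups = sorted(
        set(range(len(assay.position_labels)))
        - set(assay.pseudo_groups)
        - ({assay.control_group} if assay.control_group is not None else set())
    )
    n_real = max(len(real_groups), 1)
    n_mis = max(int(is_mis.sum()), 1)

    # greedy ascending merge of distinct score levels until covered enough
    levels = np.unique(scores[is_mis]) if is_mis.any() else np.array([], dtype=int)
    bins: list[list[int]] = []
    current: list[int] = []

    def _covered(level_set: list[int]) -> float:
        members = is_mis & np.isin(scores, level_set)
        if coverage_mode == "variants":
            return members.sum() / n_mis
        return len(set(assay.pmap[members])) / n_real

    for level in levels:
        current.append(int(level))
        if _covered(current) >= min_coverage:
            bins.append(current)
            current = []
    if current:
        if bins:
            bins[-1].extend(current)  # trailing undersized bin merges backward
        else:
            bins.append(current)

    group_labels: list[str] = []
    group_ranges: list[tuple[int, int] | None] = []
    amap = np.full(assay.n_variants, -1, dtype=int)
    free: list[bool] = []

    for level_set in bins:
        idx = len(group_labels)
        lo, hi = level_set[0], level_set[-1]
        group_labels.append(f"blosum[{lo}]" if lo == hi else f"blosum[{lo},{hi}]")
        group_ranges.append((lo, hi))
        amap[is_mis & np.isin(scores, level_set)] = idx
        free.append(True)

    for cls, label, is_free in (
        (NONSENSE, "nonsense", True),
        (DELETION, "del", indel_effects),
        (INSERTION, "ins", indel_effects),
    ):
        members = mclass == cls
        if members.any():
            idx = len(group_labels)
            group_labels.append(label)
            group_ranges.append(None)
            amap[members] = idx
            free.append(is_free)

    syn_idx = len(group_labels)
    group_labels.append("syn")
    group_ranges.append(None)
    amap[mclass == SYNONYMOUS] = syn_idx
    free.append(False)

    A = len(group_labels)
    n_per_group = np.bincount(amap, minlength=A)
    free_arr = np.array(free)
    scheme = GroupingScheme(
        A=A,
        group_labels=group_labels,
        group_score_ranges=group_ranges,
        n_per_group=n_per_group,
        amap=amap,
        free=free_arr,
    )
    scheme.w = compute_weights(n_per_group[free_arr])
    scheme.B = build_constraint(scheme.w)
    return scheme
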