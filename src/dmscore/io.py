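"""Reading and writing deep mutational scanning count tables.

A screen is a table with one row per variant and one raw sequencing count per
(selection round, replicate) pair.  Variants are written in a compact
HGVS-like shorthand ``<WT><POS><MUT>`` where ``MUT`` is a one-letter amino
acid code, ``=`` (synonymous), ``*`` (nonsense), ``del`` or ``ins``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AA_CODES = "ACDEFGHIKLMNPQRSTVWY"

#: mutation classes
SYNONYMOUS = "synonymous"
MISSENSE = "missense"
DELETION = "deletion"
INSERTION = "insertion"
NONSENSE = "nonsense"

_VARIANT_RE = re.compile(r"^([A-Z]?)(\d+)(=|del|ins|\*|[A-Z])$")


class VariantParseError(ValueError):
    """Raised when a variant descriptor does not match the grammar."""


class SchemaError(ValueError):
    """Raised when a count table violates the expected column layout."""


@dataclass
class VariantRecord:
    """A single mutation and its count trajectory.

    ``counts`` is indexed (round ``t`` in ``0..T``, replicate ``r`` in
    ``1..R``); ``NaN`` marks a missing observation.
    """

    variant_id: str
    wt: str
    position: int
    mut: str
    mclass: str
    counts: np.ndarray | None = None


def parse_variant(descriptor: str) -> VariantRecord:
    """Parse a ``<WT><POS><MUT>`` descriptor.

    ``A123V`` is a missense change, ``A123=`` (or ``A123A``) synonymous,
    ``A123*`` nonsense, ``G77del`` a single-residue deletion and ``77ins`` /
    ``G77ins`` an insertion after the position.  Multi-residue descriptors
    (e.g. ``A5V;K9R``) are rejected.
    """
    descriptor = descriptor.strip()
    match = _VARIANT_RE.match(descriptor)
    if match is None:
        raise VariantParseError(
            f"variant descriptor {descriptor!r} does not match <WT><POS><MUT> "
            "with MUT a one-letter amino acid code, '=', '*', 'del' or 'ins'"
        )
    wt, pos_str, mut = match.groups()
    position = int(pos_str)
    if position < 1:
        raise VariantParseError(
            f"variant descriptor {descriptor!r}: position must be >= 1"
        )
    if wt == "" and mut != "ins":
        raise VariantParseError(
            f"variant descriptor {descriptor!r}: wild-type residue required "
            "for non-insertion variants"
        )
    if wt and wt not in AA_CODES:
        raise VariantParseError(
            f"variant descriptor {descriptor!r}: unknown wild-type residue {wt!r}"
        )
    if mut in AA_CODES:
        mclass = SYNONYMOUS if mut == wt else MISSENSE
    elif mut == "=":
        mut = "syn"
        mclass = SYNONYMOUS
    elif mut == "*":
        mut = "ter"
        mclass = NONSENSE
    elif mut == "del":
        mclass = DELETION
    else:  # ins
        mclass = INSERTION
    return VariantRecord(
        variant_id=descriptor, wt=wt, position=position, mut=mut, mclass=mclass
    )


@dataclass
class Assay:
    """A validated growth screen.

    Attributes
    ----------
    variants : pandas.DataFrame
        One row per retained variant with columns ``variant_id``, ``wt``,
        ``position``, ``mut``, ``mclass``.
    counts : numpy.ndarray
        Raw counts of shape ``(V, T + 1, R)``; ``NaN`` marks missing cells.
    m : numpy.ndarray or None
        Aligned (normalized log) counts, same shape; filled by preprocessing.
    pmap : numpy.ndarray or None
        Per-variant position-group index ``p(v)``.  All synonymous variants
        share one virtual control group; indels live on pseudo-positions.
    amap, gmap : numpy.ndarray or None
        Substitution-group index ``a(v)`` and mean-group index ``g(v)``.
    """

    variants: pd.DataFrame
    counts: np.ndarray
    T: int
    R: int
    m: np.ndarray | None = None
    pmap: np.ndarray | None = None
    position_labels: list[str] | None = None
    control_group: int | None = None
    pseudo_groups: list[int] = field(default_factory=list)
    amap: np.ndarray | None = None
    gmap: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_position_groups(self) -> int:
        if self.pmap is None:
            raise ValueError("position map not built yet")
        return len(self.position_labels)

    def copy(self) -> "Assay":
        return Assay(
            variants=self.variants.copy(),
            counts=self.counts.copy(),
            T=self.T,
            R=self.R,
            m=None if self.m is None else self.m.copy(),
            pmap=None if self.pmap is None else self.pmap.copy(),
            position_labels=None
            if self.position_labels is None
            else list(self.position_labels),
            control_group=self.control_group,
            pseudo_groups=list(self.pseudo_groups),
            amap=None if self.amap is None else self.amap.copy(),
            gmap=None if self.gmap is None else self.gmap.copy(),
            meta=dict(self.meta),
        )

    def subset(self, index: np.ndarray) -> "Assay":
        """Row-subset the assay (mappings are invalidated, not sliced)."""
        index = np.asarray(index)
        return Assay(
            variants=self.variants.iloc[index].reset_index(drop=True),
            counts=self.counts[index],
            T=self.T,
            R=self.R,
            m=None if self.m is None else self.m[index],
            meta=dict(self.meta),
        )


@dataclass
class CountTableFormat:
    """Column layout of a count table.

    Wide layout (canonical): one count column per (round, replicate) named by
    ``count_pattern``, default ``c_<round>_<replicate>``.  Long layout: one
    row per (variant, round, replicate) with ``round``/``replicate``/``count``
    columns.
    """

    variant_col: str = "variant"
    layout: str = "wide"
    count_pattern: str = r"^c_(\d+)_(\d+)$"
    round_col: str = "round"
    replicate_col: str = "replicate"
    count_col: str = "count"


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    return pd.read_csv(path, sep=sep)


def read_counts(path: str | Path, fmt: CountTableFormat | None = None) -> Assay:
    """Read a raw count table into an :class:`Assay`.

    Variants carrying more than one mutation event (descriptors joined by
    ``;``) are dropped with a logged count.  The (round, replicate) grid must
    be complete; negative counts are rejected.
    """
    fmt = fmt or CountTableFormat()
    table = _read_table(path)
    return assay_from_frame(table, fmt)


def assay_from_frame(table: pd.DataFrame, fmt: CountTableFormat | None = None) -> Assay:
    """Build an :class:`Assay` from an in-memory count table."""
    fmt = fmt or CountTableFormat()
    if table.empty:
        raise SchemaError("count table is empty")
    if fmt.variant_col not in table.columns:
        raise SchemaError(f"missing variant column {fmt.variant_col!r}")

    if fmt.layout == "long":
        order = table[fmt.variant_col].drop_duplicates()
        table = table.pivot_table(
            index=fmt.variant_col,
            columns=[fmt.round_col, fmt.replicate_col],
            values=fmt.count_col,
            aggfunc="first",
        ).reindex(order)
        table.columns = [f"c_{t}_{r}" for t, r in table.columns]
        table = table.reset_index()
        fmt = replace(fmt, layout="wide", count_pattern=r"^c_(\d+)_(\d+)$")

    pattern = re.compile(fmt.count_pattern)
    cells = {}
    for col in table.columns:
        match = pattern.match(str(col))
        if match:
            cells[(int(match.group(1)), int(match.group(2)))] = col
    if not cells:
        raise SchemaError("no count columns matched the count pattern")
    rounds = sorted({t for t, _ in cells})
    reps = sorted({r for _, r in cells})
    if rounds != list(range(rounds[-1] + 1)) or rounds[0] != 0:
        raise SchemaError(f"selection rounds must be contiguous from 0, got {rounds}")
    missing_cols = [(t, r) for t in rounds for r in reps if (t, r) not in cells]
    if missing_cols:
        raise SchemaError(
            f"incomplete (round, replicate) grid; missing columns for {missing_cols}"
        )

    T = rounds[-1]
    R = len(reps)
    records = []
    keep_rows = []
    n_dropped = 0
    for i, descriptor in enumerate(table[fmt.variant_col].astype(str)):
        if ";" in descriptor or "," in descriptor:
            n_dropped += 1
            continue
        records.append(parse_variant(descriptor))
        keep_rows.append(i)
    if n_dropped:
        logger.info("dropped %d variants with high-order mutations", n_dropped)
    if not records:
        raise SchemaError("no single-mutation variants in table")

    counts = np.full((len(records), T + 1, R), np.nan)
    for j, t in enumerate(rounds):
        for k, r in enumerate(reps):
            counts[:, j, k] = pd.to_numeric(
                table[cells[(t, r)]].iloc[keep_rows], errors="coerce"
            ).to_numpy()
    if np.nanmin(counts) < 0:
        raise ValueError("negative counts are not allowed")

    variants = pd.DataFrame(
        {
            "variant_id": [v.variant_id for v in records],
            "wt": [v.wt for v in records],
            "position": [v.position for v in records],
            "mut": [v.mut for v in records],
            "mclass": [v.mclass for v in records],
        }
    )
    return Assay(
        variants=variants,
        counts=counts,
        T=T,
        R=R,
        meta={"n_dropped_high_order": n_dropped},
    )


def write_counts(assay: Assay, path: str | Path) -> None:
    """Write raw counts back to a wide CSV (inverse of :func:`read_counts`)."""
    table = assay.variants[["variant_id"]].rename(columns={"variant_id": "variant"})
    for t in range(assay.T + 1):
        for r in range(assay.R):
            table[f"c_{t}_{r + 1}"] = assay.counts[:, t, r]
    table.to_csv(path, index=False)


def write_outputs(result, summary, outdir: str | Path, draws: bool = False) -> dict:
    """Write score, position and decomposition tables to ``outdir``.

    Parameters
    ----------
    result : PosteriorResult
        A fitted model.
    summary : DecompositionSummary or None
        Optional downstream decomposition to write alongside the scores.
    draws : bool
        Also archive raw posterior draws as a compressed ``.npz``.

    Returns the mapping of logical names to written paths.
    """
    if result is None or not getattr(result, "draws", None):
        raise ValueError("write_outputs requires a fitted PosteriorResult")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    scores = result.score_table()
    paths["scores"] = outdir / "scores.csv"
    scores.to_csv(paths["scores"], index=False)

    positions = result.position_table()
    paths["positions"] = outdir / "positions.csv"
    positions.to_csv(paths["positions"], index=False)

    if summary is not None:
        paths["decomposition"] = outdir / "decomposition.csv"
        pd.DataFrame([summary.shares]).to_csv(paths["decomposition"], index=False)

    if draws:
        paths["draws"] = outdir / "draws.npz"
        np.savez_compressed(paths["draws"], **result.draws)
    return paths
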