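"""Gene-level loss-of-function constraint records and classification.

Population sequencing aggregates report, for every canonical transcript, the
number of distinct predicted loss-of-function (pLoF) variants actually observed
together with the number expected under a neutral mutational model.  The ratio
of the two (the observed/expected ratio, here ``loe``) and the bounds of its
90% confidence interval (``loelf``/``loeuf``) summarise how strongly purifying
selection has depleted LoF variation in the gene.  This module houses the
record type for one gene, the four-level classification scheme built on the
conventional LOEUF < 0.35 threshold, and the exact Poisson confidence bounds
used when constraint tables are synthesised rather than downloaded.
"""

from __future__ import annotations

import enum
import io
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import stats

log = logging.getLogger(__name__)

#: Conventional LOEUF cut-off below which a gene is called constrained.
DEFAULT_THRESHOLD = 0.35

#: Canonical column order of an in-memory constraint table.
CONSTRAINT_COLUMNS = [
    "gene_symbol",
    "transcript_id",
    "cds_length",
    "obs_lof",
    "exp_lof",
    "loe",
    "loelf",
    "loeuf",
    "obs_mis",
    "exp_mis",
    "moe",
    "moelf",
    "moeuf",
    "lof_metrics_defined",
]

_REQUIRED_COLUMNS = ["gene_symbol", "cds_length", "obs_lof", "exp_lof"]


class ConstraintLevel(str, enum.Enum):
    """Four-level LoF constraint call, plus UNDEFINED for non-coding genes.

    The levels are ordered from strongest to weakest evidence of constraint;
    :attr:`rank` exposes that ordering (0 = most constrained).
    """

    CONSTRAINED = "constrained"
    LIKELY_CONSTRAINED = "likely_constrained"
    LIKELY_NOT_CONSTRAINED = "likely_not_constrained"
    NOT_CONSTRAINED = "not_constrained"
    UNDEFINED = "undefined"

    @property
    def rank(self) -> int:
        return _LEVEL_RANK[self]


_LEVEL_RANK = {
    ConstraintLevel.CONSTRAINED: 0,
    ConstraintLevel.LIKELY_CONSTRAINED: 1,
    ConstraintLevel.LIKELY_NOT_CONSTRAINED: 2,
    ConstraintLevel.NOT_CONSTRAINED: 3,
    ConstraintLevel.UNDEFINED: 4,
}


@dataclass
class GeneConstraintRecord:
    """Observed/expected LoF and missense variant counts for one gene.

    ``loe`` is ``obs_lof / exp_lof``; ``loelf``/``loeuf`` are the lower and
    upper bounds of its 90% confidence interval.  ``moe``/``moelf``/``moeuf``
    are the missense analogues.  ``lof_metrics_defined`` is False for genes
    (e.g. non-coding RNA genes such as *RMRP*) where no LoF expectation can be
    computed; such records classify as UNDEFINED and are excluded from group
    statistics.
    """

    gene_symbol: str
    transcript_id: str = ""
    cds_length: int = 0
    obs_lof: float = np.nan
    exp_lof: float = np.nan
    loe: float = np.nan
    loelf: float = np.nan
    loeuf: float = np.nan
    obs_mis: float = np.nan
    exp_mis: float = np.nan
    moe: float = np.nan
    moelf: float = np.nan
    moeuf: float = np.nan
    lof_metrics_defined: bool = True

    @classmethod
    def from_series(cls, row: pd.Series) -> "GeneConstraintRecord":
        kwargs = {k: row[k] for k in CONSTRAINT_COLUMNS if k in row.index}
        return cls(**kwargs)


def classify_oe(
    oe: float, lower: float, upper: float, threshold: float = DEFAULT_THRESHOLD
) -> ConstraintLevel:
    """Classify one observed/expected ratio given its CI bounds.

    The decision cascade uses strict inequalities throughout, so a gene
    sitting exactly on the threshold falls to the less-constrained side:

    * upper bound below threshold        -> CONSTRAINED
    * point ratio below threshold        -> LIKELY_CONSTRAINED
    * lower bound above threshold        -> NOT_CONSTRAINED
    * otherwise                          -> LIKELY_NOT_CONSTRAINED

    NaN in any input yields UNDEFINED (logged, never raised).
    """
    if any(x is None or (isinstance(x, float) and np.isnan(x)) for x in (oe, lower, upper)):
        log.warning("undefined o/e metrics (oe=%s, lower=%s, upper=%s)", oe, lower, upper)
        return ConstraintLevel.UNDEFINED
    if upper < threshold:
        return ConstraintLevel.CONSTRAINED
    if oe < threshold:
        return ConstraintLevel.LIKELY_CONSTRAINED
    if lower > threshold:
        return ConstraintLevel.NOT_CONSTRAINED
    return ConstraintLevel.LIKELY_NOT_CONSTRAINED


def classify_constraint(
    record: GeneConstraintRecord,
    threshold: float = DEFAULT_THRESHOLD,
    kind: str = "lof",
) -> ConstraintLevel:
    """Classify one gene record on its LoF (default) or missense metrics."""
    if kind == "lof":
        if not record.lof_metrics_defined:
            return ConstraintLevel.UNDEFINED
        return classify_oe(record.loe, record.loelf, record.loeuf, threshold)
    if kind == "mis":
        return classify_oe(record.moe, record.moelf, record.moeuf, threshold)
    raise ValueError(f"kind must be 'lof' or 'mis', got {kind!r}")


def classify_frame(
    table: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD, kind: str = "lof"
) -> pd.Series:
    """Vectorised :func:`classify_constraint` over a constraint table.

    Returns a Series of :class:`ConstraintLevel` values aligned to the input.
    """
    if kind == "lof":
        oe, lo, up = table["loe"], table["loelf"], table["loeuf"]
        defined = table.get("lof_metrics_defined", pd.Series(True, index=table.index))
    elif kind == "mis":
        oe, lo, up = table["moe"], table["moelf"], table["moeuf"]
        defined = pd.Series(True, index=table.index)
    else:
        raise ValueError(f"kind must be 'lof' or 'mis', got {kind!r}")

    ok = defined.astype(bool) & oe.notna() & lo.notna() & up.notna()
    n_undef = int((~ok).sum())
    if n_undef:
        log.warning("%d gene(s) without defined %s metrics -> UNDEFINED", n_undef, kind)
    conditions = [
        ok & (up < threshold),
        ok & (oe < threshold),
        ok & (lo > threshold),
        ok,
    ]
    choices = [
        ConstraintLevel.CONSTRAINED,
        ConstraintLevel.LIKELY_CONSTRAINED,
        ConstraintLevel.NOT_CONSTRAINED,
        ConstraintLevel.LIKELY_NOT_CONSTRAINED,
    ]
    out = np.select(
        conditions, [lv.value for lv in choices], default=ConstraintLevel.UNDEFINED.value
    )
    return pd.Series(out, index=table.index, name=f"constraint_level_{kind}").map(ConstraintLevel)


def oe_confidence_bounds(obs, exp, ci_level: float = 0.90):
    """Exact (Garwood) Poisson confidence bounds for an observed/expected ratio.

    For an observed count ``obs`` with expectation ``exp`` under a Poisson
    model, the two-sided ``ci_level`` interval for the rate ratio is::

        lower = gamma.ppf(alpha/2, obs) / exp          (0 when obs == 0)
        upper = gamma.ppf(1 - alpha/2, obs + 1) / exp

    with ``alpha = 1 - ci_level``.  Both arguments may be scalars or arrays.
    Exact intervals are conservative: realised coverage exceeds the nominal
    level, approaching it as the expected count grows.

    Raises
    ------
    ValueError
        If any ``exp`` is not strictly positive (the ratio is undefined).
    """
    obs_arr = np.asarray(obs, dtype=float)
    exp_arr = np.asarray(exp, dtype=float)
    if np.any(exp_arr <= 0) or np.any(~np.isfinite(exp_arr)):
        raise ValueError("exp must be strictly positive and finite")
    if np.any(obs_arr < 0):
        raise ValueError("obs must be non-negative")
    alpha = 1.0 - ci_level
    with np.errstate(invalid="ignore"):
        lower = np.where(
            obs_arr > 0,
            stats.gamma.ppf(alpha / 2, np.maximum(obs_arr, 1e-300)) / exp_arr,
            0.0,
        )
    upper = stats.gamma.ppf(1 - alpha / 2, obs_arr + 1) / exp_arr
    if np.isscalar(obs) and np.isscalar(exp):
        return float(lower), float(upper)
    return lower, upper


# ---------------------------------------------------------------------------
# table I/O

def _load_packaged_yaml(name: str) -> dict:
    with resources.files("constraintscope.data").joinpath(name).open() as fh:
        return yaml.safe_load(fh)


def get_column_map(dialect) -> Mapping[str, str]:
    """Resolve a reader dialect to a {canonical: source-column} mapping.

    ``dialect`` may be a mapping (used as-is) or the name of a packaged
    dialect: ``"synthetic"`` (this package's own column names, identity map)
    or ``"gnomad"`` (the public gnomAD v2.1.1 per-gene LoF metrics file).
    """
    if isinstance(dialect, Mapping):
        return dict(dialect)
    maps = _load_packaged_yaml("column_maps.yaml")
    try:
        return maps[dialect]
    except KeyError:
        raise ValueError(f"unknown dialect {dialect!r}; known: {sorted(maps)}") from None


def _sniff_sep(path) -> str:
    if hasattr(path, "readline"):
        first = path.readline()
        path.seek(0)
    else:
        with open(path) as fh:
            first = fh.readline()
    return "\t" if "\t" in first else ","


def read_constraint_table(path, dialect="synthetic") -> pd.DataFrame:
    """Read a per-gene constraint metrics table into the canonical schema.

    One row per canonical transcript is kept: rows flagged non-canonical are
    dropped, and duplicate gene symbols are resolved in favour of the
    canonical row (ties broken by highest expected LoF count).  Missing
    ratio/bound columns are recomputed from the observed and expected counts
    (ratio directly, bounds as exact Poisson intervals).  Unparseable numeric
    cells become NaN with a logged warning and leave the record's metrics
    undefined rather than failing the whole read.
    """
    colmap = get_column_map(dialect)
    table = pd.read_csv(path, sep=_sniff_sep(path), low_memory=False)

    rename = {src: canon for canon, src in colmap.items() if src in table.columns}
    table = table.rename(columns=rename)

    missing = [c for c in _REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"constraint table {path} is missing required columns: {missing}")

    if "canonical" in table.columns:
        canonical = table["canonical"].map(_truthy)
        dropped = int((~canonical).sum())
        if dropped:
            log.info("dropping %d non-canonical transcript row(s)", dropped)
        table = table[canonical]

    numeric = [c for c in CONSTRAINT_COLUMNS if c not in ("gene_symbol", "transcript_id", "lof_metrics_defined")]
    for col in numeric:
        if col in table.columns:
            coerced = pd.to_numeric(table[col], errors="coerce")
            bad = coerced.isna() & table[col].notna()
            if bad.any():
                log.warning("%d unparseable value(s) in column %r -> NaN", int(bad.sum()), col)
            table[col] = coerced

    # recompute ratio and bounds when the source table omits them
    with np.errstate(divide="ignore", invalid="ignore"):
        if "loe" not in table.columns:
            table["loe"] = table["obs_lof"] / table["exp_lof"]
        if "loelf" not in table.columns or "loeuf" not in table.columns:
            ok = table["exp_lof"] > 0
            lo = np.full(len(table), np.nan)
            up = np.full(len(table), np.nan)
            if ok.any():
                lo[ok.to_numpy()], up[ok.to_numpy()] = oe_confidence_bounds(
                    table.loc[ok, "obs_lof"].to_numpy(), table.loc[ok, "exp_lof"].to_numpy()
                )
            table["loelf"], table["loeuf"] = lo, up
        if "moe" not in table.columns and {"obs_mis", "exp_mis"} <= set(table.columns):
            table["moe"] = table["obs_mis"] / table["exp_mis"]

    for col in CONSTRAINT_COLUMNS:
        if col not in table.columns:
            table[col] = "" if col in ("transcript_id",) else np.nan

    table["lof_metrics_defined"] = (
        table["loe"].notna() & table["loelf"].notna() & table["loeuf"].notna()
    )

    # canonical row per gene symbol: all remaining rows are canonical, so a
    # duplicate symbol is resolved by the better-supported (higher exp_lof) row
    table = table.sort_values(["gene_symbol", "exp_lof"], ascending=[True, False])
    table = table.drop_duplicates("gene_symbol", keep="first")

    return table[CONSTRAINT_COLUMNS].reset_index(drop=True)


def _truthy(v) -> bool:
    if isinstance(v, str):
        return v.strip().lower() in ("true", "t", "1", "yes")
    return bool(v)


def write_classified_table(table: pd.DataFrame, path, threshold: float = DEFAULT_THRESHOLD) -> pd.DataFrame:
    """Append a ``constraint_level`` column and write the table as TSV."""
    out = table.copy()
    levels = classify_frame(out, threshold=threshold)
    out["constraint_level"] = [lv.value for lv in levels]
    out.to_csv(path, sep="\t", index=False)
    return out


# ---------------------------------------------------------------------------
# curated gene annotations

ANNOTATION_COLUMNS = [
    "gene_symbol",
    "category",
    "moi",
    "mechanism",
    "cancer_only",
    "penetrance_class",
    "de_novo_class",
]

MOI_VALUES = ("AD", "AR", "XLR")
MECHANISM_VALUES = ("LoF", "GoF", "unknown")
CLASS_VALUES = ("very_low", "low", "high", "very_high", "unknown")


def read_annotation_table(path) -> pd.DataFrame:
    """Read a curated per-gene annotation table (CSV or TSV).

    Expected columns: gene,category,moi,mechanism,cancer_only,
    penetrance_class,de_novo_class.  ``gene`` is renamed to ``gene_symbol``.
    """
    table = pd.read_csv(path, sep=_sniff_sep(path), comment="#")
    table = table.rename(columns={"gene": "gene_symbol"})
    missing = [c for c in ANNOTATION_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"annotation table {path} is missing columns: {missing}")
    table["cancer_only"] = table["cancer_only"].map(_truthy)
    for col, allowed in [
        ("moi", MOI_VALUES),
        ("mechanism", MECHANISM_VALUES),
        ("penetrance_class", CLASS_VALUES),
        ("de_novo_class", CLASS_VALUES),
    ]:
        bad = ~table[col].isin(allowed)
        if bad.any():
            raise ValueError(f"annotation column {col!r} has invalid values: {sorted(table.loc[bad, col].unique())}")
    return table[ANNOTATION_COLUMNS]


def load_pcps_panel() -> pd.DataFrame:
    """Load the packaged 85-gene pediatric CPS panel annotation fixture.

    This is a synthetic stand-in for the curated Category-1 panel: the gene
    symbols and mode-of-inheritance/mechanism labels follow the published
    partition (59 autosomal dominant of which 9 act through gain of function,
    23 autosomal recessive, 3 X-linked recessive) but the table itself is
    assembled for testing, not a redistribution of the curated source.
    """
    ref = resources.files("constraintscope.data").joinpath("pcps_panel_synthetic.csv")
    with ref.open() as fh:
        return read_annotation_table(io.StringIO(fh.read()))


def read_annotation(path_or_none=None) -> pd.DataFrame:
    """Annotation table from ``path`` or the packaged panel when None."""
    if path_or_none is None:
        return load_pcps_panel()
    return read_annotation_table(Path(path_or_none))
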