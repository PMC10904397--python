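"""Size-matched comparison universes and group-level constraint contrasts.

Constraint confidence depends on gene size: long coding sequences accumulate
more expected LoF variants and therefore tighter observed/expected intervals.
Group comparisons against "the rest of the exome" are confounded by this, so
a target gene set is compared against a size-matched universe: targets are
ordered by CDS length and cut into nine equal-count bins, every universe gene
falling inside a bin's length range becomes a candidate for that bin, and an
equal number of candidates is sampled per bin — the largest subset satisfying
(1) each gene appears once and (2) all bins are equally sized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

from .constraint_core import ConstraintLevel, classify_frame
from .stat_engine import mann_whitney_u

log = logging.getLogger(__name__)

#: Group labels used in the census and burden tables.
GROUP_AD_LOF_XLR = "AD(LoF)/XLR"
GROUP_AR = "AR"
GROUP_AD_GOF = "AD(GoF)"


@dataclass
class SizeMatchedSubset:
    """A size-matched random gene subset with its binning evidence."""

    bins: list  # (low, high) CDS-length interval per bin, closed both ends
    members: list  # gene symbols, concatenated over bins
    member_bins: np.ndarray  # bin index of each member
    per_bin_count: int
    seed: int

    def validate(self, universe: pd.DataFrame) -> None:
        """Re-check the construction invariants against the universe table."""
        if len(set(self.members)) != len(self.members):
            raise AssertionError("duplicate genes in size-matched subset")
        lengths = universe.set_index("gene_symbol").loc[self.members, "cds_length"]
        for gene, length, b in zip(self.members, lengths, self.member_bins):
            lo, hi = self.bins[b]
            if not (lo <= length <= hi):
                raise AssertionError(f"{gene}: CDS length {length} outside bin {b} [{lo}, {hi}]")
        counts = np.bincount(self.member_bins, minlength=len(self.bins))
        if not (counts == self.per_bin_count).all():
            raise AssertionError(f"unequal bin counts: {counts.tolist()}")


def build_size_matched_subset(
    target_genes: pd.DataFrame,
    universe: pd.DataFrame,
    n_bins: int = 9,
    seed: int = 0,
) -> SizeMatchedSubset:
    """Sample the maximum equal-per-bin size-matched subset of the universe.

    Targets are sorted by CDS length and split into ``n_bins`` contiguous
    groups of (as near as possible) equal count, any remainder going to the
    smallest-length bins first.  Each bin's interval is the closed range of
    its targets' CDS lengths.  A universe gene is a candidate for the
    lowest-index bin whose interval contains its length; ``per_bin_count`` is
    the smallest candidate pool over bins and that many genes are drawn
    uniformly without replacement from every bin.  Target genes are *not*
    excluded from the universe.

    Raises
    ------
    ValueError
        If a bin interval contains no universe gene.
    """
    if len(target_genes) < n_bins:
        raise ValueError(f"need at least n_bins={n_bins} target genes, got {len(target_genes)}")
    lengths = target_genes.sort_values("cds_length")["cds_length"].to_numpy()
    groups = np.array_split(lengths, n_bins)  # remainder to the earliest bins
    bins = [(float(g.min()), float(g.max())) for g in groups]

    uni_len = universe["cds_length"].to_numpy(dtype=float)
    assigned = np.full(len(universe), -1)
    for i, (lo, hi) in enumerate(bins):
        eligible = (assigned == -1) & (uni_len >= lo) & (uni_len <= hi)
        assigned[eligible] = i

    counts = np.bincount(assigned[assigned >= 0], minlength=n_bins)
    empty = [i for i, c in enumerate(counts) if c == 0]
    if empty:
        ivals = ", ".join(f"bin {i} [{bins[i][0]:g}, {bins[i][1]:g}] bp" for i in empty)
        raise ValueError(f"no universe genes fall in: {ivals}")
    per_bin = int(counts.min())

    rng = np.random.default_rng(seed)
    symbols = universe["gene_symbol"].to_numpy()
    members: list[str] = []
    member_bins: list[int] = []
    for i in range(n_bins):
        pool = symbols[assigned == i]
        take = rng.choice(len(pool), size=per_bin, replace=False)
        members.extend(pool[np.sort(take)])
        member_bins.extend([i] * per_bin)

    subset = SizeMatchedSubset(
        bins=bins,
        members=members,
        member_bins=np.asarray(member_bins),
        per_bin_count=per_bin,
        seed=int(seed),
    )
    subset.validate(universe)
    return subset


@dataclass
class GeneSetComparison:
    """Two-group summary of one constraint metric."""

    metric: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    u: float
    p: float
    ks_distance: float
    levels_a: dict = field(default_factory=dict)
    levels_b: dict = field(default_factory=dict)

    def summary(self) -> str:
        return (
            f"{self.metric}: mean {self.mean_a:.2%} vs. {self.mean_b:.2%} "
            f"(n = {self.n_a} vs. {self.n_b}), Mann-Whitney U = {self.u:.4g}, "
            f"p = {self.p:.4g}"
        )

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "n": [self.n_a, self.n_b],
            "mean": [self.mean_a, self.mean_b],
            "u": self.u,
            "p": self.p,
            "ks_distance": self.ks_distance,
            "levels": [self.levels_a, self.levels_b],
        }


def _level_counts(table: pd.DataFrame) -> dict:
    levels = classify_frame(table)
    return {lv.value: int((levels == lv).sum()) for lv in ConstraintLevel}


def compare_gene_sets(set_a: pd.DataFrame, set_b: pd.DataFrame, metric: str = "loeuf") -> GeneSetComparison:
    """Mann-Whitney comparison of a constraint metric between two gene sets.

    ``metric`` is one of loeuf, moeuf, loe, cds_length.  Genes with an
    undefined metric are excluded; an entirely undefined set is an error.
    LoF constraint-level counts per set are included in the result, as is the
    two-sample Kolmogorov-Smirnov distance (descriptive only — the published
    size-matching check is the Mann-Whitney test).
    """
    if metric not in ("loeuf", "moeuf", "loe", "cds_length"):
        raise ValueError(f"unsupported metric {metric!r}")
    a = set_a[set_a[metric].notna()]
    b = set_b[set_b[metric].notna()]
    if a.empty or b.empty:
        raise ValueError(f"metric {metric!r} undefined for all members of one set")
    va, vb = a[metric].to_numpy(float), b[metric].to_numpy(float)
    u, p = mann_whitney_u(va, vb)
    ks = float(_scipy_stats.ks_2samp(va, vb).statistic) if (va.size and vb.size) else np.nan
    return GeneSetComparison(
        metric=metric,
        n_a=len(a),
        n_b=len(b),
        mean_a=float(va.mean()),
        mean_b=float(vb.mean()),
        u=u,
        p=p,
        ks_distance=ks,
        levels_a=_level_counts(a),
        levels_b=_level_counts(b),
    )


def annotation_groups(annotations: pd.DataFrame) -> pd.Series:
    """Map curated annotations to the three analysis groups.

    Monoallelic-risk genes driven by loss of function (autosomal dominant
    LoF/unknown mechanism, plus X-linked recessive) form one group;
    biallelic-risk (AR) genes and gain-of-function AD genes are kept apart
    because LoF constraint is only expected where a single LoF allele
    already carries the phenotype.
    """
    moi = annotations["moi"]
    mech = annotations["mechanism"]
    group = np.where(
        (moi == "AR"),
        GROUP_AR,
        np.where((moi == "AD") & (mech == "GoF"), GROUP_AD_GOF, GROUP_AD_LOF_XLR),
    )
    return pd.Series(group, index=annotations.index, name="group")


def constraint_level_census(
    constraint: pd.DataFrame,
    annotations: pd.DataFrame,
    threshold: float = 0.35,
) -> pd.DataFrame:
    """Cross-tabulate analysis group x LoF constraint level for a panel.

    Annotated genes missing from the constraint table are excluded with a
    warning; genes without defined LoF metrics are counted under
    ``undefined`` so that rows conserve panel sizes.
    """
    ann = annotations.copy()
    ann["group"] = annotation_groups(ann)
    merged = ann.merge(constraint, on="gene_symbol", how="left", indicator=True)
    absent = merged["_merge"] == "left_only"
    if absent.any():
        log.warning(
            "%d annotated gene(s) missing from the constraint table: %s",
            int(absent.sum()),
            ", ".join(merged.loc[absent, "gene_symbol"]),
        )
        # genes absent from the metrics file still count, as undefined
        for col in ("loe", "loelf", "loeuf"):
            merged[col] = merged.get(col, np.nan)
    merged["level"] = [lv.value for lv in classify_frame(merged, threshold=threshold)]
    order = [lv.value for lv in ConstraintLevel]
    census = (
        merged.groupby(["group", "level"]).size().unstack(fill_value=0).reindex(columns=order, fill_value=0)
    )
    census.index.name = "group"
    return census


def census_contingency(census: pd.DataFrame, group_a: str, group_b: str) -> tuple[int, int, int, int]:
    """2x2 table (constrained vs. not) for two census rows, ready for the exact test."""
    const_a = int(census.loc[group_a, ConstraintLevel.CONSTRAINED.value])
    const_b = int(census.loc[group_b, ConstraintLevel.CONSTRAINED.value])
    tot_a = int(census.loc[group_a].sum())
    tot_b = int(census.loc[group_b].sum())
    return const_a, tot_a - const_a, const_b, tot_b - const_b
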