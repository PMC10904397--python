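"""Distinct-LoF-variant accumulation curves under nested downsampling.

Population reference datasets publish, for each gene, the number of distinct
LoF variants observed (and expected) at a fixed ladder of cohort sizes.  To
compare a case cohort against that ladder, patients are subsampled *nested*:
the full cohort is sampled down to the largest applicable step, that sample
down to the next step, and so on — so every smaller sample is a subset of
the larger one and the resulting curve is monotone by construction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.special import gammaln

log = logging.getLogger(__name__)


def canonical_steps() -> list[int]:
    """The packaged 38-step cohort-size ladder."""
    ref = resources.files("constraintscope.data").joinpath("downsample_steps.json")
    with ref.open() as fh:
        return list(json.load(fh))


@dataclass
class DownsampleCurve:
    """Distinct LoF variants per cohort-size step, for one gene and cohort."""

    gene_symbol: str
    cohort_label: str
    steps: np.ndarray  # strictly increasing
    distinct_lof: np.ndarray  # non-decreasing along steps
    seed: int

    def __post_init__(self):
        self.steps = np.asarray(self.steps, dtype=int)
        self.distinct_lof = np.asarray(self.distinct_lof, dtype=int)
        if np.any(np.diff(self.steps) <= 0):
            raise ValueError("steps must be strictly increasing")
        if np.any(np.diff(self.distinct_lof) < 0):
            raise ValueError("distinct_lof must be non-decreasing (nested sampling violated)")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_symbol": self.gene_symbol,
                "cohort": self.cohort_label,
                "step": self.steps,
                "distinct_lof": self.distinct_lof,
            }
        )


@dataclass
class ReferenceCurve:
    """Precomputed population curve: observed and expected distinct LoF."""

    gene_symbol: str
    steps: np.ndarray
    observed_distinct_lof: np.ndarray
    expected_distinct_lof: np.ndarray


def nested_downsample(
    patient_variants,
    steps=None,
    seed: int = 0,
    gene_symbol: str = "",
    cohort_label: str = "case",
) -> DownsampleCurve:
    """Nested random downsampling of a labelled patient cohort.

    ``patient_variants`` is a sequence with one entry per patient: an
    iterable of variant labels carried by that patient in the gene (empty
    for "no variant detected").  Patients with several variants contribute
    all of them.  Steps exceeding the cohort size are dropped with a
    warning; the ladder defaults to the canonical 38 steps truncated at the
    cohort size, with the full cohort size always included as the final
    point so the curve ends at the actually observed count.

    Sampling is nested: the sample at each step is drawn without replacement
    from the sample at the next larger step, so curves are monotone
    non-decreasing by construction.
    """
    patients = [tuple(v) for v in patient_variants]
    n = len(patients)
    if steps is None:
        steps = [s for s in canonical_steps() if s < n] + [n]
    else:
        steps = sorted(int(s) for s in steps)
        too_big = [s for s in steps if s > n]
        if too_big:
            log.warning("dropping step(s) beyond cohort size %d: %s", n, too_big)
        steps = [s for s in steps if s <= n]
    if not steps:
        raise ValueError("no usable downsampling steps")

    rng = np.random.default_rng(seed)
    counts = {}
    current = np.arange(n)
    for step in sorted(steps, reverse=True):
        take = rng.choice(current.size, size=step, replace=False)
        current = current[take]
        distinct = set()
        for i in current:
            distinct.update(patients[i])
        counts[step] = len(distinct)
    ordered = np.array(sorted(counts), dtype=int)
    return DownsampleCurve(
        gene_symbol=gene_symbol,
        cohort_label=cohort_label,
        steps=ordered,
        distinct_lof=np.array([counts[s] for s in ordered]),
        seed=int(seed),
    )


def expected_distinct(variant_frequency_spectrum, n: int) -> float:
    """Expected distinct variants in a subsample of ``n`` of N individuals.

    For a spectrum of per-variant carrier counts ``k_v`` in a finite pool of
    N individuals, the hypergeometric closed form is::

        E[distinct at n] = sum_v (1 - C(N - k_v, n) / C(N, n))

    i.e. one minus the probability that all carriers of v are missed.
    ``variant_frequency_spectrum`` is ``(N, [k_1, k_2, ...])``.
    """
    N, ks = variant_frequency_spectrum
    ks = np.asarray(ks, dtype=int)
    if n < 0 or n > N:
        raise ValueError(f"subsample size n={n} outside [0, {N}]")
    if n == 0 or ks.size == 0:
        return 0.0

    def log_comb(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    miss = np.zeros(ks.size)
    feasible = (N - ks) >= n  # otherwise some carrier is always sampled
    if feasible.any():
        kf = ks[feasible]
        miss[feasible] = np.exp(log_comb(N - kf, n) - log_comb(N, n))
    return float((1.0 - miss).sum())


def spectrum_from_cohort(patient_variants) -> tuple[int, list[int]]:
    """Carrier-count spectrum (N, [k_v ...]) from labelled patients."""
    carriers: dict = {}
    n = 0
    for variants in patient_variants:
        n += 1
        for v in set(variants):
            carriers[v] = carriers.get(v, 0) + 1
    return n, sorted(carriers.values())


def compare_curves(case: DownsampleCurve, reference: ReferenceCurve) -> pd.DataFrame:
    """Join a case curve with a reference curve on their shared steps.

    Returns a long-format table (step, case count, reference observed,
    reference expected) ready for log-scaled plotting.
    """
    if reference.gene_symbol and case.gene_symbol and reference.gene_symbol != case.gene_symbol:
        raise ValueError(
            f"gene mismatch: case {case.gene_symbol!r} vs reference {reference.gene_symbol!r}"
        )
    shared = np.intersect1d(case.steps, reference.steps)
    ci = {s: v for s, v in zip(case.steps, case.distinct_lof)}
    ro = {s: v for s, v in zip(reference.steps, reference.observed_distinct_lof)}
    re_ = {s: v for s, v in zip(reference.steps, reference.expected_distinct_lof)}
    return pd.DataFrame(
        {
            "gene_symbol": case.gene_symbol or reference.gene_symbol,
            "step": shared,
            "case_distinct_lof": [ci[s] for s in shared],
            "reference_observed": [ro[s] for s in shared],
            "reference_expected": [re_[s] for s in shared],
        }
    )


def read_reference_curves(path) -> dict:
    """Read per-gene reference curves from a TSV (gene, step, observed, expected)."""
    table = pd.read_csv(path, sep="\t")
    required = {"gene_symbol", "step", "observed_distinct_lof", "expected_distinct_lof"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"reference curve table missing columns: {sorted(missing)}")
    out = {}
    for gene, sub in table.groupby("gene_symbol"):
        sub = sub.sort_values("step")
        out[gene] = ReferenceCurve(
            gene_symbol=str(gene),
            steps=sub["step"].to_numpy(int),
            observed_distinct_lof=sub["observed_distinct_lof"].to_numpy(),
            expected_distinct_lof=sub["expected_distinct_lof"].to_numpy(float),
        )
    return out


def plot_curves(joined: pd.DataFrame, path) -> None:
    """Write a log10-log10 accumulation plot (SVG) for one gene's joined table."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(joined["step"], joined["reference_expected"], "o-", label="expected", color="grey")
    ax.plot(joined["step"], joined["reference_observed"], "o-", label="population observed")
    ax.plot(joined["step"], joined["case_distinct_lof"], "o-", label="case cohort")
    ax.set_xscale("log")
    ax.set_yscale("symlog", linthresh=1)
    ax.set_xlabel("individuals sampled")
    ax.set_ylabel("distinct LoF variants")
    gene = joined["gene_symbol"].iloc[0] if len(joined) else ""
    ax.set_title(str(gene))
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)
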