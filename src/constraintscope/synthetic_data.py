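"""Synthetic inputs: constraint universes and case/background cohorts.

Every input the analysis consumes can be synthesised here so the whole
pipeline is testable offline:

* a gene universe whose per-gene expected LoF counts scale with CDS length
  (log-normal lengths, exome-like defaults) and whose observed counts are
  Poisson draws thinned by a group-specific depletion factor — the planted
  analogue of purifying selection;
* per-study variant report tables with deliberately messy ontology /
  pathogenicity spellings, panel coverage, patient overlap between two
  studies, and configurable per-gene carrier enrichment, mirroring the
  structure of published pediatric pan-cancer supplements.

Each generator records a truth manifest; any count a pipeline stage reports
should be derivable from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_harmonizer import PanelCoverage
from .constraint_core import CONSTRAINT_COLUMNS, oe_confidence_bounds

# Messy source vocabularies, keyed by the harmonized class they map to.
# All spellings resolve through the packaged label mappings.
RAW_ONTOLOGY = {
    "frameshift": ["frameshift", "Frameshift", "frameshift_variant", "Frame_Shift", "fs"],
    "nonsense": ["nonsense", "stop_gained", "Stopgain", "Nonsense", "stop gained"],
    "splice_donor": ["splice_donor", "splice donor", "Splice_Donor_Variant"],
    "splice_acceptor": ["splice_acceptor", "splice acceptor", "Splice_Acceptor_Variant"],
    "missense": ["missense", "Missense", "missense_variant", "nonsynonymous SNV"],
    "synonymous": ["synonymous", "Silent", "synonymous_variant"],
}
RAW_PATHOGENICITY = {
    "P": ["P", "Pathogenic", "C5: Pathogenic"],
    "LP": ["LP", "Likely pathogenic", "C4: Likely pathogenic", "PP"],
    "VUS": ["VUS", "Uncertain significance"],
}
RAW_ZYGOSITY = ["het", "Heterozygous", "", "het", ""]

#: Ontology class weights for reported variants in LoF-driven risk genes.
LOF_ONTOLOGY_WEIGHTS = {
    "frameshift": 0.35,
    "nonsense": 0.30,
    "splice_donor": 0.08,
    "splice_acceptor": 0.07,
    "missense": 0.17,
    "synonymous": 0.03,
}

#: Default 11-study case-cohort partition summing to 4,574 patients.
DEFAULT_STUDY_SIZES = {
    "study_01": 914,
    "study_02": 655,
    "study_03": 560,
    "study_04": 457,
    "study_05": 369,
    "study_06": 339,
    "study_07": 300,
    "study_08": 280,
    "study_09": 250,
    "study_10": 230,
    "study_11": 220,
}


@dataclass
class GeneUniverseSpec:
    """Parameters of a synthetic constraint universe.

    Defaults emulate an exome-scale metrics table: ~19,000 canonical
    transcripts, log-normal CDS lengths (median 1,400 bp, log-sd 0.75), and
    0.012 expected distinct LoF variants per coding bp at reference cohort
    depth, which puts a median gene around 17 expected LoF variants.  The
    ``risk`` group (85 genes by default, the size of the pediatric CPS
    panel) is depleted to 25% of its LoF expectation — the magnitude
    reported for pediatric CPS panels — while background genes are neutral.
    Missense depletion is much milder, as in real data.
    """

    n_genes: int = 19000
    cds_length_median_bp: float = 1400.0
    cds_length_sigma: float = 0.75
    mutation_rate_per_bp: float = 0.012
    mis_rate_per_bp: float = 0.14
    group_fractions: dict = field(default_factory=lambda: {"risk": 85 / 19000})
    depletion_by_group: dict = field(default_factory=lambda: {"risk": 0.25, "background": 1.0})
    mis_depletion_by_group: dict = field(default_factory=lambda: {"risk": 0.8, "background": 1.0})
    ci_level: float = 0.90
    seed: int = 0

    def __post_init__(self):
        for g, d in self.depletion_by_group.items():
            if not (0 < d <= 1):
                raise ValueError(f"depletion for group {g!r} must be in (0, 1], got {d}")
        if sum(self.group_fractions.values()) > 1:
            raise ValueError("group fractions must sum to <= 1")


def generate_gene_universe(spec: GeneUniverseSpec) -> pd.DataFrame:
    """Draw a constraint table with planted group-specific LoF depletion.

    Per gene: CDS length from the log-normal; ``exp_lof`` proportional to
    length; ``obs_lof ~ Poisson(depletion * exp_lof)``; ratio and exact
    Poisson CI bounds derived from the counts.  The returned frame follows
    the canonical constraint schema plus a ``group`` truth column.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_genes

    groups = np.full(n, "background", dtype=object)
    start = 0
    order = rng.permutation(n)
    for gname, frac in spec.group_fractions.items():
        size = int(round(frac * n))
        groups[order[start : start + size]] = gname
        start += size

    cds = np.maximum(
        150,
        np.round(spec.cds_length_median_bp * np.exp(rng.normal(0.0, spec.cds_length_sigma, n))),
    ).astype(int)

    dep = np.array([spec.depletion_by_group.get(g, 1.0) for g in groups])
    mis_dep = np.array([spec.mis_depletion_by_group.get(g, 1.0) for g in groups])

    exp_lof = spec.mutation_rate_per_bp * cds
    obs_lof = rng.poisson(dep * exp_lof)
    exp_mis = spec.mis_rate_per_bp * cds
    obs_mis = rng.poisson(mis_dep * exp_mis)

    loelf, loeuf = oe_confidence_bounds(obs_lof, exp_lof, spec.ci_level)
    moelf, moeuf = oe_confidence_bounds(obs_mis, exp_mis, spec.ci_level)

    table = pd.DataFrame(
        {
            "gene_symbol": [f"G{i:05d}" for i in range(n)],
            "transcript_id": [f"T{i:05d}.1" for i in range(n)],
            "cds_length": cds,
            "obs_lof": obs_lof.astype(float),
            "exp_lof": exp_lof,
            "loe": obs_lof / exp_lof,
            "loelf": loelf,
            "loeuf": loeuf,
            "obs_mis": obs_mis.astype(float),
            "exp_mis": exp_mis,
            "moe": obs_mis / exp_mis,
            "moelf": moelf,
            "moeuf": moeuf,
            "lof_metrics_defined": True,
            "group": groups,
        }
    )
    return table[CONSTRAINT_COLUMNS + ["group"]]


@dataclass
class CohortSpec:
    """Parameters of a synthetic multi-study case cohort.

    ``carrier_probability`` and ``risk_carrier_probability`` are per-gene
    Bernoulli rates for background and risk genes; ``planted_carriers``
    switches a gene to fixed-count mode (exactly that many carriers,
    allowing in-paper contingency tables to be rebuilt exactly).
    ``recurrent_variant_fraction`` is the chance a carrier draws a shared
    hotspot variant from the gene's pool instead of a fresh unique one.
    """

    n_patients: int = 4574
    carrier_probability: float = 2e-4
    risk_carrier_probability: float = 2e-3
    recurrent_variant_fraction: float = 0.2
    study_sizes: dict = field(default_factory=lambda: dict(DEFAULT_STUDY_SIZES))
    panel_by_study: dict | None = None  # study -> iterable of genes; None = all genes everywhere
    planted_carriers: dict = field(default_factory=dict)  # gene -> exact carrier count
    seed: int = 0

    def __post_init__(self):
        if sum(self.study_sizes.values()) != self.n_patients:
            raise ValueError(
                f"study sizes sum to {sum(self.study_sizes.values())}, expected {self.n_patients}"
            )
        for p in (self.carrier_probability, self.risk_carrier_probability):
            if not (0 <= p <= 1):
                raise ValueError("carrier probabilities must be in [0, 1]")


def _synth_hgvs(rng, cds_length: int) -> str:
    pos = int(rng.integers(1, max(cds_length, 2)))
    kind = rng.random()
    if kind < 0.6:
        ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
        return f"c.{pos}{ref}>{alt}"
    if kind < 0.8:
        return f"c.{pos}del"
    return f"c.{pos}dup"


def generate_cohorts(spec: CohortSpec, universe: pd.DataFrame, genes=None):
    """Per-study variant report tables plus panel coverage and truth manifest.

    ``genes`` selects which universe genes can carry reported variants
    (default: the universe's ``risk`` group).  Carrier status is Bernoulli
    per gene and patient — or exact-count for genes in
    ``spec.planted_carriers`` — restricted to patients of studies whose
    panel covers the gene.  Reported labels are drawn from messy synonym
    pools so downstream normalization is exercised.

    Returns ``(study_tables, panels, manifest)``.
    """
    rng = np.random.default_rng(spec.seed)
    uni = universe.set_index("gene_symbol")
    if genes is None:
        if "group" in universe.columns:
            genes = universe.loc[universe["group"] == "risk", "gene_symbol"].tolist()
        else:
            genes = universe["gene_symbol"].tolist()
    genes = list(genes)

    # patient roster: ids carry the study prefix
    roster = []
    for sid, size in spec.study_sizes.items():
        roster.extend((sid, f"{sid}_P{i:05d}") for i in range(size))
    roster = pd.DataFrame(roster, columns=["study_id", "patient_id"])

    panels = []
    panel_map = {}
    for sid, size in spec.study_sizes.items():
        covered = (
            frozenset(genes)
            if spec.panel_by_study is None
            else frozenset(spec.panel_by_study.get(sid, genes))
        )
        panels.append(PanelCoverage(study_id=sid, genes_on_panel=covered, n_patients=size))
        panel_map[sid] = covered

    rows = []
    manifest = {"seed": spec.seed, "genes": {}, "study_sizes": dict(spec.study_sizes)}
    for gene in genes:
        cds = int(uni.loc[gene, "cds_length"]) if gene in uni.index else 2000
        covered_mask = roster["study_id"].map(lambda s: gene in panel_map[s]).to_numpy()
        covered_idx = np.flatnonzero(covered_mask)
        if gene in spec.planted_carriers:
            k = int(spec.planted_carriers[gene])
            if k > covered_idx.size:
                raise ValueError(f"cannot plant {k} carriers of {gene}: only {covered_idx.size} covered patients")
            carrier_idx = rng.choice(covered_idx, size=k, replace=False)
        else:
            group = uni.loc[gene, "group"] if ("group" in uni.columns and gene in uni.index) else "risk"
            p = spec.risk_carrier_probability if group == "risk" else spec.carrier_probability
            carrier_idx = covered_idx[rng.random(covered_idx.size) < p]

        hotspots = [_synth_hgvs(rng, cds) for _ in range(3)]
        onto_classes = list(LOF_ONTOLOGY_WEIGHTS)
        onto_p = np.array(list(LOF_ONTOLOGY_WEIGHTS.values()))
        gene_variants = {}
        for idx in carrier_idx:
            if rng.random() < spec.recurrent_variant_fraction:
                hgvs = hotspots[int(rng.integers(len(hotspots)))]
            else:
                hgvs = _synth_hgvs(rng, cds)
            if hgvs not in gene_variants:
                gene_variants[hgvs] = onto_classes[
                    int(rng.choice(len(onto_classes), p=onto_p / onto_p.sum()))
                ]
            onto = gene_variants[hgvs]
            raw_onto = str(rng.choice(RAW_ONTOLOGY[onto]))
            path_cls = str(rng.choice(["P", "LP", "VUS"], p=[0.45, 0.35, 0.2]))
            rows.append(
                {
                    "study_id": roster.iloc[idx]["study_id"],
                    "patient_id": roster.iloc[idx]["patient_id"],
                    "gene_symbol": gene,
                    "hgvs_c": hgvs,
                    "raw_ontology": raw_onto,
                    "pathogenicity": str(rng.choice(RAW_PATHOGENICITY[path_cls])),
                    "zygosity": str(rng.choice(RAW_ZYGOSITY)),
                }
            )
        manifest["genes"][gene] = {
            "carriers": int(carrier_idx.size),
            "distinct_variants": len(gene_variants),
            "lof_variants": sorted(
                h for h, o in gene_variants.items()
                if o in ("frameshift", "nonsense", "splice_donor", "splice_acceptor")
            ),
            "denominator": int(covered_idx.size),
        }

    reports = pd.DataFrame(
        rows,
        columns=[
            "study_id", "patient_id", "gene_symbol", "hgvs_c",
            "raw_ontology", "pathogenicity", "zygosity",
        ],
    )
    study_tables = {
        sid: reports[reports["study_id"] == sid].reset_index(drop=True)
        for sid in spec.study_sizes
    }
    return study_tables, panels, manifest


def generate_overlap_fixture(
    n_secondary: int = 914,
    n_shared: int = 259,
    n_primary_extra: int = 600,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two study tables sharing St. Jude-format patient IDs.

    The secondary study has ``n_secondary`` single-report patients of which
    exactly ``n_shared`` reuse SJ-format IDs also present in the primary
    study; the rest carry non-SJ IDs.  Emulates the published overlap of a
    re-analysis cohort (259 of 914 shared SJ IDs) for deduplication tests.
    """
    if n_shared > n_secondary:
        raise ValueError("n_shared cannot exceed n_secondary")
    rng = np.random.default_rng(seed)

    def _report(study, pid):
        return {
            "study_id": study,
            "patient_id": pid,
            "gene_symbol": "TP53",
            "hgvs_c": _synth_hgvs(rng, 1182),
            "raw_ontology": str(rng.choice(RAW_ONTOLOGY["nonsense"])),
            "pathogenicity": "P",
            "zygosity": "het",
        }

    shared_ids = [f"SJ{rng.choice(['ALL', 'MB', 'NBL', 'WLM'])}{i:06d}" for i in range(n_shared)]
    primary_ids = shared_ids + [f"SJX{i + n_shared:06d}" for i in range(n_primary_extra)]
    secondary_ids = shared_ids + [f"LOCAL_{i:05d}" for i in range(n_secondary - n_shared)]
    primary = pd.DataFrame([_report("primary_study", pid) for pid in primary_ids])
    secondary = pd.DataFrame([_report("secondary_study", pid) for pid in secondary_ids])
    return primary, secondary
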