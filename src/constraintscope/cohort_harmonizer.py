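"""Harmonization of multi-study germline variant reports.

Published pan-cancer germline studies report variants in incompatible
vocabularies ("stop_gained" vs. "Nonsense", "C4: Likely pathogenic" vs.
"LP"), overlap in patients (re-analysis cohorts sharing St. Jude sample
IDs), and occasionally list alleles that are risk factors rather than
syndrome-causing variants.  This module turns a pile of per-study report
tables into one analyzable table: label normalization, cross-study
deduplication by patient-ID pattern, variant exclusions, LoF flagging, and
per-gene carrier counting against study panel coverage.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd
import yaml

log = logging.getLogger(__name__)

REPORT_COLUMNS = [
    "study_id",
    "patient_id",
    "gene_symbol",
    "hgvs_c",
    "raw_ontology",
    "ontology",
    "pathogenicity",
    "zygosity",
]

#: Ontologies that count as predicted loss of function.  Pathogenicity is
#: deliberately ignored: a frameshift reported as VUS is still a pLoF.
LOF_ONTOLOGIES = frozenset({"frameshift", "nonsense", "splice_donor", "splice_acceptor"})

#: Default cross-study patient-ID matcher: St. Jude sample IDs (SJxxxnnn).
DEFAULT_ID_PATTERN = r"^SJ[A-Za-z]*\d+$"


def load_label_mappings() -> dict:
    """Packaged nomenclature-cleaning tables (ontology/pathogenicity/zygosity)."""
    ref = resources.files("constraintscope.data").joinpath("label_mappings.yaml")
    with ref.open() as fh:
        return yaml.safe_load(fh)


def _canon(raw) -> str:
    return re.sub(r"\s+", " ", str(raw)).strip().lower()


def normalize_labels(raw, mapping: dict, default: str = "other") -> str:
    """Map one raw label to the harmonized vocabulary.

    Matching is case-insensitive and whitespace-insensitive.  Labels already
    in the harmonized vocabulary are fixed points; anything unmapped becomes
    ``default`` with a logged warning.
    """
    key = _canon(raw)
    if key in mapping:
        return mapping[key]
    canonical_values = set(mapping.values())
    if str(raw) in canonical_values or key in {v.lower() for v in canonical_values}:
        for v in canonical_values:
            if v.lower() == key:
                return v
    log.warning("unmapped label %r -> %r", raw, default)
    return default


def normalize_hgvs(hgvs) -> str:
    """Whitespace-stripped HGVS string for exact comparison (no parsing)."""
    return re.sub(r"\s+", "", str(hgvs))


def flag_lof(ontology) -> bool:
    """True iff the normalized ontology is a pLoF class (frameshift,
    nonsense, or essential splice donor/acceptor), regardless of the
    reported pathogenicity."""
    if isinstance(ontology, pd.Series):
        return ontology.isin(LOF_ONTOLOGIES)
    return ontology in LOF_ONTOLOGIES


def normalize_reports(reports: pd.DataFrame, mappings: dict | None = None) -> pd.DataFrame:
    """Normalize ontology/pathogenicity/zygosity labels and HGVS strings.

    The raw ontology is preserved in ``raw_ontology``.  Unreported zygosity
    defaults to monoallelic (source studies under-report carrier state); the
    number of such assumptions is logged.
    """
    if mappings is None:
        mappings = load_label_mappings()
    out = reports.copy()
    onto_src = out["ontology"] if "ontology" in out.columns else out["raw_ontology"]
    if "raw_ontology" not in out.columns:
        out["raw_ontology"] = onto_src
    out["ontology"] = [normalize_labels(v, mappings["ontology"]) for v in onto_src]
    out["pathogenicity"] = [
        normalize_labels(v, mappings["pathogenicity"]) for v in out["pathogenicity"]
    ]
    if "zygosity" in out.columns:
        zyg = out["zygosity"].fillna("")
    else:
        zyg = pd.Series("", index=out.index)
    unknown = zyg.map(_canon).isin(("", "nan", "unknown", "na", "not reported"))
    if unknown.any():
        log.info("assuming monoallelic zygosity for %d report(s)", int(unknown.sum()))
    out["zygosity"] = [
        "monoallelic" if u else normalize_labels(z, mappings["zygosity"], default="unknown")
        for z, u in zip(zyg, unknown)
    ]
    out["hgvs_c"] = out["hgvs_c"].map(normalize_hgvs)
    out["patient_id"] = out["patient_id"].astype(str).str.strip()
    return out


def deduplicate_overlap(
    primary: pd.DataFrame,
    secondary: pd.DataFrame,
    id_pattern: str = DEFAULT_ID_PATTERN,
) -> tuple[pd.DataFrame, int]:
    """Drop secondary-study rows whose patient re-appears in the primary study.

    Only IDs matching ``id_pattern`` (default: the St. Jude SJxxxnnn format)
    are compared across studies.  Returns the filtered secondary table and
    the number of rows removed; the primary table is never modified.
    """
    pat = re.compile(id_pattern)
    prim_ids = {
        pid for pid in primary["patient_id"].astype(str).str.strip() if pat.match(pid)
    }
    sec_ids = secondary["patient_id"].astype(str).str.strip()
    drop = sec_ids.map(lambda pid: bool(pat.match(pid)) and pid in prim_ids)
    removed = int(drop.sum())
    if removed:
        log.info(
            "overlap dedup: removing %d of %d row(s) from study %s",
            removed,
            len(secondary),
            ", ".join(secondary["study_id"].unique()),
        )
    return secondary[~drop.to_numpy()].reset_index(drop=True), removed


def load_default_exclusions() -> pd.DataFrame:
    """Packaged variant exclusion list (exactly the APC c.3920T>A allele)."""
    ref = resources.files("constraintscope.data").joinpath("variant_exclusions.csv")
    with ref.open() as fh:
        return pd.read_csv(fh)


def apply_exclusions(
    reports: pd.DataFrame, exclusions: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, int]:
    """Remove reports matching (gene, HGVS) exclusion pairs.

    HGVS strings are compared whitespace-stripped, so spelling variants like
    ``c.3920 T > A`` still match.  All other reported variants are retained.
    """
    if exclusions is None:
        exclusions = load_default_exclusions()
    if exclusions.empty:
        return reports.reset_index(drop=True), 0
    keys = {
        (g, normalize_hgvs(h))
        for g, h in zip(exclusions["gene_symbol"], exclusions["hgvs_c"])
    }
    mask = [
        (g, normalize_hgvs(h)) in keys
        for g, h in zip(reports["gene_symbol"], reports["hgvs_c"])
    ]
    mask = pd.Series(mask, index=reports.index)
    removed = int(mask.sum())
    if removed:
        log.info("exclusion list removed %d report(s)", removed)
    return reports[~mask].reset_index(drop=True), removed


@dataclass
class PanelCoverage:
    """Which genes one study's assay covered, and for how many patients."""

    study_id: str
    genes_on_panel: frozenset
    n_patients: int


def panels_from_frame(panel_genes: pd.DataFrame, study_sizes: pd.DataFrame) -> list[PanelCoverage]:
    """Build :class:`PanelCoverage` objects from long-format tables.

    ``panel_genes`` has columns (study_id, gene_symbol); ``study_sizes`` has
    (study_id, n_patients).
    """
    gene_sets = panel_genes.groupby("study_id")["gene_symbol"].agg(frozenset)
    out = []
    for _, row in study_sizes.iterrows():
        out.append(
            PanelCoverage(
                study_id=str(row["study_id"]),
                genes_on_panel=gene_sets.get(row["study_id"], frozenset()),
                n_patients=int(row["n_patients"]),
            )
        )
    return out


@dataclass
class CarrierCount:
    """Per-gene carrier tally over the studies whose panel covers the gene."""

    gene_symbol: str
    carriers: int
    denominator: int
    distinct_variants: int
    covering_studies: tuple = ()

    @property
    def frequency_percent(self) -> float:
        """Carrier frequency as a percentage (NaN when uncovered)."""
        if self.denominator == 0:
            return float("nan")
        return 100.0 * self.carriers / self.denominator


def carrier_counts(
    reports: pd.DataFrame,
    panels: list[PanelCoverage],
    gene: str,
    lof_only: bool = True,
) -> CarrierCount:
    """Count carriers of (LoF) variants in one gene across covering studies.

    Carriers are distinct patients with at least one qualifying variant,
    counted only within studies whose panel includes the gene; the
    denominator is the total patient count of those studies.  A gene on no
    panel yields denominator 0 (flagged by a warning, not an error).
    """
    covering = [p for p in panels if gene in p.genes_on_panel]
    if not covering:
        log.warning("gene %s is on no study panel; denominator is 0", gene)
        return CarrierCount(gene, 0, 0, 0, ())
    study_ids = {p.study_id for p in covering}
    denominator = sum(p.n_patients for p in covering)
    sub = reports[(reports["gene_symbol"] == gene) & reports["study_id"].isin(study_ids)]
    if lof_only:
        sub = sub[flag_lof(sub["ontology"])]
    carriers = sub.drop_duplicates(["study_id", "patient_id"]).shape[0]
    distinct = sub["hgvs_c"].nunique()
    return CarrierCount(gene, int(carriers), int(denominator), int(distinct), tuple(sorted(study_ids)))


@dataclass
class HarmonizationResult:
    reports: pd.DataFrame
    log: dict = field(default_factory=dict)


def harmonize_bundle(
    study_tables: dict,
    overlap_pairs: list[tuple[str, str]] | None = None,
    mappings: dict | None = None,
    exclusions: pd.DataFrame | None = None,
    id_pattern: str = DEFAULT_ID_PATTERN,
) -> HarmonizationResult:
    """Full harmonization pass over a dict of per-study report tables.

    Order of operations: label/HGVS normalization per study, cross-study
    patient deduplication for each (primary, secondary) pair in
    ``overlap_pairs`` (rows are removed from the *secondary* study), then
    variant exclusions.  The returned log counts every removal, and the pass
    is idempotent: harmonizing the harmonized output removes nothing.
    """
    audit: dict = {"dedup_removed": {}, "excluded": 0, "studies": sorted(study_tables)}
    tables = {sid: normalize_reports(t, mappings) for sid, t in study_tables.items()}
    for primary_id, secondary_id in overlap_pairs or []:
        filtered, removed = deduplicate_overlap(
            tables[primary_id], tables[secondary_id], id_pattern
        )
        tables[secondary_id] = filtered
        audit["dedup_removed"][f"{secondary_id} (vs {primary_id})"] = removed
    combined = pd.concat(tables.values(), ignore_index=True)
    combined, n_excluded = apply_exclusions(combined, exclusions)
    audit["excluded"] = n_excluded
    missing = [c for c in REPORT_COLUMNS if c not in combined.columns]
    if missing:
        raise ValueError(f"harmonized table is missing columns: {missing}")
    return HarmonizationResult(reports=combined[REPORT_COLUMNS], log=audit)
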