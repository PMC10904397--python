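"""End-to-end orchestration: harmonize, classify, compare, downsample.

A run is configured by a :class:`RunConfig` (usually loaded from YAML),
executes deterministically given its master seed, and writes a results
bundle — classified gene table, census and burden tables, gene-set test
JSON, harmonized cohort table with carrier counts, downsampling curves —
plus a manifest recording seeds and input/output checksums so a run can be
reproduced byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .constraint_core import (
    DEFAULT_THRESHOLD,
    read_annotation,
    read_constraint_table,
    write_classified_table,
)
from .cohort_harmonizer import carrier_counts, harmonize_bundle, panels_from_frame
from .downsample_curves import nested_downsample
from .gene_sets import (
    build_size_matched_subset,
    census_contingency,
    compare_gene_sets,
    constraint_level_census,
)
from .stat_engine import fisher_exact_cmle, resampling_null
from . import synthetic_data

log = logging.getLogger(__name__)


def stage_seed(master_seed: int, stage: str) -> int:
    """Independent per-stage seed derived from the master seed.

    Uses a SeedSequence keyed by (master seed, crc32 of the stage name), so
    adding or reordering stages never perturbs another stage's draws.
    """
    ss = np.random.SeedSequence([int(master_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Configuration of one pipeline run; all fields have working defaults.

    When ``constraint_table`` is None a synthetic universe is generated (and
    its planted risk group doubles as the target panel); otherwise the file
    is read with ``dialect`` and the target panel comes from ``annotation``
    (None = the packaged 85-gene panel).
    """

    seed: int = 0
    out_dir: str = "results"
    threshold: float = DEFAULT_THRESHOLD
    or_ci_level: float = 0.95
    n_bins: int = 9
    iterations: int = 10_000
    constraint_table: str | None = None
    dialect: str = "synthetic"
    annotation: str | None = None
    study_tables: dict = field(default_factory=dict)  # study_id -> csv path
    panel_genes: str | None = None  # long-format csv: study_id,gene_symbol
    study_sizes: str | None = None  # csv: study_id,n_patients
    overlap_pairs: list = field(default_factory=list)
    downsample_genes: list = field(default_factory=list)
    synth_universe: dict = field(default_factory=dict)
    synth_cohort: dict = field(default_factory=dict)
    make_cohort: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        """Fail before any computation if a referenced input is missing."""
        paths = [self.constraint_table, self.annotation, self.panel_genes, self.study_sizes]
        paths += list(self.study_tables.values())
        for p in paths:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured input does not exist: {p}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write the results bundle to ``config.out_dir``.

    Returns the manifest dictionary.  Any stage failure propagates with the
    stage name prepended so the offending context is visible.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": {},
        "inputs": {},
        "outputs": {},
    }
    results: dict = {}

    stage = "inputs"
    try:
        if config.constraint_table is None:
            useed = stage_seed(config.seed, "universe")
            manifest["stage_seeds"]["universe"] = useed
            spec = synthetic_data.GeneUniverseSpec(**{"seed": useed, **config.synth_universe})
            universe = synthetic_data.generate_gene_universe(spec)
            target = universe[universe["group"] == "risk"]
            annotation = None
        else:
            universe = read_constraint_table(config.constraint_table, config.dialect)
            manifest["inputs"][config.constraint_table] = _sha256(Path(config.constraint_table))
            annotation = read_annotation(config.annotation)
            target = universe[universe["gene_symbol"].isin(annotation["gene_symbol"])]

        stage = "classify"
        classified = write_classified_table(universe, out / "classified.tsv", config.threshold)

        stage = "gene_sets"
        gseed = stage_seed(config.seed, "gene_sets")
        manifest["stage_seeds"]["gene_sets"] = gseed
        rest = universe[~universe["gene_symbol"].isin(target["gene_symbol"])]
        comparison = compare_gene_sets(target, rest, "loeuf")
        subset = build_size_matched_subset(target, universe, config.n_bins, gseed)
        matched = universe[universe["gene_symbol"].isin(subset.members)]
        matched_cmp = compare_gene_sets(target, matched, "loeuf")
        null = resampling_null(
            matched["loeuf"].dropna().to_numpy(),
            k=min(len(target), len(matched)),
            iterations=config.iterations,
            observed=float(target["loeuf"].mean()),
            seed=gseed,
            tail="lower",
            statistic_name="mean LOEUF",
        )
        results["gene_sets"] = {
            "target_vs_rest": comparison.to_dict(),
            "target_vs_size_matched": matched_cmp.to_dict(),
            "size_matched_subset": {
                "n": len(subset.members),
                "per_bin_count": subset.per_bin_count,
                "bins": subset.bins,
                "seed": subset.seed,
            },
            "resampling_null": null.to_dict(),
        }

        stage = "census"
        if annotation is not None:
            census = constraint_level_census(universe, annotation, config.threshold)
            census.to_csv(out / "census.tsv", sep="\t")
            burden = {}
            pairs = [(a, b) for a in census.index for b in census.index if a < b]
            for ga, gb in pairs:
                a, b, c, d = census_contingency(census, ga, gb)
                if (a + b) and (c + d):
                    burden[f"{ga} vs {gb}"] = fisher_exact_cmle(
                        a, b, c, d, config.or_ci_level
                    ).to_dict()
            results["census_burden"] = burden

        stage = "cohort"
        if config.study_tables:
            tables = {sid: pd.read_csv(p) for sid, p in config.study_tables.items()}
            for sid, p in config.study_tables.items():
                manifest["inputs"][p] = _sha256(Path(p))
            panels = panels_from_frame(
                pd.read_csv(config.panel_genes), pd.read_csv(config.study_sizes)
            )
        elif config.make_cohort and config.constraint_table is None:
            cseed = stage_seed(config.seed, "cohort")
            manifest["stage_seeds"]["cohort"] = cseed
            cspec = synthetic_data.CohortSpec(**{"seed": cseed, **config.synth_cohort})
            tables, panels, truth = synthetic_data.generate_cohorts(cspec, universe)
            results["cohort_truth_genes"] = len(truth["genes"])
        else:
            tables, panels = {}, []

        if tables:
            harmonized = harmonize_bundle(tables, overlap_pairs=config.overlap_pairs or None)
            harmonized.reports.to_csv(out / "harmonized.tsv", sep="\t", index=False)
            results["harmonization_log"] = harmonized.log
            genes_seen = sorted(harmonized.reports["gene_symbol"].unique())
            counts = [carrier_counts(harmonized.reports, panels, g) for g in genes_seen]
            pd.DataFrame(
                {
                    "gene_symbol": [c.gene_symbol for c in counts],
                    "carriers": [c.carriers for c in counts],
                    "denominator": [c.denominator for c in counts],
                    "distinct_variants": [c.distinct_variants for c in counts],
                    "frequency_percent": [c.frequency_percent for c in counts],
                }
            ).to_csv(out / "carrier_counts.tsv", sep="\t", index=False)

            stage = "downsample"
            dseed = stage_seed(config.seed, "downsample")
            manifest["stage_seeds"]["downsample"] = dseed
            genes = config.downsample_genes or [
                c.gene_symbol
                for c in sorted(counts, key=lambda c: -c.carriers)[:3]
                if c.carriers
            ]
            curve_frames = []
            from .cohort_harmonizer import flag_lof

            lof_reports = harmonized.reports[flag_lof(harmonized.reports["ontology"])]
            for gene in genes:
                cohort = _patient_variant_labels(lof_reports, panels, gene)
                if not cohort:
                    continue
                curve = nested_downsample(cohort, seed=dseed, gene_symbol=gene)
                curve_frames.append(curve.to_frame())
            if curve_frames:
                pd.concat(curve_frames, ignore_index=True).to_csv(
                    out / "curves.tsv", sep="\t", index=False
                )
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    with open(out / "results.json", "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True)
    for artifact in sorted(out.iterdir()):
        if artifact.name != "manifest.json":
            manifest["outputs"][artifact.name] = _sha256(artifact)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _patient_variant_labels(lof_reports: pd.DataFrame, panels, gene: str) -> list:
    """Per-patient variant label lists for one gene over covering studies."""
    covering = [p for p in panels if gene in p.genes_on_panel]
    if not covering:
        return []
    sub = lof_reports[
        (lof_reports["gene_symbol"] == gene)
        & lof_reports["study_id"].isin({p.study_id for p in covering})
    ]
    by_patient: dict = {}
    for _, row in sub.iterrows():
        by_patient.setdefault((row["study_id"], row["patient_id"]), []).append(row["hgvs_c"])
    cohort = list(by_patient.values())
    n_total = sum(p.n_patients for p in covering)
    cohort.extend([] for _ in range(n_total - len(cohort)))
    return cohort
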