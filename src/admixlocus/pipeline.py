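"""End-to-end study replica: data → ancestry table → controls → proximity → report.

Three input modes:

``simulate``
    Generate a synthetic admixed cohort (:mod:`.simulate`) and run the full
    post-processing chain on it.
``rfmix-dir``
    Read an existing directory of RFMix-dialect files (the layout written by
    :func:`admixlocus.simulate.emit_cohort`).
``tables``
    Skip the cohort stage and run the catalog / proximity / enrichment
    analyses on the packaged published tables only.

Every run writes a fixed bundle into the output directory: ``all_chr.anc``,
``targets.anc`` (+ ``targets_missing.txt``), ``random_controls.tsv``,
``pairs.csv``, ``enrichment.json`` and ``run_log.json``. Outputs carry no
timestamps, so re-running with the same configuration reproduces every file
byte-identically.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import __version__
from .ancestry import lookup_summary, summarize_ancestry, write_anc
from .catalog import SnpCatalog, SnpRecord, Relation, filter_by_relation, read_catalog
from .datasets import (
    cvd_loci_catalog,
    load_random_locus_ancestry,
    load_snp_catalog,
)
from .enrichment import (
    EnrichmentConfig,
    compare_enrichment,
    count_enriched,
    random_control,
)
from .errors import ConfigError, ConsistencyError
from .proximity import ProximityConfig, bracket_search, write_pairs_csv
from .rfmix_io import (
    AncestryPosterior,
    SampleSet,
    concat_chromosomes,
    read_forward_backward,
    read_sample_list,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    mode: str = "simulate"  # simulate | rfmix-dir | tables
    out_dir: Path = Path("admixlocus_run")
    seed: int = 0
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)
    proximity: ProximityConfig = field(default_factory=ProximityConfig)
    sim_params: Optional["SimulationParams"] = None  # noqa: F821
    spikes: Sequence["EnrichmentSpike"] = ()  # noqa: F821
    rfmix_dir: Optional[Path] = None
    targets_path: Optional[Path] = None   # catalog TSV of target loci
    n_targets: int = 10                   # simulate mode: targets picked from data

    def __post_init__(self):
        if self.mode not in ("simulate", "rfmix-dir", "tables"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.mode == "rfmix-dir":
            if self.rfmix_dir is None or not Path(self.rfmix_dir).is_dir():
                raise ConfigError("rfmix-dir mode requires an existing rfmix_dir")
        if self.targets_path is not None and not Path(self.targets_path).exists():
            raise ConfigError(f"targets file not found: {self.targets_path}")


def _chrom_sort_key(c: str):
    return (0, int(c)) if c.isdigit() else (1, c)


def read_rfmix_dir(path) -> tuple[list[AncestryPosterior], SampleSet]:
    """Read every ``chr*.ForwardBackward.txt`` (plus locations and snp_info)
    under ``path``, in natural chromosome order."""
    path = Path(path)
    samples = read_sample_list(path / "samples.txt")
    chroms = []
    for fb in path.glob("chr*.ForwardBackward.txt"):
        m = re.match(r"chr(.+)\.ForwardBackward\.txt$", fb.name)
        if m:
            chroms.append(m.group(1))
    if not chroms:
        raise ConsistencyError(f"no forward–backward files found under {path}")
    chroms.sort(key=_chrom_sort_key)
    parts = []
    for chrom in chroms:
        prefix = path / f"chr{chrom}"
        ap = read_forward_backward(
            f"{prefix}.ForwardBackward.txt",
            f"{prefix}.snp_locations",
            samples,
            chrom=chrom,
        )
        info = Path(f"{prefix}.snp_info.tsv")
        if info.exists():
            import pandas as pd

            df = pd.read_csv(info, sep="\t", dtype={"chrom": str})
            from dataclasses import replace

            ap = replace(
                ap,
                rsids=list(df["rsid"].astype(str)),
                positions_bp=df["pos_bp"].to_numpy(),
            )
        parts.append(ap)
    return parts, samples


def _summary_catalog(summary, rsids: list[str]) -> SnpCatalog:
    """Catalog of the given summary loci, carrying their cM coordinates."""
    index = {r: i for i, r in enumerate(summary.rsids)}
    records = []
    for r in rsids:
        i = index[r]
        records.append(
            SnpRecord(
                rsid=r,
                chrom=str(summary.chroms[i]),
                pos_bp=int(summary.positions_bp[i]),
                cm=float(summary.locations_cm[i]),
            )
        )
    return SnpCatalog(records=records)


def _spike_loci(summary, spikes, n_targets: int) -> list[str]:
    """Target rsids for simulate mode: loci inside spiked windows when spikes
    exist, else the first n loci."""
    if spikes:
        chosen = []
        for i in range(summary.n_variants):
            for s in spikes:
                if (
                    str(summary.chroms[i]) == s.chrom
                    and s.cm_start <= summary.locations_cm[i] <= s.cm_end
                ):
                    chosen.append(summary.rsids[i])
                    break
        return chosen[:n_targets]
    return summary.rsids[:n_targets]


def run_study(cfg: RunConfig) -> dict:
    """Run the configured study end to end; returns the report dictionary.

    Any stage failure is re-raised annotated with the stage name. The report
    (also written as ``run_log.json``) records the seed, package version, and
    item counts at every stage.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "mode": cfg.mode, "seed": cfg.seed}
    stage = "setup"
    try:
        if cfg.mode == "tables":
            return _run_tables(cfg, out, report)

        stage = "cohort"
        if cfg.mode == "simulate":
            from .simulate import SimulationParams, simulate_cohort

            params = cfg.sim_params or SimulationParams(seed=cfg.seed)
            parts, _, _, samples = simulate_cohort(params, cfg.spikes)
        else:
            parts, samples = read_rfmix_dir(cfg.rfmix_dir)
        report["n_samples"] = len(samples)
        report["n_chromosomes"] = len(parts)

        stage = "ancestry-summary"
        summary = summarize_ancestry(concat_chromosomes(parts), samples)
        write_anc(summary, out / "all_chr.anc")
        report["n_variants"] = summary.n_variants

        stage = "target-lookup"
        if cfg.targets_path is not None:
            target_rsids = read_catalog(cfg.targets_path).rsids
        else:
            target_rsids = _spike_loci(summary, cfg.spikes, cfg.n_targets)
        targets, missing = lookup_summary(summary, target_rsids)
        write_anc(targets, out / "targets.anc")
        (out / "targets_missing.txt").write_text(
            "".join(r + "\n" for r in missing)
        )
        report["n_targets_queried"] = len(target_rsids)
        report["n_targets_found"] = targets.n_variants
        report["n_targets_missing"] = len(missing)

        stage = "random-controls"
        exclude = _summary_catalog(summary, targets.rsids)
        controls = random_control(
            summary, exclude, cfg.enrichment.n_random, cfg.seed
        )
        controls_frame = controls.to_frame()
        controls_frame.to_csv(out / "random_controls.tsv", sep="\t", index=False)
        report["n_controls"] = controls.n_variants

        stage = "bracket-search"
        target_cat = _summary_catalog(summary, targets.rsids)
        control_cat = _summary_catalog(summary, controls.rsids)
        pairs = bracket_search(target_cat, control_cat, cfg.proximity)
        write_pairs_csv(pairs, out / "pairs.csv")
        report["n_proximity_pairs"] = len(pairs)

        stage = "enrichment"
        t_counts = count_enriched(targets, cfg.enrichment)
        c_counts = count_enriched(controls, cfg.enrichment)
        contingency = compare_enrichment(t_counts, c_counts)
        report["enrichment"] = {
            "threshold": cfg.enrichment.threshold,
            "target_counts": t_counts.as_row(),
            "control_counts": c_counts.as_row(),
            "table": contingency.table.tolist(),
            "columns": list(contingency.columns),
            "statistic": contingency.statistic,
            "p_value": contingency.p_value,
            "method": contingency.method,
        }
        with open(out / "enrichment.json", "w") as fh:
            json.dump(report["enrichment"], fh, indent=2)

        with open(out / "run_log.json", "w") as fh:
            json.dump(report, fh, indent=2)
        return report
    except Exception as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc


def _run_tables(cfg: RunConfig, out: Path, report: dict) -> dict:
    """Fixture-only analysis over the packaged published tables."""
    catalog = load_snp_catalog()
    report["catalog_counts"] = {
        tag.value: len(filter_by_relation(catalog, tag))
        for tag in (Relation.ACS, Relation.CAD, Relation.PAD, Relation.CLOPIDOGREL)
    }
    report["n_catalog"] = len(catalog)

    cvd_cat = cvd_loci_catalog()
    pairs = bracket_search(cvd_cat, cvd_cat, cfg.proximity)
    write_pairs_csv(pairs, out / "pairs.csv")
    report["n_proximity_pairs"] = len(pairs)

    from .datasets import load_cvd_locus_ancestry

    targets_df = load_cvd_locus_ancestry()
    controls_df = load_random_locus_ancestry()
    targets_df.to_csv(out / "targets.anc", sep="\t", index=False)
    controls_df.to_csv(out / "random_controls.tsv", sep="\t", index=False)
    t_counts = count_enriched(targets_df, cfg.enrichment)
    c_counts = count_enriched(controls_df, cfg.enrichment)
    contingency = compare_enrichment(t_counts, c_counts)
    report["enrichment"] = {
        "threshold": cfg.enrichment.threshold,
        "target_counts": t_counts.as_row(),
        "control_counts": c_counts.as_row(),
        "table": contingency.table.tolist(),
        "columns": list(contingency.columns),
        "statistic": contingency.statistic,
        "p_value": contingency.p_value,
        "method": contingency.method,
    }
    with open(out / "enrichment.json", "w") as fh:
        json.dump(report["enrichment"], fh, indent=2)
    with open(out / "run_log.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report
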