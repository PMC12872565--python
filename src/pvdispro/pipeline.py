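"""End-to-end orchestration: ingest -> dedupe -> cohorts -> analyses -> outputs.

A run is driven by a YAML/JSON configuration naming the input line
listing(s), the PT->SOC mapping file (default: the bundled synthetic
mapping), the exposure ingredient sets, and analysis options.  Outputs
are delimited-text tables, two forest plots (SOC level and
muscle-PT level), and a plain-text run log with per-stage counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import yaml

from . import __version__
from .cohorts import (
    ExposureCohorts,
    ExposureConfig,
    build_cohorts,
    demographics_table,
    render_demographics,
)
from .disproportionality import (
    RORResult,
    ZeroCellPolicy,
    analyze_by_soc,
    analyze_mr_pts,
    results_frame,
)
from .icsr import ICSR
from .line_listing import (
    DEFAULT_DIALECT,
    DEFAULT_EEA_CODES,
    LineListingDialect,
    deduplicate,
    read_line_listing,
)
from .meddra import MedDRAMap, MRPTSet, default_meddra_map, load_meddra_map
from .outcomes import severity_comparison_table
from .subgroup import sex_subgroup_analysis, stratify_by_sex

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    inputs: list[str]
    out_dir: str = "pvdispro_run"
    mapping_file: str | None = None
    mapping_version: str = ""
    target_ingredients: list[str] | None = None
    comparator_ingredients: list[str] | None = None
    eea_country_codes: list[str] | None = None
    mr_pts: list[str] | None = None
    delimiter: str = ","
    multivalue_separator: str = ";"
    zero_cell_policy: str = "haldane_half"
    yates: bool = False

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text(encoding="utf-8")
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"{path}: run config must be a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def dialect(self) -> LineListingDialect:
        return LineListingDialect(
            delimiter=self.delimiter, multivalue_separator=self.multivalue_separator
        )

    def exposure(self) -> ExposureConfig:
        kwargs = {}
        if self.target_ingredients:
            kwargs["target_ingredients"] = frozenset(self.target_ingredients)
        if self.comparator_ingredients:
            kwargs["comparator_ingredients"] = frozenset(self.comparator_ingredients)
        return ExposureConfig(**kwargs)

    def meddra(self) -> MedDRAMap:
        if self.mapping_file:
            return load_meddra_map(self.mapping_file, version_label=self.mapping_version)
        return default_meddra_map()

    def mrpt_set(self) -> MRPTSet:
        if self.mr_pts:
            return MRPTSet(pts=frozenset(self.mr_pts))
        return MRPTSet()

    def policy(self) -> ZeroCellPolicy:
        return ZeroCellPolicy(self.zero_cell_policy)


def render_forest(results: list[RORResult], path: str | Path, title: str = "") -> None:
    """Forest plot: one row per result, log-scaled axis, reference at ROR=1.

    Rows are sorted by descending ROR top-to-bottom; zero-cell-corrected
    rows are drawn as open markers.  Layout is deterministic for a given
    input.
    """
    if not results:
        raise ValueError("render_forest requires at least one result")
    ordered = sorted(results, key=lambda r: r.ror, reverse=True)
    height = max(2.0, 0.4 * len(ordered) + 1.2)
    fig, ax = plt.subplots(figsize=(7.5, height))
    ys = range(len(ordered), 0, -1)
    for y, r in zip(ys, ordered):
        colour = "#1f4e79"
        ax.plot([r.ci_low, r.ci_high], [y, y], color=colour, lw=1.4)
        ax.plot(
            [r.ror],
            [y],
            marker="s",
            color="white" if r.zero_cell_corrected else colour,
            markeredgecolor=colour,
            markersize=6,
        )
    ax.axvline(1.0, color="0.35", ls="--", lw=1)
    ax.set_xscale("log")
    ax.set_yticks(list(ys))
    ax.set_yticklabels(
        [f"{r.event_label}  {r.ror:.2f} ({r.ci_low:.2f}-{r.ci_high:.2f})" for r in ordered],
        fontsize=8,
    )
    ax.set_xlabel("Reporting odds ratio (95% CI, log scale)")
    if title:
        ax.set_title(title, fontsize=10)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def analyse_reports(
    reports: list[ICSR],
    config: RunConfig,
    out_dir: Path,
    log_lines: list[str],
) -> None:
    """Shared back half of a run: cohorts through outputs."""
    meddra = config.meddra()
    mrpts = config.mrpt_set()
    policy = config.policy()
    cohorts = build_cohorts(reports, config.exposure())
    log_lines.append(
        "cohorts: target_only=%d comparator_only=%d both=%d neither=%d"
        % (
            len(cohorts.target_only),
            len(cohorts.comparator_only),
            len(cohorts.both),
            len(cohorts.neither),
        )
    )

    demo = demographics_table(cohorts, meddra)
    demo.to_csv(out_dir / "demographics.csv", index=False)
    render_demographics(demo).to_csv(out_dir / "demographics_wide.csv")

    soc_results = analyze_by_soc(cohorts, meddra, zero_cell_policy=policy, yates=config.yates)
    results_frame(soc_results).to_csv(out_dir / "ror_soc.csv", index=False)
    render_forest(soc_results, out_dir / "forest_soc.svg", title="Reporting odds ratios by SOC")

    mrpt_results = analyze_mr_pts(cohorts, mrpts, zero_cell_policy=policy, yates=config.yates)
    results_frame(mrpt_results).to_csv(out_dir / "ror_mrpt.csv", index=False)
    render_forest(
        mrpt_results, out_dir / "forest_mrpt.svg", title="Reporting odds ratios, muscle-related PTs"
    )

    severity_comparison_table(cohorts, mrpts).to_csv(out_dir / "outcome_severity.csv", index=False)

    strata = stratify_by_sex(cohorts)
    by_sex = sex_subgroup_analysis(strata, meddra, mrpts, zero_cell_policy=policy)
    frames = []
    for sex, analyses in by_sex.items():
        for level, results in analyses.items():
            frame = results_frame(results)
            frame.insert(0, "sex", sex.value)
            frame.insert(1, "level", level)
            frames.append(frame)
    if frames:
        import pandas as pd

        pd.concat(frames, ignore_index=True).to_csv(out_dir / "ror_by_sex.csv", index=False)
    log_lines.append(
        "analysis rows: soc=%d mr_pt=%d sex_strata=%d"
        % (len(soc_results), len(mrpt_results), len(by_sex))
    )


def run_pipeline(config_path: str | Path) -> Path:
    """Execute a full run from a configuration file; returns the output dir."""
    config = RunConfig.from_file(config_path)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_lines = [f"pvdispro {__version__}", f"config: {config_path}"]

    reports: list[ICSR] = []
    eea = frozenset(config.eea_country_codes) if config.eea_country_codes else DEFAULT_EEA_CODES
    for source in config.inputs:
        batch = read_line_listing(source, dialect=config.dialect(), eea_country_codes=eea)
        log_lines.append(f"ingest {source}: {len(batch)} reports")
        reports.extend(batch)
    reports, removed = deduplicate(reports)
    log_lines.append(f"deduplicate: removed {removed}, kept {len(reports)}")

    analyse_reports(reports, config, out_dir, log_lines)

    (out_dir / "run_log.txt").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    (out_dir / "run_config.json").write_text(
        json.dumps(config.__dict__, indent=2, default=str), encoding="utf-8"
    )
    logger.info("run complete: %s", out_dir)
    return out_dir
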