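"""Orchestration: run the full analysis end to end and write the report
bundle.

The pipeline never computes anything the library modules cannot — it
loads or generates inputs, calls the analysis functions, and writes the
reports.  Each report CSV starts with a comment block embedding the
resolved configuration so that any output file is self-describing, and
a run log records config, seed and software version.  Outputs are
deterministic: identical config and inputs produce byte-identical
report files.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .agreement import group_agreement, optimal_scenario, score_matrix
from .catalog import DEFAULT_CATALOG, AECPGCatalog
from .citizen_scoring import CitizenScoringConfig, read_survey_table, score_citizen_subgroups
from .errors import AECPGError, ValidationError
from .matrices import (
    DesireMatrix,
    SupplyMatrix,
    cumulative_desire_counts,
    group_desire_summary,
    read_desire_matrix,
    read_supply_matrix,
    write_desire_matrix,
    write_supply_matrix,
)
from .sensitivity import run_sensitivity
from .synthetic import (
    SyntheticConfig,
    generate_desire_matrix,
    generate_supply_matrix,
    generate_survey_table,
)

__all__ = ["RunConfig", "run_analysis", "simulate"]

logger = logging.getLogger("aecpg_align")


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of one analysis run.

    Exactly one of ``desire_path`` and ``synthetic`` must be given; the
    supply matrix likewise comes from ``supply_path`` or the synthetic
    config.  ``survey_path`` optionally adds citizen records scored from
    a percentage table.
    """

    out_dir: Path
    desire_path: Path | None = None
    supply_path: Path | None = None
    survey_path: Path | None = None
    synthetic: SyntheticConfig | None = None
    citizen_scoring: CitizenScoringConfig = field(default_factory=CitizenScoringConfig)
    overall_mode: str = "stakeholder_mean"
    boundary_policy: str = "agreement_closed_at_80"
    catalog: AECPGCatalog = DEFAULT_CATALOG

    def __post_init__(self) -> None:
        object.__setattr__(self, "out_dir", Path(self.out_dir))
        if (self.desire_path is None) == (self.synthetic is None):
            raise ValidationError(
                "exactly one of a desire matrix file and a synthetic config "
                "must be supplied"
            )
        if self.desire_path is None and self.supply_path is None and not (
            self.synthetic and self.synthetic.scenarios
        ):
            raise ValidationError("no supply matrix: give a file or scenario config")

    def describe(self) -> list[str]:
        lines = [
            f"aecpg-align {__version__}",
            f"overall_mode: {self.overall_mode}",
            f"boundary_policy: {self.boundary_policy}",
            f"citizen thresholds: t_mid={self.citizen_scoring.t_mid} "
            f"t_high={self.citizen_scoring.t_high}",
        ]
        if self.desire_path:
            lines.append(f"desire matrix: {self.desire_path}")
        if self.supply_path:
            lines.append(f"supply matrix: {self.supply_path}")
        if self.survey_path:
            lines.append(f"citizen survey: {self.survey_path}")
        if self.synthetic:
            lines.append(f"synthetic seed: {self.synthetic.seed}")
        return lines


def _write_report(df: pd.DataFrame, path: Path, header_lines: list[str],
                  index: bool = False) -> None:
    buf = io.StringIO()
    for line in header_lines:
        buf.write(f"# {line}\n")
    df.to_csv(buf, index=index)
    path.write_text(buf.getvalue())


def _load_inputs(cfg: RunConfig) -> tuple[DesireMatrix, SupplyMatrix]:
    if cfg.desire_path is not None:
        matrix = read_desire_matrix(cfg.desire_path, cfg.catalog)
        if cfg.survey_path is not None:
            table = read_survey_table(cfg.survey_path, cfg.catalog)
            citizens = score_citizen_subgroups(table, cfg.citizen_scoring)
            matrix = DesireMatrix(
                catalog=cfg.catalog,
                records=tuple(matrix.records) + tuple(citizens),
                citizen_groups=matrix.citizen_groups,
            )
    else:
        matrix = generate_desire_matrix(cfg.synthetic)
    if cfg.supply_path is not None:
        supply = read_supply_matrix(cfg.supply_path, cfg.catalog)
    else:
        supply = generate_supply_matrix(cfg.synthetic)
    return matrix, supply


def run_analysis(cfg: RunConfig) -> dict[str, Path]:
    """Run the full analysis and write the report bundle into ``out_dir``.

    Writes per-stakeholder agreement, the group desire summary, the
    supply matrix echo, the baseline + sensitivity agreement report, the
    cumulative desire counts, and a run log.  On any validation failure
    the partially written bundle is removed before the error propagates.
    """
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    header = cfg.describe()
    try:
        matrix, supply = _load_inputs(cfg)
        logger.info(
            "analysing %d stakeholders in %d groups against %d scenarios",
            len(matrix), len(matrix.groups), len(supply),
        )

        detail = pd.concat(
            [score_matrix(matrix, s, cfg.boundary_policy) for s in supply.scenarios],
            ignore_index=True,
        )
        p = cfg.out_dir / "stakeholder_agreement.csv"
        _write_report(detail, p, header)
        written["stakeholder_agreement"] = p

        summary = group_desire_summary(matrix)
        p = cfg.out_dir / "group_desire_summary.csv"
        _write_report(summary.table().reset_index(), p, header)
        written["group_desire_summary"] = p

        p = cfg.out_dir / "supply_matrix.csv"
        _write_report(supply.to_frame(), p, header)
        written["supply_matrix"] = p

        report = run_sensitivity(
            matrix, supply, cfg.overall_mode, cfg.boundary_policy
        )
        p = cfg.out_dir / "agreement_report.csv"
        _write_report(report.to_frame(), p, header)
        written["agreement_report"] = p

        counts = cumulative_desire_counts(matrix).rename_axis("aecpg").reset_index()
        p = cfg.out_dir / "cumulative_desire.csv"
        _write_report(counts, p, header)
        written["cumulative_desire"] = p

        best = optimal_scenario(supply, matrix, cfg.overall_mode)
        log = cfg.out_dir / "run_log.txt"
        log.write_text(
            "\n".join(
                header
                + [
                    f"stakeholders: {len(matrix)}",
                    f"groups: {len(matrix.groups)}",
                    f"scenarios: {len(supply)}",
                    f"optimal scenario: {best}",
                ]
            )
            + "\n"
        )
        written["run_log"] = log
        logger.info("optimal scenario: %s", best)
        return written
    except AECPGError:
        for path in written.values():
            path.unlink(missing_ok=True)
        raise


def simulate(cfg: SyntheticConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate synthetic input files (desire, supply, survey) into a folder."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    matrix = generate_desire_matrix(cfg)
    p = out / "desire_matrix.csv"
    write_desire_matrix(matrix, p)
    written["desire_matrix"] = p
    if cfg.scenarios:
        supply = generate_supply_matrix(cfg)
        p = out / "supply_matrix.csv"
        write_supply_matrix(supply, p)
        written["supply_matrix"] = p
    if cfg.citizens is not None:
        table = generate_survey_table(cfg)
        p = out / "survey_table.csv"
        table.data.to_csv(p)
        written["survey_table"] = p
    logger.info("wrote %d synthetic input file(s) to %s", len(written), out)
    return written
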