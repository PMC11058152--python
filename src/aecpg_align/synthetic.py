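"""Seeded generators for desire matrices, supply matrices, source codings
and survey tables.

The generators emulate the statistical structure the agreement analysis
assumes, so the whole pipeline is testable without the original
stakeholder-level data:

* organisation stakeholders express desire for good *i* with a per-group
  probability p_gi; a desired good is *central* to the vision
  (weight 2) with probability c_gi and otherwise mentioned (weight 1);
  an undesired good is still mentioned (weight 1, score 0) with
  probability m_gi and otherwise unmentioned (weight 0).  Records that
  would mention nothing (total weight 0) are redrawn, mirroring the
  inclusion criterion that a vision must touch at least one good;
* citizen subgroups are produced by drawing a survey percentage table
  around a configured true profile (Gaussian noise, clipped to
  [0, 100]) and pushing it through the two-threshold scorer;
* scenario supply vectors draw each level from configured
  probabilities over {0, 0.5, 1}.

Every generator takes a single seeded :class:`numpy.random.Generator`
stream derived from ``cfg.seed``; identical config ⇒ bit-identical
output.  :func:`dutch_case_config` ships the study-shaped configuration:
ten groups of sizes 6, 5, 6, 18, 7, 13, 3, 3, 9 and 13 (83 stakeholders)
whose desire probabilities equal the published group means, and citizens
drawn around the published survey percentages.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .catalog import DEFAULT_CATALOG, AECPGCatalog
from .case_study import DUTCH_CITIZEN_SURVEY, DUTCH_GROUP_PROFILES, DUTCH_SUPPLY
from .citizen_scoring import CitizenScoringConfig, SurveyTable, score_citizen_subgroups
from .errors import ValidationError
from .matrices import DesireMatrix, DesireRecord, ScenarioSupply, SupplyMatrix
from .meta_scenario import SourceCoding

__all__ = [
    "GroupSpec",
    "CitizenSpec",
    "ScenarioSpec",
    "SyntheticConfig",
    "generate_desire_matrix",
    "generate_supply_matrix",
    "generate_survey_table",
    "generate_source_codings",
    "dutch_case_config",
]

_MAX_REDRAWS = 1000


def _per_good(value: float | Sequence[float] | Mapping[str, float],
              catalog: AECPGCatalog, what: str) -> np.ndarray:
    """Broadcast a scalar / sequence / name-keyed mapping to a per-good vector."""
    if isinstance(value, Mapping):
        try:
            arr = np.array([float(value[name]) for name in catalog])
        except KeyError as e:
            raise ValidationError(f"{what}: missing probability for good {e}") from None
    elif np.isscalar(value):
        arr = np.full(len(catalog), float(value))
    else:
        arr = np.asarray(value, dtype=float)
        if arr.size != len(catalog):
            raise ValidationError(f"{what}: expected {len(catalog)} values")
    if (arr < 0).any() or (arr > 1).any():
        raise ValidationError(f"{what}: probabilities must lie in [0, 1]")
    return arr


@dataclass(frozen=True)
class GroupSpec:
    """One organisation stakeholder group.

    desire_prob / centrality_prob / mention_prob may each be a scalar,
    per-good sequence, or name-keyed mapping.
    """

    label: str
    n: int
    desire_prob: object
    centrality_prob: object = 0.3
    mention_prob: object = 0.2

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError(f"group {self.label!r}: n must be >= 1")


@dataclass(frozen=True)
class CitizenSpec:
    """Citizen subgroups generated via a noisy survey + threshold scorer.

    ``profile`` maps subgroup label -> {good: true percentage}; a flat
    {good: pct} mapping is broadcast to ``n_subgroups`` anonymous rows.
    """

    profile: Mapping[str, Mapping[str, float]] | Mapping[str, float]
    n_subgroups: int = 13
    questions_per_aecpg: int = 2
    noise_sd: float = 3.0
    scoring: CitizenScoringConfig = field(default_factory=CitizenScoringConfig)

    def subgroup_profiles(self, catalog: AECPGCatalog) -> dict[str, np.ndarray]:
        first = next(iter(self.profile.values()))
        if isinstance(first, Mapping):
            items = self.profile.items()
        else:
            items = [
                (f"subgroup_{k + 1:02d}", self.profile)
                for k in range(self.n_subgroups)
            ]
        out = {}
        for label, prof in items:
            arr = np.array([float(prof[name]) for name in catalog])
            if (arr < 0).any() or (arr > 100).any():
                raise ValidationError(
                    f"citizen profile {label!r}: percentages outside [0, 100]"
                )
            out[str(label)] = arr
        return out


@dataclass(frozen=True)
class ScenarioSpec:
    """One scenario: probabilities of supply levels 0, 0.5 and 1."""

    scenario_id: str
    level_probs: tuple[float, float, float]

    def __post_init__(self) -> None:
        p = np.asarray(self.level_probs, dtype=float)
        if p.size != 3 or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValidationError(
                f"scenario {self.scenario_id!r}: level_probs must be three "
                "non-negative numbers summing to 1"
            )


@dataclass(frozen=True)
class SyntheticConfig:
    seed: int
    groups: tuple[GroupSpec, ...] = ()
    citizens: CitizenSpec | None = None
    scenarios: tuple[ScenarioSpec, ...] = ()
    catalog: AECPGCatalog = DEFAULT_CATALOG

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        """Load a config from a YAML file (see the methods note for the schema)."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        groups = tuple(
            GroupSpec(
                label=g["label"],
                n=int(g["n"]),
                desire_prob=g["desire_prob"],
                centrality_prob=g.get("centrality_prob", 0.3),
                mention_prob=g.get("mention_prob", 0.2),
            )
            for g in raw.get("groups", [])
        )
        citizens = None
        if "citizens" in raw and raw["citizens"] is not None:
            c = raw["citizens"]
            scoring = CitizenScoringConfig(**c.get("scoring", {}))
            citizens = CitizenSpec(
                profile=c["profile"],
                n_subgroups=int(c.get("n_subgroups", 13)),
                questions_per_aecpg=int(c.get("questions_per_aecpg", 2)),
                noise_sd=float(c.get("noise_sd", 3.0)),
                scoring=scoring,
            )
        scenarios = tuple(
            ScenarioSpec(
                scenario_id=s["scenario_id"],
                level_probs=tuple(float(x) for x in s["level_probs"]),
            )
            for s in raw.get("scenarios", [])
        )
        return cls(
            seed=int(raw["seed"]),
            groups=groups,
            citizens=citizens,
            scenarios=scenarios,
        )


def _rng(cfg: SyntheticConfig, stream: str) -> np.random.Generator:
    # independent substream per artifact so generating one never shifts
    # another; crc32 is stable across processes (str hash is not)
    return np.random.default_rng([cfg.seed, zlib.crc32(stream.encode())])


def generate_survey_table(cfg: SyntheticConfig,
                          rng: np.random.Generator | None = None) -> SurveyTable:
    """Draw a subgroup × question percentage table around the true profile."""
    if cfg.citizens is None:
        raise ValidationError("config has no citizens section")
    spec = cfg.citizens
    rng = rng if rng is not None else _rng(cfg, "survey")
    profiles = spec.subgroup_profiles(cfg.catalog)
    columns = [
        f"{name}:q{q + 1}"
        for name in cfg.catalog
        for q in range(spec.questions_per_aecpg)
    ]
    rows = {}
    for label, true_pct in profiles.items():
        noisy = np.repeat(true_pct, spec.questions_per_aecpg)
        if spec.noise_sd > 0:
            noisy = noisy + rng.normal(0.0, spec.noise_sd, size=noisy.size)
        rows[label] = np.clip(noisy, 0.0, 100.0)
    df = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
    df.index.name = "subgroup"
    return SurveyTable(catalog=cfg.catalog, data=df)


def _draw_organisation(
    label: str,
    stakeholder_id: str,
    p: np.ndarray,
    c: np.ndarray,
    m: np.ndarray,
    rng: np.random.Generator,
) -> DesireRecord:
    for _ in range(_MAX_REDRAWS):
        d = (rng.random(p.size) < p).astype(float)
        central = rng.random(p.size) < c
        mentioned = rng.random(p.size) < m
        w = np.where(d == 1, np.where(central, 2, 1), np.where(mentioned, 1, 0))
        if w.sum() > 0:
            return DesireRecord(
                stakeholder_id=stakeholder_id,
                group=label,
                scores=d.astype(object),
                weights=w.astype(object),
            )
    raise ValidationError(
        f"group {label!r}: could not draw a record mentioning at least one "
        "good; desire and mention probabilities are (near) zero everywhere"
    )


def generate_desire_matrix(cfg: SyntheticConfig) -> DesireMatrix:
    """Generate a full desire matrix (organisation groups + citizens)."""
    if not cfg.groups and cfg.citizens is None:
        raise ValidationError("config defines neither groups nor citizens")
    rng = _rng(cfg, "desire")
    records: list[DesireRecord] = []
    for g in cfg.groups:
        p = _per_good(g.desire_prob, cfg.catalog, f"group {g.label!r} desire_prob")
        c = _per_good(g.centrality_prob, cfg.catalog, f"group {g.label!r} centrality_prob")
        m = _per_good(g.mention_prob, cfg.catalog, f"group {g.label!r} mention_prob")
        if p.max() == 0 and m.max() == 0:
            raise ValidationError(
                f"group {g.label!r}: desire_prob and mention_prob are all zero; "
                "no record can satisfy the at-least-one-good inclusion criterion"
            )
        slug = "".join(ch if ch.isalnum() else "_" for ch in g.label.lower())
        for k in range(g.n):
            records.append(
                _draw_organisation(g.label, f"{slug}_{k + 1:02d}", p, c, m, rng)
            )
    if cfg.citizens is not None:
        table = generate_survey_table(cfg, rng=_rng(cfg, "survey"))
        records.extend(score_citizen_subgroups(table, cfg.citizens.scoring))
    citizen_groups = (
        (cfg.citizens.scoring.group_label,) if cfg.citizens is not None else ("Citizens",)
    )
    return DesireMatrix(
        catalog=cfg.catalog, records=tuple(records), citizen_groups=citizen_groups
    )


def generate_supply_matrix(cfg: SyntheticConfig) -> SupplyMatrix:
    """Draw each scenario's supply levels from its level probabilities."""
    if not cfg.scenarios:
        raise ValidationError("config defines no scenarios")
    rng = _rng(cfg, "supply")
    levels = np.array([0.0, 0.5, 1.0])
    scenarios = tuple(
        ScenarioSupply(
            scenario_id=s.scenario_id,
            supply=rng.choice(levels, size=len(cfg.catalog),
                              p=np.asarray(s.level_probs, dtype=float)).astype(object),
        )
        for s in cfg.scenarios
    )
    return SupplyMatrix(catalog=cfg.catalog, scenarios=scenarios)


def generate_source_codings(
    cfg: SyntheticConfig, theme: str, n_sources: int = 3
) -> list[SourceCoding]:
    """Draw per-source codings for one theme from that scenario's levels.

    Useful for exercising meta-scenario synthesis: the sources share the
    level probabilities of the configured scenario named *theme*.
    """
    spec = next((s for s in cfg.scenarios if s.scenario_id == theme), None)
    if spec is None:
        raise ValidationError(f"no configured scenario named {theme!r}")
    rng = _rng(cfg, f"codings:{theme}")
    levels = np.array([0.0, 0.5, 1.0])
    return [
        SourceCoding(
            source_id=f"{theme}_source_{k + 1}",
            theme=theme,
            supply=rng.choice(levels, size=len(cfg.catalog),
                              p=np.asarray(spec.level_probs, dtype=float)).astype(object),
        )
        for k in range(n_sources)
    ]


def dutch_case_config(seed: int = 0) -> SyntheticConfig:
    """Study-shaped configuration: 83 stakeholders in 10 groups, 9 goods.

    Organisation desire probabilities equal the published per-group mean
    desire scores; citizens are drawn around the published survey
    percentages (13 subgroups, 2 questions per good, 3 pp noise) and
    scored with the default 30/60 thresholds.  Scenario level
    probabilities are the empirical level frequencies of the four
    published supply vectors.
    """
    groups = tuple(
        GroupSpec(label=label, n=n, desire_prob=means)
        for label, (n, means) in DUTCH_GROUP_PROFILES.items()
    )
    citizens = CitizenSpec(profile=DUTCH_CITIZEN_SURVEY)
    scenarios = []
    for sid, vals in DUTCH_SUPPLY.items():
        arr = np.asarray(vals, dtype=float)
        probs = tuple(float(np.mean(arr == lv)) for lv in (0.0, 0.5, 1.0))
        scenarios.append(ScenarioSpec(scenario_id=sid, level_probs=probs))
    return SyntheticConfig(
        seed=seed, groups=groups, citizens=citizens, scenarios=tuple(scenarios)
    )
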