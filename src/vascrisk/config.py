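"""Run configuration: YAML schema, defaults and validation.

Every analysis constant (significance level alpha = 0.05, DEG threshold
FDR <= 0.10, 10-fold CV, 150 bootstraps, 100 randomization seeds) lives here
as a config default rather than a hard-coded literal, so sensitivity analyses
only touch the YAML.  ``validate_config`` reports the *complete* list of
violations, not the first failure.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

from .classify import MODEL_NAMES
from .data import DataError
from .risk import DECISION_RULES
from .synth import QUERY_PROFILES, SyntheticConfig

__all__ = ["AnalysisParams", "QueryParams", "ClassifyParams", "RunConfig",
           "ConfigFileError", "load_config", "validate_config"]

SCHEMA_VERSION = 1


class ConfigFileError(DataError):
    """Configuration file is unparseable or invalid; carries all violations."""

    def __init__(self, errors: list[str]):
        super().__init__("; ".join(errors))
        self.errors = errors


@dataclass
class AnalysisParams:
    alpha: float = 0.05                 # gene p-filter and shared-pathway significance
    min_genes: int = 5                  # minimum genes per pathway correlation
    decision_rule: str = "mann_whitney"
    rho_threshold: float = 0.0
    fdr_threshold: float = 0.10         # DEG threshold
    correction: str | None = None       # None or "bh" across pathways


@dataclass
class QueryParams:
    profiles: list[str] = field(default_factory=lambda: ["risk_like", "neutral"])
    n_randomizations: int = 100         # gene-name randomization control seeds
    files: list[dict[str, str]] = field(default_factory=list)  # [{path, cell_type}]


@dataclass
class ClassifyParams:
    side_effects: list[str] | None = None   # None = all labelled side effects
    models: list[str] = field(default_factory=lambda: list(MODEL_NAMES))
    k_folds: int = 10
    n_boot: int = 150
    min_fraction: float = 0.10
    max_features: int = 2000
    enabled: bool = True


@dataclass
class RunConfig:
    seed: int = 42
    output_dir: str = "vascrisk_out"
    cell_types: list[str] = field(default_factory=lambda: ["EC", "SMC"])
    database_dir: str | None = None     # None -> generate synthetically
    gmt_path: str | None = None         # required when database_dir is given
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    queries: QueryParams = field(default_factory=QueryParams)
    classify: ClassifyParams = field(default_factory=ClassifyParams)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


def _build(cls, mapping: dict[str, Any], errors: list[str], context: str):
    known = {f.name for f in fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        errors.append(f"{context}: unknown key(s) {sorted(unknown)}")
    kwargs = {k: v for k, v in mapping.items() if k in known}
    if cls is SyntheticConfig and "pathway_size_range" in kwargs:
        kwargs["pathway_size_range"] = tuple(kwargs["pathway_size_range"])
    try:
        return cls(**kwargs)
    except TypeError as exc:
        errors.append(f"{context}: {exc}")
        return cls()


def _parse(raw: dict[str, Any], errors: list[str]) -> RunConfig:
    raw = dict(raw or {})
    version = raw.pop("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        errors.append(f"unsupported schema_version {version} (supported: {SCHEMA_VERSION})")
    sections = {
        "synthetic": SyntheticConfig,
        "analysis": AnalysisParams,
        "queries": QueryParams,
        "classify": ClassifyParams,
    }
    kwargs: dict[str, Any] = {}
    for name, cls in sections.items():
        block = raw.pop(name, {})
        if not isinstance(block, dict):
            errors.append(f"{name}: must be a mapping")
            block = {}
        kwargs[name] = _build(cls, block, errors, name)
    top_known = {"seed", "output_dir", "cell_types", "database_dir", "gmt_path"}
    unknown = set(raw) - top_known
    if unknown:
        errors.append(f"unknown top-level key(s): {sorted(unknown)}")
    for key in top_known & set(raw):
        kwargs[key] = raw[key]
    return RunConfig(**kwargs)


def _validate(cfg: RunConfig) -> list[str]:
    errors: list[str] = []
    a = cfg.analysis
    if not (0 < a.alpha < 1):
        errors.append(f"analysis.alpha must be in (0,1), got {a.alpha}")
    if a.min_genes < 3:
        errors.append(f"analysis.min_genes must be >= 3, got {a.min_genes}")
    if a.decision_rule not in DECISION_RULES:
        errors.append(f"analysis.decision_rule must be one of {DECISION_RULES}, got {a.decision_rule!r}")
    if not (0 < a.fdr_threshold <= 1):
        errors.append(f"analysis.fdr_threshold must be in (0,1], got {a.fdr_threshold}")
    if a.correction not in (None, "bh"):
        errors.append(f"analysis.correction must be null or 'bh', got {a.correction!r}")
    for ct in cfg.cell_types:
        if ct not in ("EC", "SMC"):
            errors.append(f"cell_types entries must be EC or SMC, got {ct!r}")
    if not cfg.cell_types:
        errors.append("cell_types must be non-empty")
    for profile in cfg.queries.profiles:
        if profile not in QUERY_PROFILES:
            errors.append(f"queries.profiles entries must be in {QUERY_PROFILES}, got {profile!r}")
    if cfg.queries.n_randomizations < 0:
        errors.append("queries.n_randomizations must be >= 0")
    for entry in cfg.queries.files:
        if not isinstance(entry, dict) or "path" not in entry or "cell_type" not in entry:
            errors.append(f"queries.files entries need 'path' and 'cell_type': {entry!r}")
        elif not Path(entry["path"]).exists():
            errors.append(f"queries.files path does not exist: {entry['path']}")
    c = cfg.classify
    for m in c.models:
        if m not in MODEL_NAMES:
            errors.append(f"classify.models entries must be in {MODEL_NAMES}, got {m!r}")
    if c.k_folds < 2:
        errors.append("classify.k_folds must be >= 2")
    if c.n_boot < 1:
        errors.append("classify.n_boot must be >= 1")
    if not (0 < c.min_fraction <= 1):
        errors.append("classify.min_fraction must be in (0,1]")
    if cfg.database_dir is not None:
        dbdir = Path(cfg.database_dir)
        if not (dbdir / "metadata.tsv").exists():
            errors.append(f"database_dir has no metadata.tsv: {cfg.database_dir}")
        if cfg.gmt_path is None:
            errors.append("gmt_path is required when database_dir is given")
    if cfg.gmt_path is not None and not Path(cfg.gmt_path).exists():
        errors.append(f"gmt_path does not exist: {cfg.gmt_path}")
    errors.extend(f"synthetic.{v}" for v in cfg.synthetic.violations())
    return errors


def validate_config(path: str | Path) -> tuple[RunConfig | None, list[str]]:
    """Parse and validate a YAML run configuration.

    Returns ``(config, [])`` when valid, ``(None, violations)`` otherwise —
    all violations are collected, not just the first.
    """
    path = Path(path)
    if not path.exists():
        return None, [f"config file not found: {path}"]
    try:
        raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        return None, [f"unparseable YAML: {exc}"]
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        return None, ["top level of the config must be a mapping"]
    errors: list[str] = []
    cfg = _parse(raw, errors)
    errors.extend(_validate(cfg))
    if errors:
        return None, errors
    return cfg, []


def load_config(path: str | Path) -> RunConfig:
    """Like :func:`validate_config` but raising :class:`ConfigFileError`."""
    cfg, errors = validate_config(path)
    if cfg is None:
        raise ConfigFileError(errors)
    return cfg
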