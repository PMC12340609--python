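"""Structured run configuration for the command-line interface.

A single YAML (or JSON-compatible) file describes the input table, the
model, the stressor contrast, the null models to test and the uncertainty
method. All defaults (gradient step fraction 1e-4, 10,000 Krinsky-Robb
draws, 95% level) can be overridden and are echoed into the run manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .design import Term
from .interaction_estimators import ContrastSpec, Stressor
from .model_layer import CovariateProfile, ModelSpec
from .null_models import NULL_MODELS
from .uncertainty import UncertaintyMethod


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    input: str
    model: ModelSpec
    contrast: ContrastSpec
    null_models: tuple[str, ...] = ("AD",)
    uncertainty: UncertaintyMethod = field(default_factory=UncertaintyMethod)
    output_dir: str = "stressorint-out"
    verbosity: int = 1
    raw: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if not self.null_models:
            raise ConfigError("select at least one null model")
        bad = [m for m in self.null_models if m not in NULL_MODELS]
        if bad:
            raise ConfigError(f"unknown null model(s) {bad!r}")

    def manifest(self, seed=None, extra: dict | None = None) -> dict:
        from . import __version__

        canon = json.dumps(self.raw, sort_keys=True, default=str)
        return {"config_sha256": hashlib.sha256(canon.encode()).hexdigest(),
                "package_version": __version__,
                "seed": seed if seed is not None else self.uncertainty.seed,
                **(extra or {})}


def _require(d: dict, key: str, where: str):
    if key not in d:
        raise ConfigError(f"missing field {key!r} in {where}")
    return d[key]


def _parse_terms(items) -> tuple[Term, ...]:
    terms = []
    for i, t in enumerate(items):
        kind = _require(t, "kind", f"model.terms[{i}]")
        cols = tuple(_require(t, "columns", f"model.terms[{i}]"))
        try:
            terms.append(Term(kind, cols, int(t.get("k", 10))))
        except ValueError as exc:
            raise ConfigError(f"model.terms[{i}]: {exc}") from exc
    return tuple(terms)


def _parse_stressor(d: dict, where: str) -> Stressor:
    try:
        return Stressor(column=_require(d, "column", where),
                        kind=d.get("kind", "factor"),
                        control=d.get("control"), stress=d.get("stress"))
    except ValueError as exc:
        raise ConfigError(f"{where}: {exc}") from exc


def config_from_dict(cfg: dict) -> RunConfig:
    model_d = _require(cfg, "model", "config")
    try:
        model = ModelSpec(response=_require(model_d, "response", "model"),
                          terms=_parse_terms(model_d.get("terms", [])),
                          family=model_d.get("family", "gaussian"),
                          link=model_d.get("link", "canonical"),
                          trials=model_d.get("trials"))
    except ValueError as exc:
        raise ConfigError(f"model: {exc}") from exc
    con_d = _require(cfg, "contrast", "config")
    prof_d = con_d.get("profile", {"mode": "observed"})
    try:
        profile = CovariateProfile(prof_d.get("mode", "observed"),
                                   prof_d.get("values"))
        contrast = ContrastSpec(
            stressor_a=_parse_stressor(_require(con_d, "stressor_a", "contrast"),
                                       "contrast.stressor_a"),
            stressor_b=_parse_stressor(_require(con_d, "stressor_b", "contrast"),
                                       "contrast.stressor_b"),
            step_fraction=float(con_d.get("step_fraction", 1e-4)),
            profile=profile)
    except ValueError as exc:
        raise ConfigError(f"contrast: {exc}") from exc
    unc_d = cfg.get("uncertainty", {})
    try:
        unc = UncertaintyMethod(kind=unc_d.get("kind", "kr"),
                                draws=int(unc_d.get("draws", 10_000)),
                                replicates=int(unc_d.get("replicates", 2_000)),
                                level=float(unc_d.get("level", 0.95)),
                                seed=int(unc_d.get("seed", 0)),
                                covariance_variant=unc_d.get("covariance_variant"))
    except ValueError as exc:
        raise ConfigError(f"uncertainty: {exc}") from exc
    return RunConfig(input=_require(cfg, "input", "config"), model=model,
                     contrast=contrast,
                     null_models=tuple(cfg.get("null_models", ["AD"])),
                     uncertainty=unc,
                     output_dir=cfg.get("output_dir", "stressorint-out"),
                     verbosity=int(cfg.get("verbosity", 1)), raw=cfg)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"config file {path} did not parse to a mapping")
    return config_from_dict(cfg)


def validate_columns(config: RunConfig, columns) -> None:
    cols = set(columns)
    need = {config.model.response}
    if config.model.trials:
        need.add(config.model.trials)
    for t in config.model.terms:
        need.update(t.columns)
    need.update({config.contrast.stressor_a.column,
                 config.contrast.stressor_b.column})
    missing = sorted(need - cols)
    if missing:
        raise ConfigError(f"column(s) {missing!r} referenced by the config "
                          "are missing from the input table")
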