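"""End-to-end pipeline: (optional) simulation -> feature extraction ->
ranking -> separability -> balanced classification, driven by one validated
config mapping.

Every output embeds the SHA-256 hash of the canonical config serialization,
so artifacts are traceable to the exact parameters that produced them, and a
re-run with an identical config writes byte-identical JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as lio
from .denoise import FilterSpec, NLMParams
from .evaluate import ModelSpec, SplitSpec, run_experiment
from .features import assemble_feature_table
from .select import mrmr_rank, relieff_rank
from .separability import separability_report
from .simulate import DEFAULT_NOISE, NoiseSpec, generate_cohort

__all__ = ["ConfigError", "PipelineConfig", "run_pipeline"]

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """The pipeline config violates its schema."""


class _Required:
    def __repr__(self):
        return "<required>"


_REQUIRED = _Required()

#: section -> {key: default}; _REQUIRED marks a mandatory key
_SCHEMA = {
    "seed": 0,
    "scheme": "four",
    "subset": "all38",
    "band": [0.5, 50.0],
    "paths": {"records_dir": _REQUIRED, "diagnostics": _REQUIRED,
              "output_dir": _REQUIRED},
    "simulate": {"n_per_class": 0, "classes": ["AFIB", "SB", "SR", "ST"],
                 "wander_amplitude": DEFAULT_NOISE.wander_amplitude,
                 "wander_freq": DEFAULT_NOISE.wander_freq,
                 "powerline_amplitude": DEFAULT_NOISE.powerline_amplitude,
                 "broadband_sd": DEFAULT_NOISE.broadband_sd},
    "denoise": {"enabled": True, "low": 0.5, "high": 50.0, "order": 4,
                "span_seconds": 1.5, "patch_half_width": 10,
                "search_half_width": 500, "h_scale": 0.6},
    "select": {"k": 15, "n_bins": 10, "relieff_neighbors": 10},
    "split": {"mode": "balanced_holdout", "n_test_per_class": 50,
              "test_fraction": None, "repetitions": 10},
    "models": ["bagged_trees"],
}


def _merge(section: str, defaults: dict, given: dict) -> dict:
    unknown = set(given) - set(defaults)
    if unknown:
        raise ConfigError(f"unknown key(s) in '{section}': {sorted(unknown)}")
    out = dict(defaults)
    out.update(given)
    missing = [k for k, v in out.items() if v is _REQUIRED]
    if missing:
        raise ConfigError(f"missing required key(s) in '{section}': {missing}")
    return out


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    """Validated pipeline configuration; build from a mapping with
    :meth:`from_dict` (unknown keys are rejected before any compute)."""

    seed: int
    scheme: str
    subset: str
    band: tuple
    paths: dict
    simulate: dict
    denoise: dict
    select: dict
    split: dict
    models: tuple

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        unknown = set(raw) - set(_SCHEMA)
        if unknown:
            raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
        sections = {}
        for key, default in _SCHEMA.items():
            if isinstance(default, dict):
                sections[key] = _merge(key, default, raw.get(key, {}))
            else:
                sections[key] = raw.get(key, default)
        lio.get_scheme(sections["scheme"])  # fail fast on bad scheme
        for fam in sections["models"]:
            ModelSpec(fam)
        cfg = cls(
            seed=int(sections["seed"]),
            scheme=sections["scheme"],
            subset=sections["subset"],
            band=tuple(sections["band"]),
            paths=sections["paths"],
            simulate=sections["simulate"],
            denoise=sections["denoise"],
            select=sections["select"],
            split=sections["split"],
            models=tuple(sections["models"]),
        )
        SplitSpec(
            mode=cfg.split["mode"],
            n_test_per_class=cfg.split["n_test_per_class"],
            test_fraction=cfg.split["test_fraction"],
            seed=0, repetitions=cfg.split["repetitions"],
        )
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["band"] = list(self.band)
        d["models"] = list(self.models)
        return d

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    def stage_seed(self, stage: int) -> int:
        """Counter-based per-stage seed derivation from the global seed."""
        ss = np.random.SeedSequence(entropy=self.seed, spawn_key=(stage,))
        return int(ss.generate_state(1)[0] % (2 ** 31))


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, sort_keys=True, indent=2) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; return the manifest (also written to the output dir).

    Deterministic given the config: all randomness is seeded via counter-based
    derivation from the global seed, and no timestamps enter the outputs.
    """
    out_dir = Path(config.paths["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    records_dir = Path(config.paths["records_dir"])
    diagnostics_path = Path(config.paths["diagnostics"])
    artifacts = {}

    try:
        # stage 0: simulation (optional)
        if config.simulate["n_per_class"] > 0:
            noise = NoiseSpec(
                wander_amplitude=config.simulate["wander_amplitude"],
                wander_freq=config.simulate["wander_freq"],
                powerline_amplitude=config.simulate["powerline_amplitude"],
                broadband_sd=config.simulate["broadband_sd"],
            )
            records, diags = generate_cohort(
                config.simulate["n_per_class"], config.simulate["classes"],
                seed=config.stage_seed(0), noise=noise,
            )
            for rec in records:
                lio.write_record(rec, records_dir)
            lio.write_diagnostics(diags, diagnostics_path)
        # stage 1: load
        records = [lio.load_record(p) for p in sorted(records_dir.glob("*.csv"))]
        if not records:
            raise FileNotFoundError(f"no record CSVs under {records_dir}")
        diagnostics = lio.load_diagnostics(diagnostics_path)
        scheme = lio.get_scheme(config.scheme)
        # stage 2: features
        dn = config.denoise
        table = assemble_feature_table(
            records, diagnostics, scheme,
            denoise=dn["enabled"], band=config.band,
            filter_spec=FilterSpec(dn["low"], dn["high"], dn["order"]),
            span_seconds=dn["span_seconds"],
            nlm_params=NLMParams(dn["patch_half_width"], dn["search_half_width"],
                                 dn["h_scale"]),
        )
        features_csv = out_dir / "features.csv"
        with features_csv.open("w") as fh:
            fh.write(f"# config_hash: {config.config_hash}\n")
            table.to_csv(fh)
        artifacts["features"] = features_csv.name
        # stage 3: rankings
        n_feat = table.shape[1] - 1
        k = min(config.select["k"], n_feat)
        min_class = int(table["label"].value_counts().min())
        neighbors = min(config.select["relieff_neighbors"], min_class - 1)
        for name, ranked in (
            ("mrmr", mrmr_rank(table, k, n_bins=config.select["n_bins"])),
            ("relieff", relieff_rank(table, k, n_neighbors=neighbors)),
        ):
            path = out_dir / f"ranking_{name}.json"
            _write_json(path, {
                "config_hash": config.config_hash, "method": ranked.method,
                "k": ranked.k, "names": list(ranked.names),
                "scores": list(ranked.scores),
            })
            artifacts[f"ranking_{name}"] = path.name
        # stage 4: separability
        report = separability_report(table, config.scheme)
        sep_path = out_dir / "separability.json"
        _write_json(sep_path, {"config_hash": config.config_hash,
                               **report.to_dict()})
        artifacts["separability"] = sep_path.name
        # stage 5: classification
        split = SplitSpec(
            mode=config.split["mode"],
            n_test_per_class=config.split["n_test_per_class"],
            test_fraction=config.split["test_fraction"],
            seed=config.stage_seed(5),
            repetitions=config.split["repetitions"],
        )
        results = run_experiment(
            table, config.subset, split, [ModelSpec(f) for f in config.models],
        )
        eval_path = out_dir / "evaluation.json"
        _write_json(eval_path, {
            "config_hash": config.config_hash,
            "subset": config.subset,
            "results": {fam: res.to_dict() for fam, res in results.items()},
        })
        artifacts["evaluation"] = eval_path.name
    except Exception as exc:
        raise RuntimeError(
            f"pipeline aborted (completed artifacts: {sorted(artifacts)}): {exc}"
        ) from exc

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash,
        "artifacts": artifacts,
        "n_records": len(records),
        "n_rows": int(table.shape[0]),
    }
    _write_json(out_dir / "manifest.json", manifest)
    return manifest
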