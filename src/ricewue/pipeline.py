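"""End-to-end driver: simulate/load -> effects -> PLS-VIP -> CMTI -> report.

Every output file carries a comment header with the package version, a hash
of the resolved configuration and the seed, so any run can be identified and
reproduced.  All stages are deterministic given the seed; a stage failure
removes the partial outputs it created and aborts with the stage name.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .cmti import CMTIConfig, run_cmti, vip_from_table
from .errors import ConfigError, RiceWueError
from .simulate import SimulationConfig, TraitEffect, generate_dataset
from .stats import effect_sizes_by_trait, effect_sizes_frame, pca_from_table
from .table import TraitTable, read_trait_table, write_trait_table

log = logging.getLogger("ricewue")


@dataclass
class PipelineConfig:
    """Run-level configuration (loadable from YAML via :meth:`from_yaml`)."""

    seed: int = 0
    out_dir: str = "ricewue_run"
    input_table: str | None = None  # None: simulate a dataset
    simulation: dict = field(default_factory=dict)  # SimulationConfig overrides
    prioritisation: str = "cohens_d"
    d_threshold: float = 0.8
    vip_threshold: float = 1.0
    normalization_mode: str = "plasticity"
    effect_level: str = "genotype_mean"
    pls_components: int = 2
    pls_response: str = "delta13C"

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown pipeline config key(s): {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (the output location
        does not change what is computed)."""
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")
        text = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:12]


def _simulation_config(cfg: PipelineConfig) -> SimulationConfig:
    overrides = dict(cfg.simulation)
    if "trait_effects" in overrides:
        overrides["trait_effects"] = {
            t: TraitEffect(**spec) for t, spec in overrides["trait_effects"].items()
        }
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(overrides) - known
    if unknown:
        raise ConfigError(f"unknown simulation key(s): {sorted(unknown)}")
    overrides.setdefault("seed", cfg.seed)
    return SimulationConfig(**overrides)


def _header(cfg: PipelineConfig) -> str:
    return f"# ricewue {__version__} config={cfg.config_hash()} seed={cfg.seed}\n"


def _write_with_header(path: Path, header: str, body: str) -> None:
    path.write_text(header + body)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis chain and write report files to
    ``config.out_dir``.  Returns the run summary (also written as JSON)."""
    # validate all stage parameters before touching the filesystem
    cmti_cfg = CMTIConfig(
        prioritisation=config.prioritisation,
        d_threshold=config.d_threshold,
        vip_threshold=config.vip_threshold,
        normalization_mode=config.normalization_mode,
        effect_level=config.effect_level,
        pls_components=config.pls_components,
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = _header(config)
    written: list[Path] = []

    def stage(name: str):
        log.info("stage %s", name)
        return name

    current = stage("input")
    try:
        truth = None
        if config.input_table is not None:
            table = read_trait_table(config.input_table)
        else:
            sim_cfg = _simulation_config(config)
            table, truth = generate_dataset(sim_cfg)
            table_path = out / "table.csv"
            write_trait_table(table, table_path)
            _prepend(table_path, header)
            written.append(table_path)
            truth_path = out / "truth.json"
            truth_path.write_text(json.dumps(truth.to_dict(), indent=2, sort_keys=True))
            written.append(truth_path)

        current = stage("effects")
        effects = effect_sizes_by_trait(table, level=config.effect_level)
        eff_path = out / "effects.csv"
        _write_with_header(eff_path, header, effect_sizes_frame(effects).to_csv(index=False))
        written.append(eff_path)

        current = stage("pls_vip")
        vip = None
        if config.pls_response in table.traits:
            vip = vip_from_table(table, response=config.pls_response, config=cmti_cfg)
            vip_body = "trait,vip,selected\n" + "".join(
                f"{t},{v!r},{t in vip.selected}\n" for t, v in sorted(vip.scores.items())
            )
            vip_path = out / "vip.csv"
            _write_with_header(vip_path, header, vip_body)
            written.append(vip_path)
        elif config.prioritisation == "pls_vip":
            raise ConfigError(
                f"pls_vip prioritisation requires response trait "
                f"{config.pls_response!r} in the table"
            )

        current = stage("cmti")
        result = run_cmti(table, config=cmti_cfg, effects=effects, vip=vip)
        cmti_path = out / "cmti.csv"
        _write_with_header(
            cmti_path, header, result.table.to_csv(index=True, index_label="genotype")
        )
        written.append(cmti_path)

        current = stage("pca")
        pca = pca_from_table(table)
        pca_payload = {
            "eigenvalues": [float(v) for v in pca.eigenvalues],
            "proportions_pct": [float(v) for v in pca.proportions],
            "traits": list(pca.loadings.index),
        }
        pca_path = out / "pca.json"
        pca_path.write_text(json.dumps(pca_payload, indent=2))
        written.append(pca_path)

        current = stage("report")
        summary = {
            "version": __version__,
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "n_observations": len(table),
            "traits_used": result.traits_used,
            "prioritisation": config.prioritisation,
            "normalization_mode": config.normalization_mode,
            "pc1_pct_variance": float(pca.proportions[0]),
            "classes": result.table["strategy_class"].value_counts().to_dict(),
        }
        if truth is not None and config.normalization_mode == "plasticity":
            assigned = result.table["strategy_class"].to_dict()
            hits = sum(
                assigned.get(g) == c for g, c in truth.class_assignment.items()
            )
            summary["classification_accuracy_pct"] = (
                100.0 * hits / len(truth.class_assignment)
            )
        summary_path = out / "summary.json"
        summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
        written.append(summary_path)
        return summary
    except RiceWueError as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise RiceWueError(f"stage {current!r} failed: {exc}") from exc


def _prepend(path: Path, header: str) -> None:
    path.write_text(header + path.read_text())
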