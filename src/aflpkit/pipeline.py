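"""End-to-end pipeline: simulate/ingest -> score -> distance -> tree ->
haplotypes -> chi-square, driven by one config and one global seed.

Per-stage seeds are derived deterministically from the global seed, so any
stage can be rerun in isolation with identical results.  Tabular outputs
carry ``# seed=... config_sha256=...`` header lines; strict interchange
formats (Newick, PHYLIP) stay comment-free and are hashed into the run
manifest JSON instead.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as aio
from .cluster import BootstrapConfig, bootstrap_support, count_significant_clusters
from .distance import distance_matrix
from .errors import AflpkitError, ValidationError
from .haplotypes import assign_haplotypes, sharing_summary
from .scoring import ScoringThresholds, filter_loci, quality_report, score_matrix
from .simulate import SimulationConfig, config_to_dict, simulate
from .stats import ContingencyTable, chi2_contingency, chi2_goodness_of_fit

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything one run needs; loadable from a YAML mapping."""

    output_dir: str = "aflpkit_out"
    seed: int = 0
    intensities: str | None = None      # input CSV; exclusive with simulation
    metadata: str | None = None
    simulation: SimulationConfig | None = None
    thresholds: ScoringThresholds = field(default_factory=ScoringThresholds)
    control_isolate: str | None = None
    max_conflict: float = 0.05
    require_polymorphic: bool = True
    require_control_consistent: bool = True
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        sim = raw.pop("simulation", None)
        thr = raw.pop("thresholds", None)
        boot = raw.pop("bootstrap", None)
        cfg = cls(**raw)
        if sim is not None:
            if "areas" in sim:
                sim["areas"] = tuple(sim["areas"])
            if "crops" in sim:
                sim["crops"] = tuple(sim["crops"])
            cfg.simulation = SimulationConfig(**sim)
        if thr is not None:
            cfg.thresholds = ScoringThresholds(**thr)
        if boot is not None:
            cfg.bootstrap = BootstrapConfig(**boot)
        return cfg

    def to_dict(self) -> dict:
        d = {
            "output_dir": self.output_dir,
            "seed": self.seed,
            "intensities": self.intensities,
            "metadata": self.metadata,
            "simulation": config_to_dict(self.simulation) if self.simulation else None,
            "thresholds": {"t_high": self.thresholds.t_high, "t_low": self.thresholds.t_low},
            "control_isolate": self.control_isolate,
            "max_conflict": self.max_conflict,
            "require_polymorphic": self.require_polymorphic,
            "require_control_consistent": self.require_control_consistent,
            "bootstrap": {
                "n_replicates": self.bootstrap.n_replicates,
                "seed": self.bootstrap.seed,
                "support_threshold": self.bootstrap.support_threshold,
            },
        }
        return d

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("output_dir", None)  # where outputs land does not change them
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage_seed(global_seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute every stage and write the artifact files.

    Returns a mapping of artifact name to path.  Any stage failure is
    re-raised with the stage name prefixed; files already written by
    earlier stages are listed as partial output in the raised message.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    header = [f"seed={config.seed}", f"config_sha256={chash}"]
    artifacts: dict[str, Path] = {}
    stage = "setup"
    try:
        stage = "input"
        control = config.control_isolate
        if config.simulation is not None:
            sim_cfg = config.simulation
            if sim_cfg.seed != _stage_seed(config.seed, "simulate"):
                sim_cfg = SimulationConfig(
                    **{**config_to_dict(sim_cfg), "seed": _stage_seed(config.seed, "simulate"),
                       "areas": sim_cfg.areas, "crops": sim_cfg.crops}
                )
            table, truth = simulate(sim_cfg)
            metadata = truth.metadata.set_index("isolate_id")
            if control is None:
                control = truth.control_isolate
            artifacts["intensities"] = out / "intensities.csv"
            aio.write_intensity_table(table, artifacts["intensities"], header_lines=header)
            artifacts["metadata"] = out / "metadata.csv"
            aio.write_metadata(metadata, artifacts["metadata"], header_lines=header)
        else:
            if config.intensities is None:
                raise ValidationError("config must give either intensities or simulation")
            if not Path(config.intensities).exists():
                raise ValidationError(f"intensity file not found: {config.intensities}")
            table = aio.read_intensity_table(config.intensities)
            metadata = None
            if config.metadata is not None:
                if not Path(config.metadata).exists():
                    raise ValidationError(f"metadata file not found: {config.metadata}")
                metadata = aio.read_metadata(config.metadata)

        stage = "score"
        matrix, quality = score_matrix(
            table, config.thresholds, control_isolate=control, metadata=metadata
        )
        artifacts["locus_quality"] = out / "locus_quality.tsv"
        aio._write_csv(quality_report(quality), artifacts["locus_quality"], sep="\t",
                       header_lines=header)
        filtered = filter_loci(
            matrix,
            quality,
            max_conflict=config.max_conflict,
            require_polymorphic=config.require_polymorphic,
            require_control_consistent=config.require_control_consistent,
        )
        artifacts["matrix"] = out / "matrix.tsv"
        aio.write_binary_matrix(filtered, artifacts["matrix"], header_lines=header)

        stage = "distance"
        dm = distance_matrix(filtered)
        artifacts["distances"] = out / "distances.phy"
        name_map = _phylip_names(filtered.isolate_ids)
        aio.write_phylip_distance(dm, artifacts["distances"], name_map=name_map)

        stage = "tree"
        boot = config.bootstrap
        boot = BootstrapConfig(
            n_replicates=boot.n_replicates,
            seed=_stage_seed(config.seed, "bootstrap"),
            support_threshold=boot.support_threshold,
        )
        tree, consensus = bootstrap_support(filtered, boot)
        artifacts["tree"] = out / "tree.nwk"
        aio.write_newick(tree, artifacts["tree"])
        artifacts["consensus"] = out / "consensus.nwk"
        aio.write_newick(consensus, artifacts["consensus"])
        n_signif = count_significant_clusters(tree, boot.support_threshold)

        stage = "haplotypes"
        assignment = assign_haplotypes(filtered)
        summary = None
        if metadata is not None:
            summary = sharing_summary(assignment, metadata)
            artifacts["haplotypes"] = out / "haplotypes.tsv"
            aio._write_csv(summary.composition, artifacts["haplotypes"], sep="\t",
                           header_lines=header)

        stage = "stats"
        stats_rows = []
        if metadata is not None:
            sub = metadata.loc[list(filtered.isolate_ids)]
            ct = ContingencyTable.from_metadata(sub.reset_index())
            if (ct.counts.sum(axis=0) > 0).all() and (ct.counts.sum(axis=1) > 0).all():
                res = chi2_contingency(ct)
                stats_rows.append(("area_by_crop_contingency", res))
            for margin, axis in (("area", 1), ("crop", 0)):
                counts = ct.counts.sum(axis=axis)
                res = chi2_goodness_of_fit(counts, "uniform")
                stats_rows.append((f"{margin}_uniform_gof", res))
        report = pd.DataFrame(
            [
                {"test": name, "statistic": r.statistic, "df": r.df, "p_value": r.p_value}
                for name, r in stats_rows
            ]
        )
        artifacts["chi_square"] = out / "chi_square.tsv"
        aio._write_csv(report, artifacts["chi_square"], sep="\t", header_lines=header)

        stage = "manifest"
        manifest = {
            "config": config.to_dict(),
            "config_sha256": chash,
            "seed": config.seed,
            "n_isolates": filtered.n_isolates,
            "n_loci_scored": matrix.n_loci,
            "n_loci_retained": filtered.n_loci,
            "n_haplotypes": assignment.n_haplotypes,
            "n_shared_haplotypes": summary.n_shared if summary else None,
            "n_significant_clusters": n_signif,
            "support_threshold": boot.support_threshold,
            "files": {k: _sha256(p) for k, p in artifacts.items()},
        }
        artifacts["manifest"] = out / "manifest.json"
        artifacts["manifest"].write_text(json.dumps(manifest, indent=2) + "\n")
    except AflpkitError as exc:
        partial = sorted(str(p) for p in artifacts.values())
        raise AflpkitError(
            f"pipeline stage {stage!r} failed: {exc}"
            + (f" (partial outputs: {partial})" if partial else "")
        ) from exc
    return artifacts


def _phylip_names(ids) -> dict[str, str]:
    """Rename ids longer than 10 characters to a deterministic short form."""
    name_map = {}
    used = {i for i in ids if len(i) <= 10}
    for i in ids:
        if len(i) <= 10:
            continue
        k = 0
        while True:
            cand = f"{i[:7]}_{k:02d}"
            if cand not in used:
                break
            k += 1
        used.add(cand)
        name_map[i] = cand
    return name_map


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()
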