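"""End-to-end orchestration: profiles -> networks -> tensor -> clusters.

A run is described by a :class:`RunConfig` (mirroring the CLI flags, and
loadable from a YAML file); :func:`run_full` chains the stages, writes the
cluster JSON/TSV outputs, and records a manifest with every parameter, the
seed, and input checksums so the run can be reproduced byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .inclusion import (
    InclusionMatrix,
    build_inclusion_matrix,
    exons_from_transcripts,
    read_transcript_table,
)
from .miner import FrequentCoSplicingCluster, MiningConfig, mine_all
from .network import (
    NetworkTensor,
    assemble_tensor,
    correlation_network,
    read_tensor_manifest,
    write_tensor_manifest,
)

__all__ = [
    "RunConfig",
    "Diagnostic",
    "StageError",
    "validate_inputs",
    "run_full",
    "clusters_to_json",
    "clusters_from_json",
    "write_clusters",
]

logger = logging.getLogger(__name__)

_MODES = ("build-networks", "mine", "simulate", "enrich", "full")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything a run needs; unset paths are simply skipped downstream."""

    mode: str = "full"
    transcript_tables: list[str] = field(default_factory=list)
    inclusion_matrices: list[str] = field(default_factory=list)
    tensor_manifest: str | None = None
    gmt: str | None = None
    universe: str | None = None
    exon_gene_map: str | None = None
    out_dir: str = "cosplice_out"
    seed: int = 0
    percentile: float = 80.0
    min_samples: int = 6
    min_overlap: int = 4
    edge_transform: str = "clamp"
    p_threshold: float = 0.05
    max_term_size: int | None = None
    baseline_reps: int = 1000
    mining: MiningConfig = field(default_factory=MiningConfig)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        """Load a config file; keyword overrides win over the file."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        mining_raw = raw.pop("mining", {})
        raw.update({k: v for k, v in overrides.items() if v is not None})
        mining = MiningConfig(**mining_raw)
        if "seed" in raw:
            mining = dataclasses.replace(mining, seed=int(raw["seed"]))
        return cls(mining=mining, **raw)


@dataclass(frozen=True)
class Diagnostic:
    level: str  # "error" | "warning"
    code: str
    message: str


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def validate_inputs(config: RunConfig) -> list[Diagnostic]:
    """Non-mutating consistency checks; returns machine-readable diagnostics."""
    diags: list[Diagnostic] = []

    def err(code: str, msg: str) -> None:
        diags.append(Diagnostic("error", code, msg))

    for path in [
        *config.transcript_tables,
        *config.inclusion_matrices,
        *(p for p in (config.tensor_manifest, config.gmt, config.universe,
                      config.exon_gene_map) if p),
    ]:
        if not Path(path).exists():
            err("missing-file", f"input path does not exist: {path}")
    if config.mode == "mine" and not config.tensor_manifest:
        err("missing-tensor-manifest", "mine mode requires a tensor manifest")

    for path in config.inclusion_matrices:
        if not Path(path).exists():
            continue
        try:
            mat = InclusionMatrix.from_tsv(path)
        except ValueError as exc:
            err("range", f"{path}: {exc}")
            continue
        vals = mat.values.to_numpy()
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            err("range", f"{path}: inclusion values outside [0, 1]")

    if config.tensor_manifest and Path(config.tensor_manifest).exists():
        try:
            tensor = read_tensor_manifest(config.tensor_manifest)
            tensor.validate()
        except ValueError as exc:
            err("symmetry" if "symmetric" in str(exc) else "range", str(exc))

    if config.exon_gene_map and Path(config.exon_gene_map).exists():
        mapping = read_exon_gene_map(config.exon_gene_map)
        for path in config.inclusion_matrices:
            if not Path(path).exists():
                continue
            try:
                mat = InclusionMatrix.from_tsv(path)
            except ValueError:
                continue
            unknown = set(mat.exon_ids) - set(mapping)
            if unknown:
                diags.append(
                    Diagnostic(
                        "warning",
                        "cross-reference",
                        f"{path}: {len(unknown)} exon id(s) absent from the "
                        f"exon-gene map (e.g. {sorted(unknown)[0]!r})",
                    )
                )
    return diags


def read_exon_gene_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV exon_id -> gene_id (header optional)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if list(df.iloc[0]) == ["exon_id", "gene_id"]:
        df = df.iloc[1:]
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def clusters_to_json(clusters: Sequence[FrequentCoSplicingCluster]) -> list[dict]:
    return [
        {
            "cluster_id": f"cluster{j:04d}",
            "exon_ids": sorted(c.exon_ids),
            "network_ids": sorted(c.network_ids),
            "heaviness": c.heaviness,
            "recurrence": c.recurrence,
            "objective": c.objective,
        }
        for j, c in enumerate(clusters)
    ]


def clusters_from_json(path: str | Path) -> list[FrequentCoSplicingCluster]:
    with open(path) as fh:
        raw = json.load(fh)
    return [
        FrequentCoSplicingCluster(
            exon_ids=frozenset(d["exon_ids"]),
            network_ids=frozenset(d["network_ids"]),
            heaviness=float(d["heaviness"]),
            objective=float(d.get("objective", 0.0)),
        )
        for d in raw
    ]


def write_clusters(
    clusters: Sequence[FrequentCoSplicingCluster], out_dir: str | Path
) -> tuple[Path, Path]:
    """Write the cluster JSON plus a one-row-per-exon-membership TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    json_path = out_dir / "clusters.json"
    records = clusters_to_json(clusters)
    with open(json_path, "w") as fh:
        json.dump(records, fh, indent=2, sort_keys=True)
        fh.write("\n")
    rows = [
        (rec["cluster_id"], exon, rec["heaviness"], rec["recurrence"])
        for rec in records
        for exon in rec["exon_ids"]
    ]
    tsv_path = out_dir / "cluster_memberships.tsv"
    pd.DataFrame(
        rows, columns=["cluster_id", "exon_id", "heaviness", "recurrence"]
    ).to_csv(tsv_path, sep="\t", index=False)
    return json_path, tsv_path


def _build_networks_stage(config: RunConfig) -> NetworkTensor:
    matrices: list[tuple[str, InclusionMatrix]] = []
    for path in config.transcript_tables:
        try:
            transcripts, samples = read_transcript_table(path)
            exons = exons_from_transcripts(transcripts)
            mat = build_inclusion_matrix(
                transcripts,
                exons,
                samples,
                percentile=config.percentile,
                min_samples=config.min_samples,
            )
        except Exception as exc:
            raise StageError("inclusion", f"{path}: {exc}") from exc
        matrices.append((Path(path).stem, mat))
    for path in config.inclusion_matrices:
        try:
            matrices.append((Path(path).stem, InclusionMatrix.from_tsv(path)))
        except Exception as exc:
            raise StageError("inclusion", f"{path}: {exc}") from exc
    if not matrices:
        raise StageError("networks", "no profile inputs configured")
    try:
        networks = [
            correlation_network(
                mat,
                min_overlap=config.min_overlap,
                dataset_id=name,
                edge_transform=config.edge_transform,
            )
            for name, mat in matrices
        ]
        return assemble_tensor(networks)
    except Exception as exc:
        raise StageError("networks", str(exc)) from exc


def run_full(config: RunConfig) -> dict:
    """Execute the configured pipeline and return the run manifest.

    Stages: inclusion profiles -> co-splicing networks -> tensor -> mining
    (-> enrichment when an annotation collection is configured).  The same
    config and seed reproduce byte-identical cluster output.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "mode": config.mode,
        "seed": config.seed,
        "parameters": {
            **{
                k: v
                for k, v in dataclasses.asdict(config).items()
                if k not in ("mining",)
            },
            "mining": dataclasses.asdict(config.mining),
        },
        "inputs": {},
        "outputs": {},
        "stages": [],
    }
    for path in [
        *config.transcript_tables,
        *config.inclusion_matrices,
        *(p for p in (config.tensor_manifest, config.gmt, config.universe,
                      config.exon_gene_map) if p),
    ]:
        if Path(path).exists():
            manifest["inputs"][str(path)] = _sha256(path)

    if config.tensor_manifest:
        try:
            tensor = read_tensor_manifest(config.tensor_manifest)
        except Exception as exc:
            raise StageError("tensor", str(exc)) from exc
    else:
        tensor = _build_networks_stage(config)
        write_tensor_manifest(tensor, out_dir / "networks")
        manifest["outputs"]["tensor_manifest"] = str(
            out_dir / "networks" / "tensor_manifest.tsv"
        )
    manifest["stages"].append("tensor")

    mining = dataclasses.replace(config.mining, seed=config.seed)
    try:
        clusters = mine_all(tensor, mining)
    except Exception as exc:
        raise StageError("mine", str(exc)) from exc
    json_path, tsv_path = write_clusters(clusters, out_dir)
    manifest["outputs"]["clusters_json"] = str(json_path)
    manifest["outputs"]["clusters_tsv"] = str(tsv_path)
    manifest["stages"].append("mine")

    if config.gmt and config.universe and config.exon_gene_map:
        from .enrichment import (
            AnnotationCollection,
            baseline_fold_ratio,
            enrich_clusters,
            read_gene_list,
            read_gmt,
        )

        try:
            collection = AnnotationCollection(
                name=Path(config.gmt).stem,
                terms=read_gmt(config.gmt),
                universe=read_gene_list(config.universe),
                p_threshold=config.p_threshold,
                max_term_size=config.max_term_size,
            )
            mapping = read_exon_gene_map(config.exon_gene_map)
            results = enrich_clusters(clusters, mapping, collection)
            pd.DataFrame([dataclasses.asdict(r) for r in results]).to_csv(
                out_dir / "enrichment.tsv", sep="\t", index=False
            )
            manifest["outputs"]["enrichment_tsv"] = str(out_dir / "enrichment.tsv")
            if clusters:
                pct_real, pct_random, fold = baseline_fold_ratio(
                    clusters,
                    mapping,
                    collection,
                    reps=config.baseline_reps,
                    seed=config.seed,
                )
                manifest["enrichment_summary"] = {
                    "pct_real": pct_real,
                    "pct_random": pct_random,
                    "fold_ratio": fold,
                }
        except Exception as exc:
            raise StageError("enrich", str(exc)) from exc
        manifest["stages"].append("enrich")

    manifest_path = out_dir / "run_manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest["outputs"]["manifest"] = str(manifest_path)
    return manifest
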