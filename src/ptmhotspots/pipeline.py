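"""End-to-end orchestration: catalog -> hotspots -> projection -> scoring -> stats.

A run is fully described by a :class:`RunConfig` (loadable from a TOML
file); all inputs are local files, outputs land in one directory together
with a manifest recording input checksums, the configuration echo, and the
package version, so a run is reproducible byte-for-byte from the manifest
plus its inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .catalog import (
    annotate_known_function,
    deduplicate,
    filter_records,
    read_function_table,
    read_ptm_table,
)
from .errors import ConfigurationError
from .hotspots import build_hotspots, write_hotspot_table
from .msa import read_alignment
from .projection import (
    assign_unresolved_sasa,
    map_alignment_to_structure,
    read_disorder_annotation,
    write_projection,
)
from .scoring import FPWeights, compute_fp, rank_hotspots, write_score_table
from .stats import (
    known_fraction_vs_threshold,
    multi_type_distribution,
    separation_report,
)
from .structure import detect_interface_residues, read_structure, shrake_rupley_sasa

logger = logging.getLogger(__name__)

ALL_STAGES = ("hotspots", "project", "score", "stats")
DEFAULT_THRESHOLDS = (0.0, 1.0, 2.0, 5.0, 10.0, 20.0, 50.0)


@dataclass
class RunConfig:
    """Everything one pipeline run needs; paths are validated up front."""

    ptm_table: str
    alignment: str
    out_dir: str
    structure: str | None = None
    target_member: str | None = None
    target_chain: str | None = None
    function_table: str | None = None
    disorder: str | None = None
    id_map: str | None = None  # TSV protein_id -> member_id; identity if absent
    family_id: str = "family"
    weights: FPWeights = field(default_factory=FPWeights)
    probe_radius: float = 1.4
    n_points: int = 960
    contact_cutoff: float = 5.0
    group_by: str = "family"  # or "pooled"
    keep_experimental_only: bool = True
    assume_terminal_disorder: bool = False
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        weights = FPWeights(**data.pop("weights", {}))
        if "thresholds" in data:
            data["thresholds"] = tuple(float(t) for t in data["thresholds"])
        return cls(weights=weights, **data)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        return out

    def validate(self, stages=ALL_STAGES) -> None:
        needed = [("ptm_table", self.ptm_table), ("alignment", self.alignment)]
        if "project" in stages or "score" in stages or "stats" in stages:
            needed.append(("structure", self.structure))
            if not self.target_member or not self.target_chain:
                raise ConfigurationError(
                    "target_member and target_chain are required for projection/scoring"
                )
        for name, value in needed:
            if value is None:
                raise ConfigurationError(f"config field {name!r} is required")
            if not Path(value).exists():
                raise ConfigurationError(f"{name} path does not exist: {value}")
        for name, value in (
            ("function_table", self.function_table),
            ("disorder", self.disorder),
            ("id_map", self.id_map),
        ):
            if value is not None and not Path(value).exists():
                raise ConfigurationError(f"{name} path does not exist: {value}")


def _sha256(path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            digest.update(block)
    return digest.hexdigest()


def _read_id_map(path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        for line in fh:
            if line.strip():
                protein_id, member_id = line.rstrip("\n").split("\t")[:2]
                out[protein_id] = member_id
    return out


def run_pipeline(config: RunConfig, stages=ALL_STAGES) -> dict:
    """Run the requested stages and return the run manifest.

    Stage names: ``hotspots`` (catalog + MSA layering), ``project``
    (structure mapping, SASA, interfaces, projection artifacts), ``score``
    (FP + ranking), ``stats`` (separation reports, threshold curve,
    multi-type composition).  Later stages imply the earlier ones.
    """
    stages = tuple(stages)
    config.validate(stages)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    records = read_ptm_table(config.ptm_table)
    records = filter_records(records, keep_experimental_only=config.keep_experimental_only)
    records = deduplicate(records)
    if config.function_table:
        records = annotate_known_function(
            records, read_function_table(config.function_table)
        )
    alignment = read_alignment(config.alignment, family_id=config.family_id)
    id_map = _read_id_map(config.id_map) if config.id_map else None
    hotspots = build_hotspots(alignment, records, id_map=id_map)
    hotspot_path = out_dir / "hotspots.tsv"
    write_hotspot_table(hotspots, hotspot_path)
    outputs["hotspots"] = str(hotspot_path)

    results = None
    if {"project", "score", "stats"} & set(stages):
        structure = read_structure(config.structure)
        chain = structure.chain(config.target_chain)
        target_map = map_alignment_to_structure(alignment, config.target_member, chain)
        sasa = shrake_rupley_sasa(
            chain, probe_radius=config.probe_radius, n_points=config.n_points
        )
        interfaces = detect_interface_residues(structure, config.contact_cutoff)
        disorder_by_member = (
            read_disorder_annotation(config.disorder) if config.disorder else {}
        )
        member_seq = alignment.ungapped(config.target_member)
        residue_info = assign_unresolved_sasa(
            member_seq,
            target_map,
            sasa,
            disorder=disorder_by_member.get(config.target_member),
            interface_residues=interfaces,
            burial_threshold=config.weights.burial_threshold,
            assume_terminal_disorder=config.assume_terminal_disorder,
        )
        proj_paths = write_projection(structure, target_map, hotspots, out_dir)
        outputs.update({f"projection_{k}": str(v) for k, v in proj_paths.items()})

        if {"score", "stats"} & set(stages):
            c2r = alignment.column_to_residue[config.target_member]
            scored = []
            for h in hotspots:
                info = residue_info.get(c2r.get(h.column, -1))
                res = compute_fp(h, info, weights=config.weights)
                if res is not None:
                    scored.append(res)
            results = rank_hotspots(scored, group_by=config.group_by)
            score_path = out_dir / "scores.tsv"
            write_score_table(results, score_path)
            outputs["scores"] = str(score_path)

    if "stats" in stages and results:
        labels = [r.known_function for r in results]
        stats_block: dict = {}
        if any(labels) and not all(labels):
            factors = {
                "total_ptms": [float(r.hotspot.total_ptms) for r in results],
                "ptm_res_con": [r.prc for r in results],
                "total_sasa": [r.relative_sasa for r in results],
                "fp": [r.fp for r in results],
            }
            stats_block["separation"] = {
                name: separation_report(vals, labels, factor=name).to_dict()
                for name, vals in factors.items()
            }
            stats_block["threshold_curve"] = [
                p.to_dict() for p in known_fraction_vs_threshold(results, config.thresholds)
            ]
        else:
            logger.warning("need both known and unknown hotspots for separation stats")
        stats_block["multi_type"] = multi_type_distribution(hotspots).to_dict()
        stats_path = out_dir / "stats.json"
        stats_path.write_text(json.dumps(stats_block, indent=2) + "\n", encoding="utf-8")
        outputs["stats"] = str(stats_path)

    input_paths = {
        name: value
        for name, value in (
            ("ptm_table", config.ptm_table),
            ("function_table", config.function_table),
            ("alignment", config.alignment),
            ("structure", config.structure),
            ("disorder", config.disorder),
            ("id_map", config.id_map),
        )
        if value
    }
    manifest = {
        "version": __version__,
        "stages": list(stages),
        "config": config.to_dict(),
        "inputs": {name: {"path": p, "sha256": _sha256(p)} for name, p in input_paths.items()},
        "outputs": outputs,
        "n_records": len(records),
        "n_hotspots": len(hotspots),
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
    return manifest
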