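"""Readers, writers and run configuration.

Segment tables are tab-separated with a header; genetic coordinates must be
declared in centimorgans through the column-name suffix ``_cM`` (readers
never silently coerce units).  Binned count tables are written as a TSV
(``bin_low``, ``bin_high``, ``count``) with a JSON sidecar carrying the
metadata needed to re-derive expectations.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .demography import (
    SamplingSpec,
    model_from_dict,
    sampling_from_dict,
    sampling_to_dict,
)
from .segments import GenomeMap, LengthBins, SegmentCountTable, SegmentRecord

logger = logging.getLogger(__name__)

__all__ = [
    "read_segment_table",
    "write_segment_table",
    "read_count_table",
    "write_count_table",
    "RunConfig",
    "run_pipeline",
    "PipelineError",
]

_IBD_REQUIRED = ("sample1", "sample2", "chromosome", "length_cM")
_ROH_REQUIRED = ("sample", "chromosome", "start_cM", "end_cM")
_UNIT_TRAPS = {
    "length",
    "length_M",
    "length_bp",
    "start",
    "end",
    "start_M",
    "end_M",
    "start_bp",
    "end_bp",
}


def read_segment_table(path, dialect: str) -> List[SegmentRecord]:
    """Read a tab-separated IBD or ROH segment table.

    ``dialect='ibd'`` requires columns ``sample1, sample2, chromosome,
    length_cM``; ``dialect='roh'`` requires ``sample, chromosome, start_cM,
    end_cM`` (``length_cM`` optional, validated when present).  Columns with
    undeclared units (e.g. ``length`` or ``start_M``) are rejected.
    Malformed rows are dropped with a logged line number.
    """
    if dialect not in ("ibd", "roh"):
        raise ValueError("dialect must be 'ibd' or 'roh'")
    df = pd.read_csv(path, sep="\t", dtype=str)
    traps = _UNIT_TRAPS.intersection(df.columns)
    if traps:
        raise ValueError(
            f"columns {sorted(traps)} do not declare centimorgan units; "
            "rename with the _cM suffix"
        )
    required = _IBD_REQUIRED if dialect == "ibd" else _ROH_REQUIRED
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    records: List[SegmentRecord] = []
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        try:
            if dialect == "ibd":
                length = float(row["length_cM"])
                if not length > 0:
                    raise ValueError("non-positive length")
                start = float(row["start_cM"]) if "start_cM" in df.columns else 0.0
                end = float(row["end_cM"]) if "end_cM" in df.columns else start + length
                rec = SegmentRecord(
                    sample=str(row["sample1"]),
                    sample2=str(row["sample2"]),
                    chromosome=str(row["chromosome"]),
                    start_cm=start,
                    end_cm=end,
                    length_cm=length,
                )
            else:
                start = float(row["start_cM"])
                end = float(row["end_cM"])
                length = (
                    float(row["length_cM"])
                    if "length_cM" in df.columns and pd.notna(row["length_cM"])
                    else end - start
                )
                rec = SegmentRecord(
                    sample=str(row["sample"]),
                    chromosome=str(row["chromosome"]),
                    start_cm=start,
                    end_cm=end,
                    length_cm=length,
                )
        except (ValueError, TypeError) as exc:
            logger.warning("%s line %d rejected: %s", path, line_no, exc)
            continue
        records.append(rec)
    return records


def write_segment_table(records: Sequence[SegmentRecord], path, dialect: str) -> None:
    rows = []
    for r in records:
        if dialect == "ibd":
            rows.append(
                {
                    "sample1": r.sample,
                    "sample2": r.sample2 or "",
                    "chromosome": r.chromosome,
                    "start_cM": r.start_cm,
                    "end_cM": r.end_cm,
                    "length_cM": r.length_cm,
                }
            )
        else:
            rows.append(
                {
                    "sample": r.sample,
                    "chromosome": r.chromosome,
                    "start_cM": r.start_cm,
                    "end_cM": r.end_cm,
                    "length_cM": r.length_cm,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_count_table(table: SegmentCountTable, path) -> None:
    """Write a binned count table (TSV) plus a JSON metadata sidecar."""
    path = Path(path)
    edges = table.bins.edges_cm
    df = pd.DataFrame(
        {
            "bin_low_cM": edges[:-1],
            "bin_high_cM": edges[1:],
            "count": np.asarray(table.counts, dtype=int),
        }
    )
    df.to_csv(path, sep="\t", index=False)
    meta = {
        "n_individuals": table.n_individuals,
        "pair_count": table.pair_count,
        "sampling": sampling_to_dict(table.sampling),
        "bin_edges_cM": list(edges),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def read_count_table(path) -> SegmentCountTable:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    bins = LengthBins(tuple(meta["bin_edges_cM"]))
    return SegmentCountTable(
        counts=df["count"].to_numpy(),
        pair_count=int(meta["pair_count"]),
        sampling=sampling_from_dict(meta["sampling"]),
        bins=bins,
        n_individuals=meta.get("n_individuals"),
    )


# ---------------------------------------------------------------------------
# Pipeline


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclasses.dataclass
class RunConfig:
    """YAML-driven configuration of a full inference run."""

    outdir: str
    seed: int = 0
    ibd_counts: Optional[str] = None
    roh_counts: Optional[str] = None
    simulate: Optional[dict] = None  # StudyConfig overrides; used if no paths
    genome_map: Optional[str] = None
    fixed_single: Dict[str, float] = dataclasses.field(default_factory=dict)
    fixed_two_pop: Dict[str, float] = dataclasses.field(default_factory=dict)
    bounds: Dict[str, list] = dataclasses.field(default_factory=dict)
    bootstrap_replicates: int = 0
    selection_replicates: int = 0
    de_options: Dict[str, object] = dataclasses.field(default_factory=dict)
    stages: List[str] = dataclasses.field(
        default_factory=lambda: ["fit_single", "fit_two_pop"]
    )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        cfg = cls(**data)
        for p in (cfg.ibd_counts, cfg.roh_counts, cfg.genome_map):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        if not isinstance(cfg.seed, int):
            raise ValueError("seed must be an integer")
        return cfg

    def canonical_hash(self) -> str:
        payload = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_genome(config: RunConfig) -> GenomeMap:
    if config.genome_map is None:
        return GenomeMap.default()
    df = pd.read_csv(config.genome_map, sep="\t")
    return GenomeMap(tuple(df["length_cM"].astype(float)))


def run_pipeline(config: RunConfig) -> dict:
    """Run the staged analysis: load/simulate -> fit -> bootstrap -> select.

    Deterministic given the config seeds; every stage's result is persisted
    as JSON in ``outdir`` with the config hash embedded.  A stage failure
    aborts with the stage name, leaving earlier outputs on disk.
    """
    from . import inference, synthetic  # local import to avoid cycles

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.canonical_hash()
    genome = _load_genome(config)
    results: dict = {"config_hash": chash, "seed": config.seed}

    def persist(stage: str, payload: dict) -> None:
        payload = {"config_hash": chash, "seed": config.seed, **payload}
        (outdir / f"{stage}.json").write_text(json.dumps(payload, indent=2))

    stage = "load"
    try:
        datasets: List[SegmentCountTable] = []
        if config.ibd_counts or config.roh_counts:
            if config.ibd_counts:
                datasets.append(read_count_table(config.ibd_counts))
            if config.roh_counts:
                datasets.append(read_count_table(config.roh_counts))
        else:
            sim = dict(config.simulate or {})
            if "model" in sim:
                sim["model"] = model_from_dict(sim["model"])
            study = synthetic.generate_study(
                synthetic.StudyConfig(genome=genome, **sim), seed=config.seed
            )
            write_count_table(study.ibd, outdir / "ibd_counts.tsv")
            write_count_table(study.roh, outdir / "roh_counts.tsv")
            datasets = [study.ibd, study.roh]

        single_space = inference.default_space("single", fixed=config.fixed_single)
        two_space = inference.default_space("two_pop", fixed=config.fixed_two_pop)
        single_fit = None
        if "fit_single" in config.stages:
            stage = "fit_single"
            single_fit = inference.fit(
                datasets, single_space, seed=config.seed, genome=genome,
                de_options=config.de_options or None,
            )
            persist(stage, single_fit.to_dict())
            results["single_fit"] = single_fit

        if "fit_two_pop" in config.stages:
            stage = "fit_two_pop"
            two_fit = inference.fit(
                datasets, two_space, seed=config.seed + 1, genome=genome,
                de_options=config.de_options or None,
            )
            persist(stage, two_fit.to_dict())
            results["two_pop_fit"] = two_fit

        if config.bootstrap_replicates >= 2 and single_fit is not None:
            stage = "bootstrap"
            boot = inference.bootstrap_ci(
                single_fit, datasets, n_replicates=config.bootstrap_replicates,
                seed=config.seed + 2, genome=genome,
                de_options=config.de_options or None,
            )
            persist(stage, boot.to_dict())
            results["bootstrap"] = boot

        if config.selection_replicates >= 1:
            stage = "select"
            sel = inference.model_selection_bootstrap(
                datasets, single_space, two_space,
                n_replicates=config.selection_replicates,
                seed=config.seed + 3, genome=genome,
                de_options=config.de_options or None,
            )
            persist(stage, sel.to_dict())
            results["selection"] = sel
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise PipelineError(stage, exc) from exc
    return results
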