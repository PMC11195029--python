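"""YAML pipeline configuration and end-to-end orchestration.

A configuration file holds one section per subcommand plus a ``global``
section (log level, seed).  Unknown keys are rejected with their full path;
command-line flags override file values which override built-in defaults.
Every artifact a pipeline stage writes is accompanied by a provenance JSON
(inputs, parameters, seed) so any output can be recomputed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import yaml

from . import embedding, events, io_store
from .analysis import cluster_linkage, pairwise_distance
from .background import (
    PeakMaskConfig, RbfConfig, estimate_background, subtract_background,
)
from .detection import DetectionConfig, EventCollection, detect
from .errors import ValidationError

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

_SECTION_KEYS: dict[str, set] = {
    "global": {"log_level", "seed", "threads"},
    "convert-input": {
        "source", "channels", "subtract_background", "output_path", "loc",
        "compression", "dtype", "chunks", "input_loc",
    },
    "subtract-background": {
        "method", "scale_factor", "blur_sigma", "blur_radius", "prominence",
        "wlen", "distance", "width", "rel_height", "neighbors", "rbf_smoothing",
        "rbf_kernel", "rbf_epsilon", "rbf_degree", "loc", "output_loc",
    },
    "detect-events": {f.name for f in fields(DetectionConfig)} | {"output", "loc"},
    "filter-events": {"ranges", "output"},
    "normalize-events": {"instructions"},
    "embed": {"method", "latent_dim", "epochs", "seed", "output"},
    "cluster": {"method", "criterion", "cutoff", "linkage_method", "output"},
    "simulate": {"num_rows", "z_range", "video_shape", "seed", "output"},
}

STAGES = (
    "convert", "background", "detect", "filter", "normalize", "embed",
    "cluster", "analyze",
)


@dataclass
class PipelineConfig:
    sections: dict = field(default_factory=dict)
    version: int = SCHEMA_VERSION

    def section(self, name: str) -> dict:
        return dict(self.sections.get(name, {}))

    def effective(self, name: str, overrides: Optional[dict] = None) -> dict:
        """File values overridden by any non-None CLI flags."""
        merged = self.section(name)
        for key, value in (overrides or {}).items():
            if value is not None:
                merged[key] = value
        return merged


def load_config(path: Union[str, Path, None]) -> PipelineConfig:
    """Parse and validate a YAML configuration file (None -> all defaults)."""
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        return PipelineConfig()
    if not isinstance(raw, dict):
        raise ValidationError("config root must be a mapping of sections")
    version = raw.pop("schema_version", SCHEMA_VERSION)
    for section, content in raw.items():
        if section not in _SECTION_KEYS:
            raise ValidationError(f"unknown config section {section!r}")
        if content is None:
            continue
        if not isinstance(content, dict):
            raise ValidationError(f"section {section!r} must be a mapping")
        for key in content:
            if key not in _SECTION_KEYS[section]:
                raise ValidationError(
                    f"unknown config key {section}.{key!r}; expected one of "
                    f"{sorted(_SECTION_KEYS[section])}"
                )
    return PipelineConfig(sections={k: (v or {}) for k, v in raw.items()}, version=version)


def dump_config(cfg: PipelineConfig, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {"schema_version": cfg.version, **cfg.sections}, fh, sort_keys=False
        )


def write_provenance(
    artifact: Union[str, Path], inputs: dict, parameters: dict, seed=None
) -> None:
    record = {
        "artifact": str(artifact),
        "inputs": {k: str(v) for k, v in inputs.items()},
        "parameters": parameters,
        "seed": seed,
        "schema_version": SCHEMA_VERSION,
    }
    path = Path(str(artifact) + ".provenance.json")
    path.write_text(json.dumps(record, indent=2, default=str))


# ---------------------------------------------------------------------------
# pipeline orchestration
# ---------------------------------------------------------------------------
def run_pipeline(
    config: PipelineConfig,
    stages: Sequence[str],
    workdir: Union[str, Path] = ".",
) -> dict:
    """Run pipeline stages in order, each consuming its predecessor's artifact.

    Raises a dependency error before any work when a stage's input artifact
    is neither produced by an earlier stage nor present in ``workdir``.
    """
    for stage in stages:
        if stage not in STAGES:
            raise ValidationError(f"unknown stage {stage!r}")
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.section("global").get("seed", 0))

    # artifact each stage needs / provides (checked up front)
    needs = {
        "convert": None, "background": "store", "detect": "store",
        "filter": "roi", "normalize": "table", "embed": "table",
        "cluster": "embedding_or_table", "analyze": "embedding",
    }
    provides = {
        "convert": "store", "background": "store", "detect": "roi",
        "filter": "table", "normalize": "table", "embed": "embedding",
        "cluster": "clusters", "analyze": "scores",
    }
    available = set()
    if (workdir / "converted.h5").exists():
        available.add("store")
    for p in workdir.glob("*.roi"):
        available.add("roi")
    for stage in stages:
        need = needs[stage]
        if need == "embedding_or_table":
            ok = {"embedding", "table"} & available
            if not ok:
                raise ValidationError(
                    f"stage {stage!r} needs an embedding or event table; run "
                    "earlier stages first"
                )
        elif need is not None and need not in available:
            raise ValidationError(
                f"stage {stage!r} requires a {need!r} artifact; run earlier "
                "stages first"
            )
        available.add(provides[stage])

    context: dict = {}
    for stage in stages:
        logger.info("pipeline stage: %s", stage)
        _run_stage(stage, config, workdir, seed, context)
    return context


def _run_stage(stage, config, workdir, seed, context):
    if stage == "convert":
        params = config.effective("convert-input")
        source = params.pop("source")
        cfg = io_store.ConversionConfig(
            output_path=workdir / "converted.h5", **params
        )
        stores = io_store.convert_input(source, cfg)
        context["store"] = stores[0]
        write_provenance(cfg.output_path, {"source": source}, params, seed)
    elif stage == "background":
        params = config.effective("subtract-background")
        store = context.get("store") or io_store.VideoStore(
            workdir / "converted.h5", "data/ch0"
        )
        video = store.read_full()
        method = params.get("method", "dF")
        bg = estimate_background(
            video,
            scale_factor=params.get("scale_factor", 0.25),
            blur_sigma=params.get("blur_sigma", 0.0),
            peaks=PeakMaskConfig(prominence=params.get("prominence", 0.1)),
            rbf=RbfConfig(neighbors=params.get("neighbors", 50)),
        )
        result = subtract_background(video, bg, method=method)
        out_loc = params.get("output_loc", f"{method}/ch0")
        context["store"] = io_store.write_store(
            result.corrected, store.path, loc=out_loc
        )
        write_provenance(store.path, {"input_loc": store.loc}, params, seed)
    elif stage == "detect":
        params = config.effective("detect-events")
        out = workdir / params.pop("output", "events.roi")
        params.pop("loc", None)
        store = context.get("store") or io_store.VideoStore(
            workdir / "converted.h5", "data/ch0"
        )
        coll = detect(store, DetectionConfig(**params), out)
        context["roi"] = coll
        write_provenance(out, {"store": store.path}, params, seed)
    elif stage == "filter":
        params = config.effective("filter-events")
        coll = context.get("roi") or EventCollection(next(workdir.glob("*.roi")))
        table = coll.to_table()
        ranges = {
            k: tuple(v) for k, v in (params.get("ranges") or {}).items()
        }
        context["table"] = events.filter_events(table, ranges)
    elif stage == "normalize":
        params = config.effective("normalize-events")
        instructions = params.get("instructions") or {}
        context["table"] = events.normalize_events(context["table"], instructions)
    elif stage == "embed":
        params = config.effective("embed")
        method = params.get("method", "fext")
        table = context["table"]
        if method == "fext":
            matrix, _ = embedding.extract_features(table)
        else:
            spec = embedding.AutoencoderSpec(
                kind=method,
                latent_dim=params.get("latent_dim", 16),
                epochs=params.get("epochs", 25),
                seed=params.get("seed", seed),
            )
            train = {
                "cnn": embedding.train_cnn_autoencoder,
                "rnn": embedding.train_rnn_autoencoder,
            }[method]
            model, _ = train(list(table["trace"]), spec)
            matrix = model.encode(list(table["trace"]))
        context["embedding"] = matrix
        out = workdir / params.get("output", "embedding.npy")
        np.save(out, matrix)
        write_provenance(out, {}, {"method": method}, seed)
    elif stage == "cluster":
        params = config.effective("cluster")
        table = context["table"]
        dist = pairwise_distance(
            list(table["trace"]), method=params.get("method", "dtw"),
            index=list(table["event_id"]),
        )
        result = cluster_linkage(
            dist,
            criterion=params.get("criterion", "maxclust"),
            cutoff=params.get("cutoff", 2),
            linkage_method=params.get("linkage_method", "average"),
            traces=list(table["trace"]),
        )
        context["clusters"] = result
        out = workdir / params.get("output", "clusters.csv")
        table.assign(cluster=result.labels)[["event_id", "cluster"]].to_csv(
            out, index=False
        )
        write_provenance(out, {}, dict(params), seed)
    elif stage == "analyze":
        from .analysis import train_discriminator

        table = context["table"]
        _, report = train_discriminator(
            context["embedding"], list(table["group"]), seed=seed
        )
        context["scores"] = report
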