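"""End-to-end segmentation pipeline over tiles and tile directories.

Stage order for one tile: tile-level gating on the classifier score, stain
separation (SNMF, with a reference-basis fallback on degenerate tiles),
class-attention probability map, inclusive thresholding, dense-CRF
refinement, stain gating of connected components, then instance
post-processing (small-object removal, label association, Feret filter)
and 256 x 256 crop extraction around each aggregate centroid.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .attention import (
    OracleAttentionProvider,
    SurrogateAttentionProvider,
    attention_to_map,
    class_attention,
    combine_with_stain,
    crf_refine,
    threshold_attention,
)
from .crf import CRFParams
from .errors import DegenerateInputError
from .instances import (
    CropSpec,
    InstanceMask,
    extract_crop,
    extract_instances,
    postprocess,
)
from .stain import separate_stains, threshold_stain
from .types import REFERENCE_OD_VECTORS, BinaryMask, RGBTile, StainBasis

log = logging.getLogger("lewyseg.pipeline")


@dataclass
class PipelineConfig:
    """All stage parameters; defaults are the pipeline's operating point
    (stain threshold 0.5, tau 0.1, Ts 100, Td 20, TF 33, 256-px crops)."""

    snmf_sparsity: float = 0.01
    snmf_max_iter: int = 200
    norm_percentile: float = 99.0
    stain_threshold: float = 0.5
    tau: float = 0.1
    crf: CRFParams = field(default_factory=CRFParams)
    min_overlap_fraction: float = 0.0
    Ts: int = 100
    Td: float = 20.0
    TF: float = 33.0
    crop_size: int = 256
    tile_score_threshold: float = 0.5
    provider: str = "surrogate"
    reuse_reference_basis: bool = False
    seed: int = 0
    version: str = ""

    def __post_init__(self):
        if not self.version:
            self.version = __version__

    def to_yaml(self, path):
        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path):
        d = yaml.safe_load(Path(path).read_text())
        crf = d.pop("crf", {})
        cfg = cls(**{k: v for k, v in d.items() if k in
                     {f.name for f in dataclasses.fields(cls)} - {"crf"}})
        cfg.crf = CRFParams(**crf)
        return cfg


@dataclass
class TileReport:
    tile_id: str
    classifier_score: float
    n_instances: int
    used_reference_basis: bool = False
    instances: list = field(default_factory=list)
    timings: dict = field(default_factory=dict)

    def to_dict(self):
        return {
            "tile_id": self.tile_id,
            "classifier_score": self.classifier_score,
            "n_instances": self.n_instances,
            "used_reference_basis": self.used_reference_basis,
            "instances": self.instances,
            "timings": self.timings,
        }


def make_provider(config: PipelineConfig, ground_truth=None):
    if config.provider == "oracle":
        if ground_truth is None:
            raise ValueError("oracle provider needs ground truth")
        return OracleAttentionProvider(ground_truth)
    return SurrogateAttentionProvider(seed=config.seed)


def segment_tile(
    tile: RGBTile,
    config: PipelineConfig | None = None,
    provider=None,
    tile_id: str = "tile",
):
    """Segment one tile; returns ``(InstanceMask, TileReport, crops)``.

    Tiles whose provider score falls below the gating threshold are
    skipped (empty mask), mirroring the production flow where only tiles
    classified as containing aggregates are segmented.
    """
    config = config or PipelineConfig()
    provider = provider or make_provider(config)
    timings = {}
    t0 = time.perf_counter()
    score, atten = provider(tile)
    timings["classifier"] = time.perf_counter() - t0

    empty = InstanceMask(np.zeros(tile.shape, dtype=np.int32), 0)
    if score < config.tile_score_threshold:
        report = TileReport(tile_id, float(score), 0, timings=timings)
        return empty, report, []

    t0 = time.perf_counter()
    used_reference = False
    try:
        reference = (
            StainBasis(REFERENCE_OD_VECTORS.copy())
            if config.reuse_reference_basis
            else None
        )
        basis, concs, prob = separate_stains(
            tile,
            sparsity=config.snmf_sparsity,
            max_iter=config.snmf_max_iter,
            seed=config.seed,
            norm_percentile=config.norm_percentile,
            reference_basis=reference,
        )
        used_reference = config.reuse_reference_basis
    except DegenerateInputError:
        log.warning("degenerate stain fit on %s; reference-basis fallback", tile_id)
        basis, concs, prob = separate_stains(
            tile,
            norm_percentile=config.norm_percentile,
            reference_basis=StainBasis(REFERENCE_OD_VECTORS.copy()),
        )
        used_reference = True
    s_alkaline = threshold_stain(prob, config.stain_threshold)
    timings["stain"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    a_cls = class_attention(atten)
    P = attention_to_map(a_cls, atten.patch_grid, tile.shape)
    s_attention = threshold_attention(P, config.tau)
    timings["attention"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    s_refined = crf_refine(tile, P, s_attention, config.crf)
    timings["crf"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    s_combined = combine_with_stain(
        s_refined, s_alkaline, config.min_overlap_fraction
    )
    inst = postprocess(s_combined, config.Ts, config.Td, config.TF)
    timings["postprocess"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    records = extract_instances(inst)
    spec = CropSpec(size=config.crop_size)
    crops = []
    rows = []
    for rec in records:
        crop, _ = extract_crop(tile, rec, spec)
        crops.append(crop)
        rows.append(
            {
                "label": rec.label,
                "area_px": rec.area_px,
                "centroid_row": rec.centroid[0],
                "centroid_col": rec.centroid[1],
                "max_feret_px": rec.max_feret_px,
                "feret_um": rec.max_feret_px * tile.pixel_size_um,
            }
        )
    timings["crops"] = time.perf_counter() - t0

    report = TileReport(
        tile_id,
        float(score),
        inst.n_instances,
        used_reference_basis=used_reference,
        instances=rows,
        timings=timings,
    )
    return inst, report, crops


def run_directory(
    input_dir,
    output_dir,
    config: PipelineConfig | None = None,
    force: bool = False,
):
    """Process every PNG/TIFF tile in ``input_dir``.

    Outputs per tile: instance mask (16-bit TIFF), per-aggregate CSV,
    crops (PNG), report JSON; a global manifest CSV at the output root
    plus the serialized config. Existing outputs are skipped unless
    ``force``. Returns the manifest DataFrame; unreadable tiles are
    logged, skipped and flagged in the manifest.
    """
    from . import io as lio

    config = config or PipelineConfig()
    input_dir = Path(input_dir)
    output_dir = Path(output_dir)
    tiles = sorted(
        p for p in input_dir.iterdir()
        if p.suffix.lower() in (".png", ".tif", ".tiff")
    )
    if not tiles:
        raise FileNotFoundError(f"no PNG/TIFF tiles in {input_dir}")
    for sub in ("masks", "crops", "reports"):
        (output_dir / sub).mkdir(parents=True, exist_ok=True)
    config.to_yaml(output_dir / "config.yaml")

    rows = []
    for path in tiles:
        tile_id = path.stem
        report_path = output_dir / "reports" / f"{tile_id}.json"
        if report_path.exists() and not force:
            payload = json.loads(report_path.read_text())
            rows.append(
                {
                    "tile_id": tile_id,
                    "status": "cached",
                    "classifier_score": payload["classifier_score"],
                    "n_instances": payload["n_instances"],
                }
            )
            continue
        try:
            tile = lio.read_tile(path)
        except Exception as exc:  # unreadable file: log and continue
            log.error("failed to read %s: %s", path, exc)
            rows.append(
                {
                    "tile_id": tile_id,
                    "status": "error",
                    "classifier_score": np.nan,
                    "n_instances": 0,
                }
            )
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            inst, report, crops = segment_tile(tile, config, tile_id=tile_id)
        lio.write_instance_tiff(output_dir / "masks" / f"{tile_id}.tiff", inst)
        for rec, crop in zip(report.instances, crops):
            lio.write_tile(
                output_dir / "crops" / f"{tile_id}_{rec['label']}.png",
                RGBTile(crop, white_point=tile.white_point),
            )
        if report.instances:
            pd.DataFrame(report.instances).assign(tile_id=tile_id).to_csv(
                output_dir / "reports" / f"{tile_id}_instances.csv", index=False
            )
        report_path.write_text(json.dumps(report.to_dict(), indent=2))
        rows.append(
            {
                "tile_id": tile_id,
                "status": "ok",
                "classifier_score": report.classifier_score,
                "n_instances": report.n_instances,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(output_dir / "manifest.csv", index=False)
    return manifest
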