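"""Pipeline orchestration: the three processing approaches and the evaluation loop.

Approaches (applied between the tensor-to-field lift and the scoring step):

* ``initial`` — score on the raw lifted field, no mask, no processing.
* ``A``       — white-matter mask, square the profiles (grey-value
                sharpening), enhance by shift–twist convolution with the
                numerically computed kernel, min–max normalize per voxel.
* ``B``       — white-matter mask, subtract the per-voxel minimum and divide
                by the global maximum, erode (HJB sharpening), enhance by the
                finite-difference Fokker–Planck evolution.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .odf import (
    NormalizationMode,
    OrientationField,
    TensorField,
    normalize,
    square_sharpen,
    tensor_to_orientation_field,
    white_matter_mask,
)
from .pde import (
    EnhancementParams,
    ErosionParams,
    compute_kernel,
    enhance,
    erode,
    shift_twist_convolve,
)
from .scoring import ScoringParams, critical_threshold, score_pathways
from .sphere import build_angular_operators, tessellate_icosphere
from .tracts import Pathway, lift_pathway, write_streamlines

APPROACHES = ("initial", "A", "B")


@dataclass
class MaskParams:
    fa_min: float = 0.25
    fa_alt: float = 0.15
    md_max: float = 1.5e-3
    dilate_voxels: int = 1


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one processing + scoring run."""

    approach: str = "B"
    tess_order: int = 2
    step_mm: float = 1.0
    enhancement: EnhancementParams = field(default_factory=EnhancementParams)
    erosion: ErosionParams = field(default_factory=ErosionParams)
    scoring: ScoringParams = field(default_factory=ScoringParams)
    mask: MaskParams = field(default_factory=MaskParams)
    kernel_half_extent: int = 4
    top_fraction: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.approach not in APPROACHES:
            raise ValueError(f"approach must be one of {APPROACHES}, got {self.approach!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, typ in (("enhancement", EnhancementParams), ("erosion", ErosionParams),
                         ("scoring", ScoringParams), ("mask", MaskParams)):
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**d[key])
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)


def process_field(T: TensorField, cfg: PipelineConfig) -> OrientationField:
    """Lift the tensor field and apply the configured contextual processing."""
    tess = tessellate_icosphere(cfg.tess_order)
    if cfg.approach == "initial":
        return tensor_to_orientation_field(T, tess)
    wm = white_matter_mask(T, cfg.mask.fa_min, cfg.mask.fa_alt,
                           cfg.mask.md_max, cfg.mask.dilate_voxels)
    Tm = TensorField(tensors=T.tensors, affine=T.affine, mask=wm & T.mask)
    U = tensor_to_orientation_field(Tm, tess)
    ops = build_angular_operators(tess)
    if cfg.approach == "A":
        U = square_sharpen(U)
        he = cfg.kernel_half_extent
        K = compute_kernel(cfg.enhancement, (he, he, he), tess, ops)
        U = shift_twist_convolve(U, K)
        return normalize(U, NormalizationMode.MINMAX_PER_VOXEL)
    # approach B
    U = normalize(U, NormalizationMode.MIN_PER_VOXEL_THEN_GLOBAL_MAX)
    U = erode(U, cfg.erosion, ops)
    return enhance(U, cfg.enhancement, ops)


def run_pipeline(T: TensorField, pathways: list[Pathway], cfg: PipelineConfig,
                 labels: np.ndarray | None = None, out_dir=None,
                 log=print) -> dict:
    """Full run: process the field, lift and score the pathways, evaluate.

    Returns a dict with the scores DataFrame, the processed field, the
    evaluation report (if labels were given) and run metadata; writes
    scores.csv / report.json / metadata.json / top streamlines to ``out_dir``
    if given.
    """
    t0 = time.time()
    U = process_field(T, cfg)
    log(f"[fiberlift] processed field (approach {cfg.approach}) in {time.time()-t0:.1f}s")

    t1 = time.time()
    lps = [lift_pathway(p, cfg.step_mm) for p in pathways]
    results = score_pathways(U, lps, cfg.scoring)
    scores = pd.DataFrame(
        {
            "pathway_id": [r.pathway_id for r in results],
            "external": [r.external for r in results],
            "internal": [r.internal for r in results],
            "total": [r.total for r in results],
            "n_samples": [r.n_samples for r in results],
        }
    )
    log(f"[fiberlift] scored {len(results)} pathways in {time.time()-t1:.1f}s")

    report = None
    if labels is not None:
        report = critical_threshold(scores["total"].to_numpy(), labels)
        log(f"[fiberlift] critical threshold {report.threshold:.4f}: "
            f"sensitivity {report.sensitivity:.3f} at specificity 1")

    out = {"scores": scores, "field": U, "report": report,
           "metadata": {
               "fiberlift_version": __version__,
               "config": cfg.to_dict(),
               "n_pathways": len(pathways),
               "runtime_s": round(time.time() - t0, 2),
           }}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        scores.to_csv(out_dir / "scores.csv", index=False)
        with open(out_dir / "metadata.json", "w") as f:
            json.dump(out["metadata"], f, indent=2)
        if report is not None:
            with open(out_dir / "report.json", "w") as f:
                json.dump(report.to_dict(), f, indent=2)
        if cfg.top_fraction:
            order = np.argsort(-scores["total"].to_numpy())
            n_top = max(1, int(round(cfg.top_fraction * len(pathways))))
            top = [pathways[i] for i in order[:n_top]]
            write_streamlines(top, out_dir / "top_pathways.trk",
                              affine=T.affine, shape=T.shape)
    return out
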