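"""End-to-end pipeline: manifest in, agreement report out.

Wires the dataset manifest through the three agreement levels — per-image
segmentation agreement (FK/BWFK), cell detection agreement (DBCAA) and
per-observer TILs scores — then the dataset-level concordance statistics
(ICC, LOAM, subgroup correlation test).  Also supports treating externally
produced masks/points (e.g. an AI system's predictions) as additional
observers alongside the humans.
"""

from __future__ import annotations

import logging
import time

import numpy as np
import pandas as pd

from . import kappa_agreement as ka
from . import tils_scoring as ts
from .cell_agreement import LYMPHOCYTE_DIAMETER_UM
from .concordance_stats import correlation_test
from .io_annotations import AgreementReport, DatasetManifest, MaskStack, PointSets
from .model import CellDetectionAgreement, SegmentationAgreement, TilsConcordance

__all__ = ["run_full_framework", "compare_observer_sets", "merge_observers"]

logger = logging.getLogger("tilagree")


def run_full_framework(
    manifest: DatasetManifest,
    dt: float = ka.DEFAULT_DT,
    d_l: float | None = None,
    lymph_diameter_um: float = LYMPHOCYTE_DIAMETER_UM,
    normalization: str = "max_match",
    subgroup_size: int = 10,
    repeats: int = 50,
    seed: int | None = None,
) -> AgreementReport:
    """Compute every agreement measure over a dataset.

    Per image: FK, BWFK (at ``dt``), DBCAA (match radius ``d_l`` pixels, or
    ``lymph_diameter_um`` / pixel size), per-observer TILs scores.  Dataset
    level: ICC and LOAM over the TILs score matrix, and — when the dataset
    has at least ``subgroup_size`` images — the subgroup correlation test.
    """
    if d_l is None:
        d_l = lymph_diameter_um / manifest.pixel_size_um
    rows, tils_rows = [], {}
    for image_id in manifest.image_ids:
        t0 = time.perf_counter()
        stack, points = manifest.load_image(image_id)
        seg = SegmentationAgreement(stack, dt=dt).fit()
        cell = CellDetectionAgreement(points, d_l=d_l,
                                      normalization=normalization).fit()
        tils = ts.tils_per_observer(stack, points,
                                    pixel_size_um=manifest.pixel_size_um)
        rows.append(
            {
                "image_id": image_id,
                "fk": seg.fk.kappa,
                "bwfk": seg.bwfk.kappa,
                "dbcaa": cell.score,
            }
        )
        tils_rows[image_id] = {
            obs: r.t for obs, r in zip(stack.observer_ids, tils)
        }
        logger.info("image %s done in %.2fs", image_id, time.perf_counter() - t0)
    per_image = pd.DataFrame(rows).set_index("image_id")
    score_matrix = pd.DataFrame.from_dict(tils_rows, orient="index").loc[
        per_image.index
    ]
    for obs in score_matrix.columns:
        per_image[f"tils_{obs}"] = score_matrix[obs]

    dataset: dict = {}
    if len(per_image) >= 2:
        conc = TilsConcordance(score_matrix).fit()
        dataset["icc"] = conc.icc.value
        dataset["icc_model"] = conc.icc.model
        dataset["icc_degenerate"] = conc.icc.degenerate
        dataset["loam"] = {
            "mean_difference": conc.loam.mean_difference,
            "lower": conc.loam.lower,
            "upper": conc.loam.upper,
            "outliers": conc.loam.outlier_count,
        }
    if len(per_image) >= subgroup_size:
        corr = correlation_test(
            per_image["bwfk"].to_numpy(), per_image["dbcaa"].to_numpy(),
            score_matrix, subgroup_size=subgroup_size, repeats=repeats, seed=seed,
        )
        dataset["correlation_test"] = {
            "r_matrix": corr.r_matrix.to_numpy().tolist(),
            "measures": list(corr.r_matrix.columns),
            "subgroup_size": subgroup_size,
            "repeats": repeats,
            "degenerate": corr.degenerate,
        }
    config = {
        "dt": dt,
        "d_l_px": d_l,
        "normalization": normalization,
        "pixel_size_um": manifest.pixel_size_um,
        "subgroup_size": subgroup_size,
        "repeats": repeats,
        "seed": seed,
        "observers": list(manifest.observer_ids),
    }
    return AgreementReport(per_image=per_image, dataset=dataset, config=config)


def merge_observers(
    stack: MaskStack, points: PointSets,
    extra_stack: MaskStack | None = None,
    extra_points: PointSets | None = None,
    provenance: str = "model",
) -> tuple[MaskStack, PointSets]:
    """Append externally produced observers (e.g. AI predictions) to the
    human annotation set, labelling their provenance in the observer ids."""
    masks = [stack.masks]
    obs_ids = list(stack.observer_ids)
    pts = list(points.points)
    pt_ids = list(points.observer_ids)
    if extra_stack is not None:
        if extra_stack.shape != stack.shape:
            raise ValueError(
                f"frame mismatch: extra masks are {extra_stack.shape}, "
                f"dataset is {stack.shape}"
            )
        masks.append(extra_stack.masks)
        obs_ids += [f"{provenance}:{o}" for o in extra_stack.observer_ids]
    if extra_points is not None:
        pts += list(extra_points.points)
        pt_ids += [f"{provenance}:{o}" for o in extra_points.observer_ids]
    merged_stack = MaskStack(
        masks=np.concatenate(masks), observer_ids=obs_ids,
        image_id=stack.image_id, exclusion=stack.exclusion,
    )
    merged_points = PointSets(
        points=pts, observer_ids=pt_ids, image_id=points.image_id,
        frame=points.frame,
    )
    return merged_stack, merged_points


def compare_observer_sets(
    manifest: DatasetManifest,
    extra_manifest: DatasetManifest,
    provenance: str = "model",
    **framework_kw,
) -> AgreementReport:
    """Agreement over the union of human and supplied algorithmic observers.

    ``extra_manifest`` must list the same image ids; its observers (e.g. an
    AI segmentation/detection system treated as one more rater) are merged
    into each image's stack and point sets, then the full framework runs on
    the union.  Extra observers appear in the output with a
    ``provenance:`` prefix.
    """
    if list(extra_manifest.image_ids) != list(manifest.image_ids):
        raise ValueError("extra manifest must cover the same images in order")

    merged = _MergedManifest(manifest, extra_manifest, provenance)
    return run_full_framework(merged, **framework_kw)


class _MergedManifest(DatasetManifest):
    """Manifest view that yields merged human + extra observer data."""

    def __init__(self, base: DatasetManifest, extra: DatasetManifest,
                 provenance: str):
        self.entries = base.entries
        self.pixel_size_um = base.pixel_size_um
        self.observer_ids = list(base.observer_ids) + [
            f"{provenance}:{o}" for o in extra.observer_ids
        ]
        self.root = base.root
        self._base = base
        self._extra = extra
        self._provenance = provenance

    def load_image(self, image_id: str, category_map="grayscale"):
        stack, points = self._base.load_image(image_id, category_map)
        ex_stack, ex_points = self._extra.load_image(image_id, category_map)
        return merge_observers(stack, points, ex_stack, ex_points,
                               provenance=self._provenance)
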