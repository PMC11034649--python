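"""Segmentation evaluation: Dice, Jaccard, HD95 and ASD.

Overlap metrics are set-based (Dice = 2|P&G| / (|P|+|G|), Jaccard =
|P&G| / |P|G|-union); the empty/empty pair scores 1.0 by convention and an
empty-vs-non-empty pair scores 0.0.

Surface distances are computed in-plane, in pixels. A boundary pixel is a
foreground pixel with at least one background 4-neighbour, where the image
border counts as background. For each boundary pixel of each mask we take
the Euclidean distance to the nearest boundary pixel of the other mask;
HD95 is the 95th percentile (linear interpolation) of the pooled symmetric
multiset and ASD its mean. Distances are undefined when either mask is
empty; `evaluate` records those entries as missing and excludes them from
aggregation.

Multi-class masks are scored one-vs-rest per foreground class; background
(class 0) is never scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .backbone import InputError, ModelState, forward


class EmptyMaskError(ValueError):
    """Surface distances are undefined for an empty mask."""


def _check_pair(pred, gt):
    pred = np.asarray(pred).astype(bool)
    gt = np.asarray(gt).astype(bool)
    if pred.shape != gt.shape:
        raise InputError(f"mask shapes differ: {pred.shape} vs {gt.shape}")
    return pred, gt


def dice(pred, gt) -> float:
    pred, gt = _check_pair(pred, gt)
    p, g = pred.sum(), gt.sum()
    if p + g == 0:
        return 1.0
    return 2.0 * np.logical_and(pred, gt).sum() / float(p + g)


def jaccard(pred, gt) -> float:
    pred, gt = _check_pair(pred, gt)
    union = np.logical_or(pred, gt).sum()
    if union == 0:
        return 1.0
    return np.logical_and(pred, gt).sum() / float(union)


def boundary_pixels(mask) -> np.ndarray:
    """Coordinates (N, 2) of foreground pixels with a background 4-neighbour;
    pixels on the image border count as adjacent to background."""
    mask = np.asarray(mask).astype(bool)
    padded = np.pad(mask, 1, constant_values=False)
    interior = (padded[:-2, 1:-1] & padded[2:, 1:-1] &
                padded[1:-1, :-2] & padded[1:-1, 2:])
    return np.argwhere(mask & ~interior)


def surface_distances(pred, gt) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-boundary distances, pred-to-gt and gt-to-pred."""
    pred, gt = _check_pair(pred, gt)
    if not pred.any() or not gt.any():
        raise EmptyMaskError("surface distances undefined for an empty mask")
    bp = boundary_pixels(pred).astype(np.float64)
    bg = boundary_pixels(gt).astype(np.float64)
    d_pg, _ = cKDTree(bg).query(bp)
    d_gp, _ = cKDTree(bp).query(bg)
    return d_pg, d_gp


def hd95(pred, gt) -> float:
    """95th percentile of the pooled symmetric surface-distance multiset."""
    d_pg, d_gp = surface_distances(pred, gt)
    return float(np.percentile(np.concatenate([d_pg, d_gp]), 95))


def asd(pred, gt) -> float:
    """Mean of the pooled symmetric surface-distance multiset."""
    d_pg, d_gp = surface_distances(pred, gt)
    return float(np.concatenate([d_pg, d_gp]).mean())


@dataclass
class MetricRow:
    case_id: str
    class_id: int
    dice: float
    jaccard: float
    hd95: float  # nan when undefined on every scored slice
    asd: float


@dataclass
class MetricReport:
    """Per-case, per-class metrics with table-style aggregation."""

    rows: list = field(default_factory=list)
    n_distance_excluded: int = 0  # (case, class) entries lacking distances

    def classes(self) -> list:
        return sorted({r.class_id for r in self.rows})

    def class_mean(self, class_id: int, metric: str) -> float:
        vals = [getattr(r, metric) for r in self.rows if r.class_id == class_id]
        vals = [v for v in vals if not np.isnan(v)]
        return float(np.mean(vals)) if vals else float("nan")

    def overall_mean(self, metric: str) -> float:
        per_class = [self.class_mean(c, metric) for c in self.classes()]
        per_class = [v for v in per_class if not np.isnan(v)]
        return float(np.mean(per_class)) if per_class else float("nan")

    @property
    def mean_dice(self) -> float:
        return self.overall_mean("dice")

    def to_table(self) -> str:
        """Delimited per-row table plus an aggregate block.

        Distances are in-plane 2D per-slice values, in pixels.
        """
        lines = ["# surface distances computed per 2D slice, in pixels",
                 "case\tclass\tdice\tjaccard\thd95\tasd"]
        for r in self.rows:
            lines.append(f"{r.case_id}\t{r.class_id}\t{r.dice:.4f}\t"
                         f"{r.jaccard:.4f}\t{r.hd95:.4f}\t{r.asd:.4f}")
        lines.append("# aggregate (mean over cases)")
        for c in self.classes():
            lines.append(
                f"mean\t{c}\t{self.class_mean(c, 'dice'):.4f}\t"
                f"{self.class_mean(c, 'jaccard'):.4f}\t"
                f"{self.class_mean(c, 'hd95'):.4f}\t{self.class_mean(c, 'asd'):.4f}")
        lines.append(
            f"mean\tall\t{self.overall_mean('dice'):.4f}\t"
            f"{self.overall_mean('jaccard'):.4f}\t"
            f"{self.overall_mean('hd95'):.4f}\t{self.overall_mean('asd'):.4f}")
        if self.n_distance_excluded:
            lines.append(f"# {self.n_distance_excluded} case/class entries lacked "
                         "defined surface distances and were excluded from hd95/asd")
        return "\n".join(lines)


def evaluate(model: ModelState, test_cases, batch_size: int = 8) -> MetricReport:
    """Predict every slice of every test case and score each foreground class.

    ``test_cases`` yields (case_id, image stack (S, H, W), mask stack).
    Per case and class, overlap metrics pool pixel counts over the slices
    where prediction or ground truth contains the class (so the Dice/Jaccard
    identity holds exactly per row); distance metrics are averaged per slice
    over the slices where both masks are non-empty, and recorded as missing
    for the case when no such slice exists.
    """
    num_classes = model.arch.num_classes
    report = MetricReport()
    for case_id, images, masks in test_cases:
        images = np.asarray(images, dtype=np.float32)
        preds = np.empty(images.shape, dtype=np.int64)
        for start in range(0, images.shape[0], batch_size):
            chunk = images[start:start + batch_size][:, None]
            preds[start:start + batch_size] = forward(model, chunk).argmax(axis=1)
        for c in range(1, num_classes):
            inter = psum = gsum = union = 0
            hs, as_ = [], []
            scored = False
            for p_slice, g_slice in zip(preds == c, np.asarray(masks) == c):
                if not (p_slice.any() or g_slice.any()):
                    continue
                scored = True
                inter += np.logical_and(p_slice, g_slice).sum()
                union += np.logical_or(p_slice, g_slice).sum()
                psum += p_slice.sum()
                gsum += g_slice.sum()
                if p_slice.any() and g_slice.any():
                    hs.append(hd95(p_slice, g_slice))
                    as_.append(asd(p_slice, g_slice))
            if scored:
                d = 2.0 * inter / float(psum + gsum)
                j = inter / float(union)
            else:  # class absent from this case entirely: perfect agreement
                d = j = 1.0
            if not hs:
                report.n_distance_excluded += 1
            report.rows.append(MetricRow(
                case_id=case_id, class_id=c, dice=float(d), jaccard=float(j),
                hd95=float(np.mean(hs)) if hs else float("nan"),
                asd=float(np.mean(as_)) if as_ else float("nan")))
    return report
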