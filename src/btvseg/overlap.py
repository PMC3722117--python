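"""Volumetric agreement between a reference GTV and an automated BTV.

The conformity index is intersection over union of the two volumes,
expressed as a percentage (Jaccard x 100).  Because published phrasing of
"inclusion ratio" is direction-ambiguous, BOTH directions are always
computed and reported explicitly: the fraction of the BTV inside the GTV
and the fraction of the GTV inside the BTV.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

from .imaging import StructureMask

__all__ = ["OverlapReport", "conformity_index", "inclusion_ratios", "compare_pair"]


@dataclass(frozen=True)
class OverlapReport:
    """Volumes and agreement metrics for one structure pair (A = GTV, B = BTV)."""

    label_a: str
    label_b: str
    volume_a_ml: float
    volume_b_ml: float
    intersection_ml: float
    union_ml: float
    conformity_index_pct: float
    a_in_b_pct: float  # |A ∩ B| / |A|, GTV fraction inside BTV
    b_in_a_pct: float  # |A ∩ B| / |B|, BTV fraction inside GTV
    both_empty: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


def _check_pair(a: StructureMask, b: StructureMask) -> None:
    if not a.geometry.approx_equal(b.geometry):
        raise ValueError(
            "masks live on different grids; resample one onto the other first "
            "(imaging.resample_mask)"
        )


def conformity_index(a: StructureMask, b: StructureMask) -> float:
    """100 x |a ∩ b| / |a ∪ b|; 0 when both masks are empty."""
    _check_pair(a, b)
    inter = int((a.voxels & b.voxels).sum())
    union = int((a.voxels | b.voxels).sum())
    if union == 0:
        return 0.0
    return 100.0 * inter / union


def inclusion_ratios(gtv: StructureMask, btv: StructureMask) -> tuple[float, float]:
    """(btv_in_gtv_pct, gtv_in_btv_pct).

    ``btv_in_gtv`` = 100 x |∩| / |btv| (fraction of the automated volume the
    manual GTV covers); ``gtv_in_btv`` = 100 x |∩| / |gtv|.  An empty
    denominator yields 0.0 rather than NaN.
    """
    _check_pair(gtv, btv)
    inter = int((gtv.voxels & btv.voxels).sum())
    n_gtv = int(gtv.voxels.sum())
    n_btv = int(btv.voxels.sum())
    btv_in_gtv = 100.0 * inter / n_btv if n_btv else 0.0
    gtv_in_btv = 100.0 * inter / n_gtv if n_gtv else 0.0
    return btv_in_gtv, gtv_in_btv


def compare_pair(gtv: StructureMask, btv: StructureMask) -> OverlapReport:
    """Full agreement report for one GTV/BTV pair (same grid)."""
    _check_pair(gtv, btv)
    vv = gtv.geometry.voxel_volume_ml
    inter = int((gtv.voxels & btv.voxels).sum())
    union = int((gtv.voxels | btv.voxels).sum())
    btv_in_gtv, gtv_in_btv = inclusion_ratios(gtv, btv)
    return OverlapReport(
        label_a=gtv.label or "GTV",
        label_b=btv.label or "BTV",
        volume_a_ml=gtv.volume_ml,
        volume_b_ml=btv.volume_ml,
        intersection_ml=inter * vv,
        union_ml=union * vv,
        conformity_index_pct=100.0 * inter / union if union else 0.0,
        a_in_b_pct=gtv_in_btv,
        b_in_a_pct=btv_in_gtv,
        both_empty=(union == 0),
    )
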