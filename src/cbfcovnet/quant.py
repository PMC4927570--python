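"""CBF quantification from control/label ASL signal pairs and regional averaging.

The single-compartment pCASL quantification used here is

    CBF = rho_b * (S_c - S_l) /
          (2 * alpha * C * omega_a * T1a * exp(-w / T1a) * (1 - exp(-tl / T1a)))

with S_c and S_l the control and labeled signal intensities, rho_b the brain
tissue density, alpha the labeling efficiency, C the sensitivity of the image
to water, omega_a the density of water in blood, T1a the longitudinal
relaxation time of arterial blood, w the post-labeling delay and tl the
labeling duration. The output is linear in the control-label difference, so
any uncertainty in the constant parameters cancels from correlation-based
network edges once maps are normalized to the whole-brain mean.

Default parameter values are assumptions typical for 3T pCASL (alpha = 0.8,
T1a = 1.65 s, w = 2.025 s, tl = 1.5 s, rho_b = C = omega_a = 1) and should
be overridden when the acquisition differs.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "QuantificationParams",
    "quantify_cbf",
    "normalize_to_global_mean",
    "regional_means",
    "read_parcellation",
    "extract_regional_table",
]


@dataclass(frozen=True)
class QuantificationParams:
    """Constants of the single-compartment pCASL quantification.

    Units: densities in g/mL, times in seconds; ``alpha`` and ``C`` are
    dimensionless. All must be strictly positive and ``alpha <= 1``.
    """

    rho_b: float = 1.0
    alpha: float = 0.8
    C: float = 1.0
    omega_a: float = 1.0
    T1a: float = 1.65
    w: float = 2.025
    tl: float = 1.5

    def __post_init__(self) -> None:
        for name in ("rho_b", "alpha", "C", "omega_a", "T1a", "w", "tl"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.alpha > 1:
            raise ValueError("labeling efficiency alpha cannot exceed 1")

    @property
    def denominator(self) -> float:
        return (
            2.0 * self.alpha * self.C * self.omega_a * self.T1a
            * math.exp(-self.w / self.T1a)
            * (1.0 - math.exp(-self.tl / self.T1a))
        )


def quantify_cbf(s_control, s_label, params: QuantificationParams | None = None):
    """CBF from control/label signals; scalar in, scalar out, array in, array out.

    The result is exactly linear in ``s_control - s_label`` and zero when
    the two signals coincide. Negative differences yield negative values,
    which are passed through (correlation edges are invariant to monotone
    linear effects; clipping would bias the covariance).
    """
    params = params or QuantificationParams()
    diff = np.asarray(s_control, dtype=float) - np.asarray(s_label, dtype=float)
    out = params.rho_b * diff / params.denominator
    if np.ndim(out) == 0:
        return float(out)
    return out


def normalize_to_global_mean(voxel_values, mask=None):
    """Divide voxel values by the whole-brain mean so that the mean becomes 1.

    ``mask`` (boolean, same shape) restricts both the mean computation and
    the returned values' defined region; outside-mask voxels are set to 0.
    Ratios between voxels are preserved; the operation is idempotent.
    """
    values = np.asarray(voxel_values, dtype=float)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != values.shape:
            raise ValueError("mask shape must match the values")
        selected = values[mask]
    else:
        selected = values.ravel()
    if selected.size == 0:
        raise ValueError("empty brain mask")
    mean = selected.mean()
    if mean == 0:
        raise ValueError("whole-brain mean CBF is zero; cannot normalize")
    out = values / mean
    if mask is not None:
        out = np.where(mask, out, 0.0)
    return out


def regional_means(
    voxel_values,
    labels,
    parcellation: Sequence[int] | None = None,
    empty_region: str = "error",
) -> dict[int, float]:
    """Mean voxel value per region of an integer label image.

    ``labels`` is aligned voxel-for-voxel with ``voxel_values``; label 0 is
    background and always excluded. ``parcellation`` lists the expected
    region ids (default: all nonzero labels present). A region without any
    voxel raises by default; ``empty_region="nan"`` emits NaN instead.
    """
    values = np.asarray(voxel_values, dtype=float).ravel()
    labs = np.asarray(labels).ravel()
    if values.shape != labs.shape:
        raise ValueError("voxel values and labels must be aligned")
    if parcellation is None:
        region_ids = [int(r) for r in np.unique(labs) if r != 0]
    else:
        region_ids = [int(r) for r in parcellation]
    out: dict[int, float] = {}
    for rid in region_ids:
        sel = labs == rid
        if not sel.any():
            if empty_region == "error":
                raise ValueError(f"region {rid} has no voxels in the label image")
            out[rid] = float("nan")
            continue
        out[rid] = float(values[sel].mean())
    neg = [rid for rid, v in out.items() if v < 0]
    if neg:
        logger.warning("negative mean CBF in %d region(s): %s", len(neg), neg[:5])
    return out


def read_parcellation(path) -> dict[int, str]:
    """Region id -> name mapping from a parcellation JSON file."""
    with open(path) as fh:
        raw = json.load(fh)
    return {int(k): str(v) for k, v in raw.items()}


def extract_regional_table(
    cbf_map_paths: Mapping[str, str] | Sequence[tuple[str, str]],
    labels_path,
    parcellation: Mapping[int, str],
    normalize: bool = True,
) -> pd.DataFrame:
    """Regional mean CBF table from per-subject NIfTI maps and a label volume.

    ``cbf_map_paths`` maps subject id -> NIfTI path. All maps must share the
    label volume's grid (no resampling is attempted; spatial normalization
    is assumed done upstream). Values are divided by each subject's
    whole-brain mean (over nonzero labels) when ``normalize`` is set.
    Returns a subjects x regions DataFrame with region names as columns.
    """
    import nibabel as nib

    labels = np.asanyarray(nib.load(str(labels_path)).dataobj).astype(int)
    items = cbf_map_paths.items() if isinstance(cbf_map_paths, Mapping) else cbf_map_paths
    region_ids = sorted(parcellation)
    rows = {}
    for subject, path in items:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj).astype(float)
        if data.shape != labels.shape:
            raise ValueError(
                f"map {path} has shape {data.shape} but labels have {labels.shape}"
            )
        if normalize:
            data = normalize_to_global_mean(data, mask=labels > 0)
        means = regional_means(data, labels, parcellation=region_ids)
        rows[subject] = [means[r] for r in region_ids]
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[parcellation[r] for r in region_ids]
    )
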