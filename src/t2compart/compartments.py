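"""Partition T2 spectra into the three water pools and assemble 3-D maps.

Grid nodes below 40 ms are labeled myelin water, nodes in [40, 250] ms
intra/extracellular water (IEw) and nodes above 250 ms CSF/free water. A node
exactly on a bound belongs to the IEw pool (the default 200-node log grid has
no node exactly at either bound, so this is a fixed convention). Each pool is
summarized by its relative amplitude (fraction of the total spectrum) and its
amplitude-weighted average T2; the weighted average is arithmetic in linear
ms by default, with the geometric mean available as an option.

The myelin and CSF weighted-T2 maps are produced for completeness but are
unreliable by construction: few echoes constrain T2 below 40 ms, and the
train stops at 320 ms so T2 above 250 ms is barely sampled. The IEw T2 map
is the quantitatively meaningful readout.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .acquisition import T2Grid

__all__ = [
    "CompartmentBounds",
    "CompartmentSummary",
    "MapSet",
    "partition_spectrum",
    "assemble_maps",
    "MAP_NAMES",
]

MAP_NAMES = (
    "myelin_fraction",
    "iew_fraction",
    "csf_fraction",
    "myelin_t2",
    "iew_t2",
    "csf_t2",
    "flip_angle",
    "residual_norm",
)


@dataclass(frozen=True)
class CompartmentBounds:
    """T2 cutoffs (ms) separating myelin water, IEw and CSF pools."""

    myelin_max: float = 40.0
    iew_max: float = 250.0

    def __post_init__(self) -> None:
        if not (0 < self.myelin_max < self.iew_max):
            raise ValueError("require 0 < myelin_max < iew_max")

    def labels(self, t2_values: np.ndarray) -> np.ndarray:
        """0 = myelin, 1 = IEw, 2 = CSF for each grid node (bounds are IEw)."""
        t2 = np.asarray(t2_values, dtype=float)
        out = np.ones(t2.shape, dtype=int)
        out[t2 < self.myelin_max] = 0
        out[t2 > self.iew_max] = 2
        return out


@dataclass(frozen=True)
class CompartmentSummary:
    """Per-voxel pool fractions and weighted T2s (myelin, IEw, CSF order)."""

    fractions: tuple[float, float, float]
    weighted_t2: tuple[float, float, float]
    total_amplitude: float


def partition_spectrum(
    amplitudes: np.ndarray,
    grid: T2Grid,
    bounds: CompartmentBounds | None = None,
    average: str = "arithmetic",
) -> CompartmentSummary:
    """Compartment fractions and weighted average T2s of one spectrum.

    Parameters
    ----------
    amplitudes : array
        Non-negative spectrum amplitudes on ``grid``.
    average : str
        ``"arithmetic"`` (default) or ``"geometric"`` amplitude-weighted mean.

    A zero-amplitude spectrum yields fractions (0, 0, 0) and NaN T2s; a pool
    with zero amplitude gets weighted T2 NaN.
    """
    bounds = bounds or CompartmentBounds()
    if average not in ("arithmetic", "geometric"):
        raise ValueError(f"unknown average {average!r}")
    a = np.asarray(amplitudes, dtype=float)
    t2 = grid.array
    if a.shape != t2.shape:
        raise ValueError("amplitudes and grid have different lengths")
    if np.any(a < 0):
        raise ValueError("spectrum amplitudes must be non-negative")
    total = float(a.sum())
    if total == 0.0:
        return CompartmentSummary((0.0, 0.0, 0.0), (np.nan, np.nan, np.nan), 0.0)
    labels = bounds.labels(t2)
    fractions = []
    wt2 = []
    for pool in (0, 1, 2):
        sel = labels == pool
        amp = float(a[sel].sum())
        fractions.append(amp / total)
        if amp == 0.0:
            wt2.append(np.nan)
        elif average == "arithmetic":
            wt2.append(float((a[sel] * t2[sel]).sum() / amp))
        else:
            wt2.append(float(np.exp((a[sel] * np.log(t2[sel])).sum() / amp)))
    return CompartmentSummary(tuple(fractions), tuple(wt2), total)


@dataclass
class MapSet:
    """The quantitative 3-D maps on a common voxel grid.

    Six compartment maps (fraction + weighted T2 per pool), the fitted
    flip-angle map and the residual-norm QC map. Out-of-mask or skipped
    voxels are NaN everywhere.
    """

    volumes: dict[str, np.ndarray]
    affine: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {v.shape for v in self.volumes.values()}
        if len(shapes) != 1:
            raise ValueError("all map volumes must share one shape")
        missing = set(MAP_NAMES) - set(self.volumes)
        if missing:
            raise ValueError(f"missing map volumes: {sorted(missing)}")

    @property
    def shape(self) -> tuple[int, ...]:
        return next(iter(self.volumes.values())).shape

    @property
    def voxel_volume_ml(self) -> float:
        """Voxel volume in milliliters from the affine."""
        mm3 = float(abs(np.linalg.det(self.affine[:3, :3])))
        return mm3 / 1000.0

    def save(self, outdir: str | Path, stem: str = "t2compart") -> list[Path]:
        """Write each map as float32 NIfTI-1 plus a JSON provenance sidecar."""
        import nibabel as nib

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        for name in MAP_NAMES:
            img = nib.Nifti1Image(self.volumes[name].astype(np.float32), self.affine)
            path = outdir / f"{stem}_{name}.nii.gz"
            nib.save(img, path)
            written.append(path)
        sidecar = outdir / f"{stem}_provenance.json"
        payload = dict(self.provenance)
        blob = json.dumps(payload, sort_keys=True, default=str)
        payload["config_hash"] = hashlib.sha256(blob.encode()).hexdigest()[:16]
        sidecar.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))
        written.append(sidecar)
        return written


def assemble_maps(
    amplitudes: np.ndarray,
    mask: np.ndarray,
    grid: T2Grid,
    affine: np.ndarray,
    bounds: CompartmentBounds | None = None,
    flip_angles: np.ndarray | None = None,
    residuals: np.ndarray | None = None,
    average: str = "arithmetic",
    provenance: dict | None = None,
) -> MapSet:
    """Build the MapSet from per-voxel spectra of the in-mask voxels.

    Parameters
    ----------
    amplitudes : (n_in_mask, n_t2) array
        Fitted spectra in mask-scan (C) order; rows of NaN mark skipped
        voxels. ``flip_angles``/``residuals`` align with the rows.
    mask : 3-D bool array
        In-mask voxels, ``mask.sum() == amplitudes.shape[0]``.
    """
    bounds = bounds or CompartmentBounds()
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise ValueError("mask must be 3-D")
    amplitudes = np.asarray(amplitudes, dtype=float)
    if amplitudes.ndim != 2 or amplitudes.shape[0] != int(mask.sum()):
        raise ValueError("amplitudes rows must match the number of in-mask voxels")
    n = amplitudes.shape[0]
    flip_angles = np.full(n, np.nan) if flip_angles is None else np.asarray(flip_angles, float)
    residuals = np.full(n, np.nan) if residuals is None else np.asarray(residuals, float)

    cols = {name: np.full(n, np.nan) for name in MAP_NAMES}
    for i in range(n):
        row = amplitudes[i]
        if np.any(np.isnan(row)):
            continue
        summ = partition_spectrum(row, grid, bounds, average=average)
        if summ.total_amplitude == 0.0:
            continue
        (cols["myelin_fraction"][i], cols["iew_fraction"][i], cols["csf_fraction"][i]) = summ.fractions
        (cols["myelin_t2"][i], cols["iew_t2"][i], cols["csf_t2"][i]) = summ.weighted_t2
        cols["flip_angle"][i] = flip_angles[i]
        cols["residual_norm"][i] = residuals[i]

    volumes = {}
    for name in MAP_NAMES:
        vol = np.full(mask.shape, np.nan)
        vol[mask] = cols[name]
        volumes[name] = vol
    prov = dict(provenance or {})
    prov.setdefault("grid", {"t_min": grid.values[0], "t_max": grid.values[-1], "n": len(grid)})
    prov.setdefault("bounds", {"myelin_max": bounds.myelin_max, "iew_max": bounds.iew_max})
    prov.setdefault("t2_average", average)
    return MapSet(volumes=volumes, affine=np.asarray(affine, dtype=float), provenance=prov)
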