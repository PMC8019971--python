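"""Synthetic multi-echo phantoms with known compartmental ground truth.

The phantom emulates the statistical structure the analysis assumes: each
voxel's noiseless echo train is a proton-density-weighted superposition of
EPG pool decays (myelin ~ 20 ms, intra/extracellular ~ 80 ms, fluid ~ 1 s),
the refocusing flip angle varies linearly across the volume (B1
inhomogeneity), and magnitude images carry Rician noise. A spherical lesion
has its IEw T2 elevated by 30 ms over white matter at the defaults, while the
FLAIR-positive mask covers only the lesion core — leaving a shell of elevated
T2 outside the FLAIR abnormality, the "mismatch" geometry.

The default white-matter model is 12% myelin water at 20 ms, 80% IEw at
80 ms and 8% fluid at 1000 ms; the lesion model is 6% / 86% / 8% with IEw at
110 ms, placing the lesion's IEw peak inside the 70-140 ms range where such
alterations are observed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .acquisition import AcquisitionParams
from .epg import epg_decay

__all__ = [
    "TissueModel",
    "PhantomSpec",
    "Phantom",
    "WHITE_MATTER",
    "LESION",
    "voxel_signal",
    "add_rician_noise",
    "make_phantom",
]


@dataclass(frozen=True)
class TissueModel:
    """Three-pool tissue model: (fraction, T2 ms) per pool + proton density."""

    myelin_fraction: float = 0.12
    myelin_t2: float = 20.0
    iew_fraction: float = 0.80
    iew_t2: float = 80.0
    csf_fraction: float = 0.08
    csf_t2: float = 1000.0
    proton_density: float = 1.0

    def __post_init__(self) -> None:
        total = self.myelin_fraction + self.iew_fraction + self.csf_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"pool fractions must sum to 1, got {total}")
        for t2 in (self.myelin_t2, self.iew_t2, self.csf_t2):
            if not t2 > 0:
                raise ValueError("pool T2s must be positive")

    @property
    def pools(self) -> tuple[tuple[float, float], ...]:
        return (
            (self.myelin_fraction, self.myelin_t2),
            (self.iew_fraction, self.iew_t2),
            (self.csf_fraction, self.csf_t2),
        )


WHITE_MATTER = TissueModel()
LESION = TissueModel(myelin_fraction=0.06, iew_fraction=0.86, iew_t2=110.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, tissue models, flip-angle field and noise of a phantom.

    All geometric quantities are in voxel units on the (default) 2.5 mm
    isotropic grid. ``snr`` is the first-echo tissue signal divided by the
    Gaussian channel noise sd; ``float("inf")`` disables noise.
    """

    shape: tuple[int, int, int] = (24, 24, 12)
    voxel_size: float = 2.5
    tissue: TissueModel = field(default_factory=lambda: WHITE_MATTER)
    lesion: TissueModel = field(default_factory=lambda: LESION)
    lesion_center: tuple[float, float, float] = (7.0, 12.0, 6.0)
    lesion_radius: float = 4.0
    flair_radius: float = 2.5
    ctv_margin: float = 4.0
    contralateral_radius: float = 3.0
    flip_start: float = 180.0
    flip_end: float = 160.0
    snr: float = 200.0
    seed: int = 0
    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)

    def __post_init__(self) -> None:
        if not self.snr > 0:
            raise ValueError("snr must be positive (use inf for noiseless)")
        if self.flair_radius > self.lesion_radius:
            raise ValueError("flair_radius must not exceed lesion_radius")
        if self.lesion_radius < 0:
            raise ValueError("lesion_radius must be >= 0")


def voxel_signal(
    model: TissueModel,
    flip: float,
    acq: AcquisitionParams | None = None,
) -> np.ndarray:
    """Noiseless echo train of a tissue model: superposition of pool decays."""
    acq = acq or AcquisitionParams()
    sig = np.zeros(acq.n_echoes)
    for fraction, t2 in model.pools:
        if fraction > 0:
            sig += fraction * epg_decay(t2, acq.t1_assumed, flip, acq)
    return model.proton_density * sig


def add_rician_noise(
    signal: np.ndarray,
    snr: float,
    seed: int | np.random.Generator = 0,
    ref_amplitude: float | None = None,
) -> np.ndarray:
    """Replace each sample s by sqrt((s + g1)^2 + g2^2), g ~ N(0, sigma^2).

    ``sigma = ref_amplitude / snr``; ``ref_amplitude`` defaults to the
    largest magnitude in ``signal`` (the first-echo amplitude for a decay).
    """
    signal = np.asarray(signal, dtype=float)
    if not snr > 0:
        raise ValueError("snr must be positive")
    if np.isinf(snr):
        return signal.copy()
    if ref_amplitude is None:
        ref_amplitude = float(np.max(np.abs(signal)))
        if ref_amplitude == 0.0:
            raise ValueError("ref_amplitude required for an all-zero signal")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigma = ref_amplitude / snr
    g1 = rng.normal(0.0, sigma, signal.shape)
    g2 = rng.normal(0.0, sigma, signal.shape)
    return np.sqrt((signal + g1) ** 2 + g2**2)


def _sphere(shape: tuple[int, int, int], center: tuple[float, float, float], radius: float) -> np.ndarray:
    if radius <= 0:
        return np.zeros(shape, dtype=bool)
    idx = np.indices(shape, dtype=float)
    d2 = sum((idx[i] - center[i]) ** 2 for i in range(3))
    return d2 <= radius**2


def _ellipsoid(shape: tuple[int, int, int]) -> np.ndarray:
    center = tuple((s - 1) / 2.0 for s in shape)
    semi = tuple(0.45 * s for s in shape)
    idx = np.indices(shape, dtype=float)
    d2 = sum(((idx[i] - center[i]) / semi[i]) ** 2 for i in range(3))
    return d2 <= 1.0


@dataclass
class Phantom:
    """Generated phantom: 4-D echo data, truth volumes, masks and affine."""

    data: np.ndarray                      # (nx, ny, nz, n_echoes)
    affine: np.ndarray
    masks: dict[str, np.ndarray]          # brain, lesion, flair, gtv, ctv, contralateral
    truth: dict[str, np.ndarray]          # per-voxel true fractions / T2s / flip
    spec: PhantomSpec

    @property
    def voxel_volume_ml(self) -> float:
        return float(self.spec.voxel_size**3) / 1000.0

    def save(self, outdir: str | Path) -> None:
        """Write echoes, truth maps, masks (NIfTI-1) and the resolved spec (YAML)."""
        import nibabel as nib

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), self.affine), outdir / "echoes.nii.gz")
        for name, m in self.masks.items():
            nib.save(nib.Nifti1Image(m.astype(np.uint8), self.affine), outdir / f"mask_{name}.nii.gz")
        for name, v in self.truth.items():
            nib.save(nib.Nifti1Image(v.astype(np.float32), self.affine), outdir / f"truth_{name}.nii.gz")
        spec = self.spec
        payload = {
            "shape": list(spec.shape),
            "voxel_size": spec.voxel_size,
            "tissue": vars(spec.tissue).copy(),
            "lesion": vars(spec.lesion).copy(),
            "lesion_center": list(spec.lesion_center),
            "lesion_radius": spec.lesion_radius,
            "flair_radius": spec.flair_radius,
            "ctv_margin": spec.ctv_margin,
            "contralateral_radius": spec.contralateral_radius,
            "flip_start": spec.flip_start,
            "flip_end": spec.flip_end,
            "snr": spec.snr,
            "seed": spec.seed,
        }
        (outdir / "phantom_spec.yaml").write_text(yaml.safe_dump(payload))


def make_phantom(spec: PhantomSpec | None = None, outdir: str | Path | None = None) -> Phantom:
    """Generate a multi-echo phantom volume with ground-truth sidecars.

    Deterministic for a fixed ``spec.seed``. The brain is a centered
    ellipsoid of white matter; the lesion sphere carries the lesion tissue
    model; the FLAIR-positive mask is the concentric lesion core (its GTV);
    the CTV is the GTV dilated by ``ctv_margin``; a contralateral ROI mirrors
    the lesion across x. Background voxels are pure noise.
    """
    spec = spec or PhantomSpec()
    acq = spec.acquisition
    shape = spec.shape

    brain = _ellipsoid(shape)
    lesion = _sphere(shape, spec.lesion_center, spec.lesion_radius) & brain
    flair = _sphere(shape, spec.lesion_center, spec.flair_radius) & brain
    gtv = flair.copy()
    ctv = _sphere(shape, spec.lesion_center, spec.flair_radius + spec.ctv_margin) & brain
    mirror_center = (shape[0] - 1 - spec.lesion_center[0], spec.lesion_center[1], spec.lesion_center[2])
    contralateral = _sphere(shape, mirror_center, spec.contralateral_radius) & brain & ~lesion

    nx = shape[0]
    flip_profile = spec.flip_start + (spec.flip_end - spec.flip_start) * (
        np.arange(nx) / max(nx - 1, 1)
    )
    flip_vol = np.broadcast_to(flip_profile[:, None, None], shape).astype(float).copy()
    flip_vol[~brain] = np.nan

    # Noiseless signals: one echo train per (tissue, quantized flip) pair.
    data = np.zeros(shape + (acq.n_echoes,), dtype=float)
    for ix in range(nx):
        flip = float(flip_profile[ix])
        sl_brain = brain[ix]
        if not sl_brain.any():
            continue
        sig_t = voxel_signal(spec.tissue, flip, acq)
        sig_l = voxel_signal(spec.lesion, flip, acq)
        sl_lesion = lesion[ix]
        data[ix][sl_brain & ~sl_lesion] = sig_t
        data[ix][sl_lesion] = sig_l

    # Rician noise: sigma referenced to the tissue first-echo amplitude at the
    # ideal 180 degree end of the flip ramp.
    ref = float(voxel_signal(spec.tissue, spec.flip_start, acq)[0])
    rng = np.random.default_rng(spec.seed)
    data = add_rician_noise(data, spec.snr, rng, ref_amplitude=ref)

    truth = {}
    for name, t_val, l_val in (
        ("myelin_fraction", spec.tissue.myelin_fraction, spec.lesion.myelin_fraction),
        ("iew_fraction", spec.tissue.iew_fraction, spec.lesion.iew_fraction),
        ("csf_fraction", spec.tissue.csf_fraction, spec.lesion.csf_fraction),
        ("myelin_t2", spec.tissue.myelin_t2, spec.lesion.myelin_t2),
        ("iew_t2", spec.tissue.iew_t2, spec.lesion.iew_t2),
        ("csf_t2", spec.tissue.csf_t2, spec.lesion.csf_t2),
    ):
        vol = np.full(shape, np.nan)
        vol[brain] = t_val
        vol[lesion] = l_val
        truth[name] = vol
    truth["flip_angle"] = flip_vol

    affine = np.diag([spec.voxel_size] * 3 + [1.0])
    masks = {
        "brain": brain,
        "lesion": lesion,
        "flair": flair,
        "gtv": gtv,
        "ctv": ctv,
        "contralateral": contralateral,
    }
    phantom = Phantom(data=data, affine=affine, masks=masks, truth=truth, spec=spec)
    if outdir is not None:
        phantom.save(outdir)
    return phantom
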