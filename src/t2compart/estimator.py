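"""Scikit-learn style interface to the voxelwise T2 decomposition.

`T2SpectrumFitter` treats echo trains as samples (rows) and transforms them
into compartment features: pool fractions, pool weighted T2s, fitted flip
angle and residual norm. It follows the sklearn estimator contract
(`get_params`/`set_params`, `fit`, `transform`, `n_features_in_`,
`get_feature_names_out`) so it composes with sklearn pipelines; the
module-level functions in :mod:`t2compart.fitting` remain the lower-level
functional API it wraps.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .acquisition import AcquisitionParams, T2Grid
from .compartments import CompartmentBounds, partition_spectrum
from .fitting import FitConfig, fit_voxels

__all__ = ["T2SpectrumFitter"]

_FEATURES = (
    "myelin_fraction",
    "iew_fraction",
    "csf_fraction",
    "myelin_t2",
    "iew_t2",
    "csf_t2",
    "flip_angle",
    "residual_norm",
)


class T2SpectrumFitter(BaseEstimator, TransformerMixin):
    """Transform multi-echo decays into three-pool compartment features.

    Parameters mirror the functional configuration: the log-T2 grid
    (``grid_min``/``grid_max``/``grid_n``), minimum-curvature regularization
    with discrepancy factor ``misfit_inflation``, the refocusing-angle search
    range/step, and the 40/250 ms compartment bounds. ``echo_spacing`` and
    the row length of X define the echo times.

    Examples
    --------
    >>> est = T2SpectrumFitter()
    >>> feats = est.fit_transform(echo_trains)   # (n_voxels, 8)
    """

    def __init__(
        self,
        grid_min: float = 1.0,
        grid_max: float = 3000.0,
        grid_n: int = 200,
        regularization: str = "min_curvature",
        misfit_inflation: float = 1.02,
        flip_min: float = 120.0,
        flip_max: float = 180.0,
        flip_step: float = 1.0,
        fit_flip: bool = True,
        flip_angle: float = 180.0,
        myelin_max: float = 40.0,
        iew_max: float = 250.0,
        echo_spacing: float = 10.0,
        t1_assumed: float = 1000.0,
        t2_average: str = "arithmetic",
    ):
        self.grid_min = grid_min
        self.grid_max = grid_max
        self.grid_n = grid_n
        self.regularization = regularization
        self.misfit_inflation = misfit_inflation
        self.flip_min = flip_min
        self.flip_max = flip_max
        self.flip_step = flip_step
        self.fit_flip = fit_flip
        self.flip_angle = flip_angle
        self.myelin_max = myelin_max
        self.iew_max = iew_max
        self.echo_spacing = echo_spacing
        self.t1_assumed = t1_assumed
        self.t2_average = t2_average

    def _configs(self, n_echoes: int) -> tuple[FitConfig, AcquisitionParams, CompartmentBounds]:
        acq = AcquisitionParams(
            n_echoes=n_echoes, echo_spacing=self.echo_spacing, t1_assumed=self.t1_assumed
        )
        cfg = FitConfig(
            grid=T2Grid.geometric(self.grid_min, self.grid_max, self.grid_n),
            regularization=self.regularization,
            misfit_inflation=self.misfit_inflation,
            flip_min=self.flip_min,
            flip_max=self.flip_max,
            flip_step=self.flip_step,
        )
        bounds = CompartmentBounds(myelin_max=self.myelin_max, iew_max=self.iew_max)
        return cfg, acq, bounds

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_features=2)
        self.n_features_in_ = X.shape[1]
        cfg, acq, bounds = self._configs(X.shape[1])
        self.fit_config_, self.acquisition_, self.bounds_ = cfg, acq, bounds
        self.grid_ = cfg.grid
        return self

    def transform(self, X) -> np.ndarray:
        """Fit every row and return the (n_samples, 8) compartment features."""
        check_is_fitted(self, "fit_config_")
        X = check_array(X, ensure_min_features=2)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} echoes; fitted with {self.n_features_in_}"
            )
        res = fit_voxels(
            X,
            self.fit_config_,
            self.acquisition_,
            fit_flip=self.fit_flip,
            flip_angle=self.flip_angle,
        )
        n = X.shape[0]
        out = np.full((n, len(_FEATURES)), np.nan)
        for i in range(n):
            amp = res["amplitudes"][i]
            if np.any(np.isnan(amp)):
                continue
            summ = partition_spectrum(amp, self.grid_, self.bounds_, average=self.t2_average)
            out[i, :3] = summ.fractions
            out[i, 3:6] = summ.weighted_t2
            out[i, 6] = res["flip_angle"][i]
            out[i, 7] = res["residual_norm"][i]
        return out

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(_FEATURES, dtype=object)
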