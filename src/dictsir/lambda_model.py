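"""Automatic selection of the regularization parameter.

The adaptive-weight dictionary reconstruction balances a data target and a
patch-model target through a single scalar ``lambda``.  Its proper value
depends on the scan protocol and the projection noise, and searching for it
by repeated reconstructions is expensive.  The selector implemented here
exploits the fact that one reconstruction pass with ``lambda -> infinity``
(pure patch-model updates) yields a weighted relative data-fidelity error

    delta_inf = sum_i (omega_i/2)([A mu_inf]_i - l_i)^2
                / sum_i (omega_i/2) l_i^2

that grows with the projection noise, exactly as the proper ``lambda``
does.  A piecewise-quadratic model fitted over a series of calibration
reconstructions maps the scaled predictor ``delta_G = 1e6 * delta_inf`` to
the recommended parameter:

    lambda* =  1.74485 dG^2 + 0.58883 dG - 6.88253   if dG > 1.96
    lambda* = -0.21545 dG^2 + 1.08602 dG - 0.32634   if dG <= 1.96

The full workflow is two reconstruction passes: one at infinite lambda to
measure ``delta_inf``, then one at ``lambda*``.

The model coefficients are data, not code: a refitted
:class:`LambdaModel` (see ``scripts/fit_lambda_model.py``) can be passed
anywhere the default is used.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .geometry import ScanGeometry, SystemMatrix, forward_project
from .reconstruct import (ReconConfig, ReconResult, run_count,
                          run_reconstruction, sart_reconstruct,
                          weighted_delta)
from .simulation import Sinogram

__all__ = [
    "LambdaModel",
    "PipelineReport",
    "relative_fidelity_error",
    "delta_at_infinity",
    "lambda_star",
    "awr_pipeline",
]


@dataclass(frozen=True)
class LambdaModel:
    """Piecewise-quadratic map from ``delta_G`` to ``lambda*``.

    ``scale`` converts the raw fidelity error to the predictor
    (``delta_G = scale * delta_inf``); each branch holds quadratic
    coefficients ``(a, b, c)`` for ``a x**2 + b x + c``.  The quadratics
    were fitted on calibration runs with ``delta_G`` roughly in
    ``operating_range``; outside it the model extrapolates (with a warning)
    and the result is clamped to ``lam_floor`` to stay positive.
    """

    scale: float = 1e6
    threshold: float = 1.96
    high: tuple[float, float, float] = (1.74485, 0.58883, -6.88253)
    low: tuple[float, float, float] = (-0.21545, 1.08602, -0.32634)
    operating_range: tuple[float, float] = (0.4, 10.0)
    lam_floor: float = 1e-2

    def branch_high(self, delta_g: float) -> float:
        a, b, c = self.high
        return a * delta_g ** 2 + b * delta_g + c

    def branch_low(self, delta_g: float) -> float:
        a, b, c = self.low
        return a * delta_g ** 2 + b * delta_g + c


DEFAULT_MODEL = LambdaModel()


def relative_fidelity_error(mu: np.ndarray, A: SystemMatrix,
                            omega: np.ndarray, l_ref: np.ndarray) -> float:
    """Weighted relative data-fidelity error ``delta`` of image ``mu``
    against reference line integrals ``l_ref``."""
    return weighted_delta(forward_project(A, mu), np.asarray(l_ref, float),
                          np.asarray(omega, float))


def lambda_star(delta_inf: float, model: LambdaModel = DEFAULT_MODEL) -> float:
    """Map the infinite-regularization fidelity error to the recommended
    regularization parameter via the piecewise-quadratic model.

    ``delta_inf`` is the raw (unscaled) error; warns when the scaled
    predictor leaves the model's calibrated operating range, and clamps the
    result to ``model.lam_floor`` if the extrapolated quadratic turns
    nonpositive.
    """
    if delta_inf < 0:
        raise ValueError("delta must be >= 0")
    dg = model.scale * delta_inf
    lo, hi = model.operating_range
    if not (lo <= dg <= hi):
        warnings.warn(f"delta_G = {dg:.4g} outside the calibrated range "
                      f"[{lo}, {hi}]; lambda* is an extrapolation",
                      RuntimeWarning, stacklevel=2)
    lam = model.branch_high(dg) if dg > model.threshold else model.branch_low(dg)
    if lam <= 0:
        warnings.warn(f"model gave nonpositive lambda* ({lam:.4g}); "
                      f"clamping to {model.lam_floor}", RuntimeWarning,
                      stacklevel=2)
        lam = model.lam_floor
    return float(lam)


def delta_at_infinity(sino: Sinogram, A: SystemMatrix | ScanGeometry,
                      dict_mode: str = "adaptive",
                      config: ReconConfig | None = None,
                      init_image: np.ndarray | None = None
                      ) -> tuple[float, ReconResult]:
    """Run the infinite-regularization pass and return its relative
    fidelity error against the measured data.

    With ``lambda = inf`` the image update is the pure patch-model
    projection ``mu = [d]_+``; iterating it only compounds the smoothing
    of the overlapping-patch average, so the limit of interest is the
    projection of the data-consistent warm start under a converged
    dictionary.  The pass therefore trains the dictionary on the warm
    start and applies one patch-model update with faithful coding (the
    relative-tolerance regime the annealed reconstruction pass reaches at
    its own fixed point); the resulting ``delta`` isolates the dictionary
    misfit plus the projection-noise floor, which is what the lambda
    selector is calibrated against.

    The measured integrals ``l_hat`` serve as the reference (the noiseless
    integrals are unknown at reconstruction time).
    """
    config = config or ReconConfig()
    cfg = replace(config, lam=math.inf, max_outer=1, code_tol=0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = run_reconstruction(sino, A, dict_mode=dict_mode, config=cfg,
                                 init_image=init_image)
    return res.delta, res


@dataclass
class PipelineReport:
    """Machine-readable record of one two-pass selection workflow."""

    delta_inf: float
    delta_g: float
    lam: float
    passes: int
    pass1_iters: int
    pass2_iters: int
    converged: bool


def awr_pipeline(sino: Sinogram, A: SystemMatrix | ScanGeometry,
                 dict_mode: str = "adaptive",
                 config: ReconConfig | None = None,
                 model: LambdaModel = DEFAULT_MODEL,
                 init_image: np.ndarray | None = None
                 ) -> tuple[ReconResult, PipelineReport]:
    """The two-pass adaptive-weight workflow.

    Pass 1 reconstructs with ``lambda = inf`` and measures ``delta_inf``;
    the piecewise-quadratic model turns it into ``lambda*``; pass 2
    reconstructs with ``lambda*``.  Both passes share one warm-start image
    (``init_image`` if given, else a SART pass) and the dictionary adapted
    to it in pass 1.  Returns the final reconstruction and a report;
    exactly two dictionary-SIR passes are executed.
    """
    config = config or ReconConfig()
    before = run_count()
    if init_image is not None:
        warm = np.asarray(init_image, dtype=float)
    elif config.init == "sart":
        warm = sart_reconstruct(sino, A, config).image
    else:
        warm = None
    d_inf, res1 = delta_at_infinity(sino, A, dict_mode, config,
                                    init_image=warm)
    lam = lambda_star(d_inf, model)
    # pass 2 reuses the dictionary adapted to the warm start in pass 1
    res2 = run_reconstruction(sino, A, dict_mode=dict_mode,
                              config=replace(config, lam=lam,
                                             dictionary=res1.dictionary),
                              init_image=warm)
    report = PipelineReport(delta_inf=d_inf, delta_g=model.scale * d_inf,
                            lam=lam, passes=run_count() - before,
                            pass1_iters=res1.n_iters,
                            pass2_iters=res2.n_iters,
                            converged=res1.converged and res2.converged)
    return res2, report
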