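"""Synthetic response surfaces for end-to-end pipeline testing.

Real conversion data for the esterification reaction exists only as the
48 published runs, so this module provides a stand-in ground truth: a
quadratic five-factor surface in coded units,

    y(x) = b0 + Σ li·xi + Σ qi·xi² + Σ cij·xi·xj,

with independent Gaussian replicate noise.  With every diagonal curvature
qi < 0 and no interactions the noiseless surface is strictly concave, so
it has a unique maximum on any bounded box — which lets argmax-recovery
tests compare the full pipeline (simulate → train → optimize) against a
closed-form answer.

The default coefficients mimic the qualitative shape of the published
optimum: an interior maximum in enzyme, temperature and agitation, but a
boundary maximum in time (longer is better up to the factorial limit) and
in molar ratio (less oleic-acid excess is better).  The default noise SD
of 5 conversion% matches the scatter of the study's replicated center
points (sample SD ≈ 4.9 over the seven published replicates).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import yaml

from .dataset import ExperimentRecord
from .doe import DesignPoint, PointRole, ReactionCondition

__all__ = ["SurfaceSpec", "analytic_argmax", "simulate_runs", "true_response"]

#: fraction of runs assigned to the training split (30 of 48 in the study)
TRAIN_FRACTION = 30 / 48


@dataclass(frozen=True)
class SurfaceSpec:
    """Quadratic response surface in coded units plus replicate noise."""

    intercept: float = 55.0
    linear: tuple[float, ...] = (-1.0, 6.0, 2.0, -5.0, 1.0)
    quadratic: tuple[float, ...] = (-6.0, -2.0, -5.0, -2.0, -4.0)
    interactions: tuple[tuple[int, int, float], ...] = ()
    noise_sd: float = 5.0  #: replicate SD, conversion %
    clip: bool = True  #: clip simulated conversions to [0, 100]

    def __post_init__(self) -> None:
        if len(self.linear) != len(self.quadratic):
            raise ValueError("linear and quadratic must have equal length")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def k(self) -> int:
        return len(self.linear)


def true_response(spec: SurfaceSpec, coded) -> np.ndarray:
    """Noiseless surface value at coded points, shape (m, k) or (k,)."""
    x = np.atleast_2d(np.asarray(coded, dtype=float))
    l = np.asarray(spec.linear)
    q = np.asarray(spec.quadratic)
    y = spec.intercept + x @ l + (x**2) @ q
    for i, j, c in spec.interactions:
        y = y + c * x[:, i] * x[:, j]
    return y if np.asarray(coded).ndim == 2 else y[0]


def analytic_argmax(
    spec: SurfaceSpec, bounds: Sequence[tuple[float, float]]
) -> tuple[np.ndarray, float]:
    """Closed-form box-constrained maximum of a separable concave surface.

    Requires no interaction terms and all quadratic coefficients < 0; each
    coordinate then maximizes independently at clip(−li / 2qi, lo, hi).
    """
    if spec.interactions:
        raise ValueError("analytic argmax requires a separable surface (no interactions)")
    q = np.asarray(spec.quadratic)
    if np.any(q >= 0):
        raise ValueError("analytic argmax requires strictly negative curvature")
    l = np.asarray(spec.linear)
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    x = np.clip(-l / (2.0 * q), lo, hi)
    return x, float(true_response(spec, x[None, :])[0])


def simulate_runs(
    spec: SurfaceSpec,
    design: Sequence[DesignPoint],
    seed: int,
) -> list[ExperimentRecord]:
    """Simulate one run table over a design.

    Adds iid Gaussian noise (SD ``spec.noise_sd``) to the true response at
    every design point and clips to [0, 100] when ``spec.clip`` is set.
    Splits are deterministic given the seed: all axial and center points
    go to training (they pin curvature and the intercept), and shuffled
    factorial points top the training set up to round(0.625·n) runs — the
    study's 30/48 proportion — with the rest becoming the test set.
    """
    design = list(design)
    coded = np.array([p.coded for p in design], dtype=float)
    if coded.shape[1] != spec.k:
        raise ValueError(f"design has {coded.shape[1]} factors, surface expects {spec.k}")
    rng = np.random.default_rng(seed)
    y = true_response(spec, coded) + rng.normal(0.0, spec.noise_sd, size=len(design))
    if spec.clip:
        y = np.clip(y, 0.0, 100.0)

    n_train = int(round(TRAIN_FRACTION * len(design)))
    non_factorial = [i for i, p in enumerate(design) if p.role != PointRole.FACTORIAL]
    factorial = [i for i, p in enumerate(design) if p.role == PointRole.FACTORIAL]
    rng.shuffle(factorial)
    train_idx = set(non_factorial) | set(factorial[: max(0, n_train - len(non_factorial))])

    records = []
    for i, p in enumerate(design):
        records.append(
            ExperimentRecord(
                run_id=i + 1,
                condition=ReactionCondition.from_array(p.natural) if spec.k == 5 else None,
                conversion_actual=float(y[i]),
                split="train" if i in train_idx else "test",
            )
        )
    return records


def read_surface_yaml(path) -> SurfaceSpec:
    """Load a surface description from YAML (keys = SurfaceSpec fields)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "linear" in raw:
        raw["linear"] = tuple(raw["linear"])
    if "quadratic" in raw:
        raw["quadratic"] = tuple(raw["quadratic"])
    if "interactions" in raw:
        raw["interactions"] = tuple((int(i), int(j), float(c)) for i, j, c in raw["interactions"])
    return SurfaceSpec(**raw)
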