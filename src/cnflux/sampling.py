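"""Uniform sampling of the steady-state flux polytope.

Artificially-centered hit-and-run (ACHR): warmup points are the FVA extreme
solutions of the pruned model; the chain then repeatedly steps from its
current point along the direction from the running center towards a randomly
chosen stored point, landing uniformly on the feasible chord.  Directions are
differences of steady-state points and therefore stay in the null space of S,
so every sample is mass-balanced by construction (up to float accumulation).

Every run is a pure function of ``(model, n_points, step_count, seed)``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fba import fva
from .model import MetabolicModel

__all__ = [
    "FluxSampleSet",
    "ValidationReport",
    "generate_warmup",
    "sample",
    "validate_samples",
    "write_samples_tsv",
    "read_samples_tsv",
]

_DIR_TOL = 1e-11  # coordinates with |direction| below this do not bound the chord
_CLIP_TOL = 1e-9  # bound overshoot repaired by clipping


@dataclass
class FluxSampleSet:
    reaction_ids: list[str]
    samples: np.ndarray  # n_samples x n_reactions
    meta: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    def column(self, rid: str) -> np.ndarray:
        return self.samples[:, self.reaction_ids.index(rid)]


@dataclass(frozen=True)
class ValidationReport:
    n_samples: int
    max_mass_balance_residual: float
    max_bound_violation: float
    n_offending: int


def generate_warmup(model: MetabolicModel, seed: int = 0) -> np.ndarray:
    """FVA-extreme flux vectors (2 per reaction) plus their centroid.

    The LP solutions at each per-reaction minimum/maximum are vertices of the
    flux polytope; their centroid is an interior starting point for the chain.
    The result is deterministic; *seed* is accepted for interface symmetry.
    """
    from .fba import _lp_parts, _solve_lp

    S, bounds = _lp_parts(model)
    b_eq = np.zeros(S.shape[0])
    n = len(model.reactions)
    points = []
    for j in range(n):
        c = np.zeros(n)
        for sign in (1.0, -1.0):
            c[j] = sign
            res, status = _solve_lp(c, S, b_eq, bounds)
            if status != "optimal":
                raise RuntimeError(
                    f"warmup LP for {model.reaction_ids[j]} is {status}"
                )
            points.append(res.x.copy())
    points = np.asarray(points)
    centroid = points.mean(axis=0)
    return np.vstack([points, centroid])


def sample(
    model: MetabolicModel, n_points: int, step_count: int, seed: int
) -> FluxSampleSet:
    """Draw ``n_points`` flux vectors by ACHR.

    ``step_count`` is the total mixing parameter in the published convention
    (2x the number of reactions by default); it is converted to a per-sample
    thinning of ``ceil(step_count / n_points)`` chain steps (minimum 1)
    between retained points.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    if step_count < 1:
        raise ValueError("step_count must be >= 1")
    rng = np.random.default_rng(seed)
    warmup = generate_warmup(model)
    lb, ub = model.bounds_arrays()
    thinning = max(1, math.ceil(step_count / n_points))

    # orthonormal basis of the steady-state null space over the non-fixed
    # coordinates: projecting every direction onto it keeps S v = 0 exact
    # instead of letting LP residuals amplify when a direction is short
    from scipy.linalg import null_space

    free = ub - lb > 1e-12
    S = model.stoichiometric_matrix()
    basis = null_space(S[:, free]) if free.any() else np.zeros((0, 0))

    targets = [w for w in warmup]
    center = warmup.mean(axis=0)
    n_seen = len(targets)
    x = warmup[-1].copy()  # the centroid
    retained: list[np.ndarray] = []

    if basis.size == 0:  # polytope is a single point
        samples = np.tile(x, (n_points, 1))
        meta = {
            "seed": int(seed), "n_points": int(n_points),
            "step_count": int(step_count), "thinning": int(thinning),
            "condition": "",
        }
        return FluxSampleSet(list(model.reaction_ids), samples, meta)

    def _project(raw: np.ndarray) -> np.ndarray:
        d = np.zeros_like(raw)
        d[free] = basis @ (basis.T @ raw[free])
        return d

    while len(retained) < n_points:
        for _ in range(thinning):
            # direction: from the running center towards a random stored point
            for _try in range(16):
                t = targets[rng.integers(len(targets))]
                d = _project(t - center)
                norm = np.linalg.norm(d)
                if norm > 1e-9:
                    break
            else:  # every candidate collapsed onto the center: keep x as is
                break
            d = d / norm
            movable = np.abs(d) > _DIR_TOL
            if not movable.any():
                continue
            lo = (lb[movable] - x[movable]) / d[movable]
            hi = (ub[movable] - x[movable]) / d[movable]
            a_min = np.minimum(lo, hi).max()
            a_max = np.maximum(lo, hi).min()
            if not np.isfinite(a_min) or not np.isfinite(a_max) or a_max - a_min < 1e-12:
                continue
            alpha = rng.uniform(a_min, a_max)
            x = x + alpha * d
            # numerical guard: repair sub-tolerance overshoot by clipping;
            # anything larger means the chord arithmetic failed
            over = np.maximum(x - ub, lb - x)
            worst = over.max()
            if worst > _CLIP_TOL:
                # re-project onto the chord interior and continue
                alpha_safe = np.clip(alpha, a_min, a_max)
                x = x - (alpha - alpha_safe) * d
                over = np.maximum(x - ub, lb - x)
                if over.max() > _CLIP_TOL:
                    raise RuntimeError(
                        f"sample escaped the polytope by {over.max():.3g}"
                    )
            x = np.clip(x, lb, ub)
            center = (center * n_seen + x) / (n_seen + 1)
            n_seen += 1
        retained.append(x.copy())
        targets.append(x.copy())

    samples = np.asarray(retained[:n_points])
    meta = {
        "seed": int(seed),
        "n_points": int(n_points),
        "step_count": int(step_count),
        "thinning": int(thinning),
        "condition": "",
    }
    return FluxSampleSet(list(model.reaction_ids), samples, meta)


def validate_samples(
    model: MetabolicModel,
    s: FluxSampleSet,
    tol_ss: float = 1e-6,
    tol_b: float = 1e-9,
) -> ValidationReport:
    """Report mass-balance and bound violations over a sample matrix."""
    if s.n_samples == 0:
        return ValidationReport(0, 0.0, 0.0, 0)
    order = [s.reaction_ids.index(rid) for rid in model.reaction_ids]
    V = s.samples[:, order]
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    residual = np.abs(S @ V.T)  # metabolites x samples
    max_res_per_row = residual.max(axis=0) if residual.size else np.zeros(V.shape[0])
    bound_viol = np.maximum(np.maximum(lb - V, V - ub), 0.0).max(axis=1)
    offending = (max_res_per_row > tol_ss) | (bound_viol > tol_b)
    return ValidationReport(
        n_samples=int(V.shape[0]),
        max_mass_balance_residual=float(max_res_per_row.max(initial=0.0)),
        max_bound_violation=float(bound_viol.max(initial=0.0)),
        n_offending=int(offending.sum()),
    )


def write_samples_tsv(s: FluxSampleSet, path) -> None:
    """Samples as TSV (header = reaction ids) with a JSON meta sidecar."""
    pd.DataFrame(s.samples, columns=s.reaction_ids).to_csv(
        path, sep="\t", index=False, float_format="%.12g"
    )
    with open(str(path) + ".meta.json", "w") as fh:
        json.dump(s.meta, fh, indent=1)
        fh.write("\n")


def read_samples_tsv(path) -> FluxSampleSet:
    df = pd.read_csv(path, sep="\t")
    meta = {}
    try:
        with open(str(path) + ".meta.json") as fh:
            meta = json.load(fh)
    except FileNotFoundError:
        pass
    return FluxSampleSet(list(df.columns), df.to_numpy(float), meta)
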