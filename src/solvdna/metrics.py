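"""Density prediction error metrics and learning-curve bookkeeping.

The central quantity is the integrated absolute density error

    eps_rho (%) = 100 * integral |rho_test(r) - rho_ref(r)| dr
                        / integral rho_ref(r) dr,

evaluated on a shared cubic grid (the volume element cancels).  With the
projected (auxiliary-basis) reference this is the model-fitting error
(eps_rho^ML); with the original gridded reference it is the true error
(eps_rho^true) which adds the constant projection error on top.  The
electron-count error is the signed relative error of the predicted total
electron number, reported in percent: negative means the model
underestimates the number of electrons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import ScalarField
from .structure import Structure, heavy_atom_count


@dataclass
class DensityError:
    eps_ml: float          # percent, vs projected reference
    eps_true: float | None  # percent, vs original reference (if supplied)
    grid_spacing: float    # Bohr


@dataclass
class ElectronCountError:
    eps_nele: float  # signed percent
    n_ml: float
    n_true: float


@dataclass
class LearningCurvePoint:
    heavy_atoms_in_training: int
    mean_eps: float
    std_err: float


def epsilon_rho(ml_field: ScalarField, ref_field: ScalarField) -> float:
    """Integrated absolute density error in percent of the reference density."""
    if not ml_field.same_grid(ref_field):
        raise ValueError("epsilon_rho requires both fields on the identical grid.")
    denom = ref_field.values.sum()
    if denom <= 0:
        raise ValueError("Reference density integrates to a non-positive value.")
    return float(100.0 * np.abs(ml_field.values - ref_field.values).sum() / denom)


def epsilon_nele(n_ml: float, n_true: float) -> float:
    """Signed relative electron-count error in percent.

    Negative values mean the model underestimates the electron count.
    """
    if n_true <= 0:
        raise ValueError(f"Reference electron count must be positive, got {n_true}.")
    return float(100.0 * (n_ml - n_true) / n_true)


def learning_curve(
    records: list[tuple[list[Structure] | int, np.ndarray | list[float]]],
) -> list[LearningCurvePoint]:
    """Aggregate per-subset evaluation errors into learning-curve points.

    Each record is ``(training_subset, eps_values)`` where the subset is
    either a list of training structures (heavy atoms are counted) or the
    heavy-atom count itself.  Points are sorted by training size; the
    spread is the standard error of the mean.
    """
    if not records:
        raise ValueError("learning_curve needs at least one record.")
    points = []
    for subset, eps_values in records:
        eps = np.asarray(eps_values, dtype=float)
        if eps.size == 0:
            raise ValueError("Each learning-curve record needs at least one evaluation value.")
        if isinstance(subset, int):
            x = subset
        else:
            x = sum(heavy_atom_count(s) for s in subset)
        if x <= 0:
            raise ValueError("Training subsets must contain at least one heavy atom.")
        sem = float(eps.std(ddof=1) / np.sqrt(eps.size)) if eps.size > 1 else 0.0
        points.append(LearningCurvePoint(x, float(eps.mean()), sem))
    return sorted(points, key=lambda p: p.heavy_atoms_in_training)


def mean_with_sem(values: np.ndarray | list[float]) -> tuple[float, float]:
    """Mean and standard error of the mean (the table-style "a ± b")."""
    v = np.asarray(values, dtype=float)
    sem = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0
    return float(v.mean()), sem
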