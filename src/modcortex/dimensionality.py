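"""Cross-validated dimensionality of activity-pattern ensembles.

The ensemble of event patterns (or an events x cells matrix) is split into
two non-overlapping halves X1 and X2; principal axes are estimated on X1 and
the variance lambda_i explained by each axis is measured on X2.  The
participation ratio

    d_eff = (sum_i lambda_i)^2 / sum_i lambda_i^2

counts the effective number of independent patterns: it equals n when all
variances are equal and 1 for a rank-1 ensemble.  Cross-validation prevents
the upward bias of within-sample PCA; projected variances can come out
slightly negative after the (shared) mean is removed and are clipped at zero
before the ratio, a conservative and declared choice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class SpectrumEstimate:
    """Cross-validated variance spectrum."""

    lambda_i: np.ndarray      # variance of X2 projected on X1's axes
    n_components: int
    train_idx: np.ndarray
    test_idx: np.ndarray
    seed: int


@dataclass
class DimensionalityResult:
    d_eff: float
    n_variance_75: int
    n_samples: int = 1
    meta: dict | None = None


def _as_matrix(ensemble) -> np.ndarray:
    """Accept a PatternEnsemble or an (N, features) array."""
    from modcortex.corrnet import PatternEnsemble

    if isinstance(ensemble, PatternEnsemble):
        return ensemble.patterns[:, ensemble.roi_mask]
    x = np.asarray(ensemble, dtype=float)
    if x.ndim == 3:
        return x.reshape(x.shape[0], -1)
    return x


def crossval_spectrum(
    ensemble,
    split_fraction: float = 0.5,
    seed: int = 0,
) -> SpectrumEstimate:
    """Split-half cross-validated principal-component spectrum.

    Patterns are mean-centered per feature across the full ensemble, randomly
    divided into train/test subsets, principal axes computed on the train
    half by SVD, and lambda_i taken as the variance of the test half
    projected on axis i.
    """
    x = _as_matrix(ensemble)
    n = x.shape[0]
    if n < 4:
        raise ValueError("need at least 4 patterns for a cross-validated spectrum")
    x = x - x.mean(axis=0)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(n * split_fraction))
    n_train = min(max(n_train, 2), n - 2)
    train_idx, test_idx = perm[:n_train], perm[n_train:]
    x1, x2 = x[train_idx], x[test_idx]
    # principal axes of the training half
    _, _, vt = np.linalg.svd(x1 - x1.mean(axis=0), full_matrices=False)
    proj = (x2 - x2.mean(axis=0)) @ vt.T
    lam = proj.var(axis=0)
    return SpectrumEstimate(
        lambda_i=lam,
        n_components=lam.size,
        train_idx=train_idx,
        test_idx=test_idx,
        seed=seed,
    )


def participation_ratio(lambda_i) -> float:
    """d_eff = (sum lambda)^2 / sum lambda^2, negatives clipped at zero."""
    lam = np.asarray(lambda_i, dtype=float)
    lam = np.clip(lam, 0.0, None)
    total = lam.sum()
    if total == 0:
        raise ValueError("all-zero variance spectrum")
    return float(total**2 / (lam**2).sum())


def variance_75_count(lambda_i) -> int:
    """Smallest number of components explaining >= 75% of total variance."""
    lam = np.sort(np.clip(np.asarray(lambda_i, dtype=float), 0.0, None))[::-1]
    total = lam.sum()
    if total <= 0:
        raise ValueError("total variance must be positive")
    frac = np.cumsum(lam) / total
    return int(np.searchsorted(frac, 0.75 - 1e-12) + 1)


def crossval_dimensionality(
    ensemble,
    n_splits: int = 20,
    split_fraction: float = 0.5,
    seed: int = 0,
) -> DimensionalityResult:
    """Participation ratio averaged over seeded random splits."""
    d_effs, n75s = [], []
    for k in range(n_splits):
        spec = crossval_spectrum(ensemble, split_fraction, seed=seed + k)
        d_effs.append(participation_ratio(spec.lambda_i))
        n75s.append(variance_75_count(spec.lambda_i))
    return DimensionalityResult(
        d_eff=float(np.mean(d_effs)),
        n_variance_75=int(round(np.mean(n75s))),
        n_samples=n_splits,
        meta={"d_eff_per_split": d_effs},
    )


def cellular_dimensionality(
    cell_event_matrix: np.ndarray,
    n_cells_subset: int = 50,
    n_frames_subset: int = 100,
    n_samples: int = 100,
    seed: int = 0,
) -> DimensionalityResult:
    """Size-controlled dimensionality of a cellular event matrix.

    Draws ``n_samples`` random subsets of ``n_cells_subset`` cells and
    ``n_frames_subset`` event frames (without replacement; sizes shrink with
    a warning when the matrix is smaller), computes the cross-validated
    participation ratio on each subset, and averages.
    """
    x = np.asarray(cell_event_matrix, dtype=float)
    n_events, n_cells = x.shape
    if n_events < 4:
        raise ValueError("need at least 4 event frames")
    if x.std() == 0:
        raise ValueError("degenerate (constant) cell-event matrix")
    if n_cells < n_cells_subset:
        warnings.warn(
            f"only {n_cells} cells available; reducing subset from {n_cells_subset}"
        )
        n_cells_subset = n_cells
    if n_events < n_frames_subset:
        warnings.warn(
            f"only {n_events} events available; reducing subset from {n_frames_subset}"
        )
        n_frames_subset = n_events
    rng = np.random.default_rng(seed)
    d_effs, n75s = [], []
    for k in range(n_samples):
        cells = rng.choice(n_cells, size=n_cells_subset, replace=False)
        frames = rng.choice(n_events, size=n_frames_subset, replace=False)
        sub = x[np.ix_(frames, cells)]
        spec = crossval_spectrum(sub, seed=int(rng.integers(0, 2**31 - 1)))
        d_effs.append(participation_ratio(spec.lambda_i))
        n75s.append(variance_75_count(spec.lambda_i))
    return DimensionalityResult(
        d_eff=float(np.mean(d_effs)),
        n_variance_75=int(round(np.mean(n75s))),
        n_samples=n_samples,
        meta={"n_cells_subset": n_cells_subset, "n_frames_subset": n_frames_subset},
    )
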