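"""Residual-based removal of unwanted variation (RUVr).

Hidden sample-level factors (batch, technical artefacts) are estimated from
the residuals of a first-pass supervised NB GLM: whatever structure remains
in the residuals after the known design is accounted for is, by assumption,
unwanted variation.  The first k right-singular vectors of the gene-centred
deviance-residual matrix give per-sample factor loadings W, which are then
appended to every engine's design matrix so all three models are corrected
identically.  Negative-control-gene (RUVg) and technical-replicate (RUVs)
variants are out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import _glm
from .de_engines import DesignMatrix, estimate_tagwise_dispersion
from .errors import DesignError
from .experiment_io import ContrastPair, CountExperiment, subset_for_pair
from .normalization import NormFactors, tmm_factors


@dataclass
class RUVFactors:
    """Estimated unwanted-variation factors for one contrast.

    ``W`` is samples x k with unit-norm columns whose largest-magnitude entry
    is positive (a fixed SVD sign convention, making the estimate
    deterministic).  ``residuals`` is the genes x samples deviance-residual
    matrix of the first-pass fit, kept for the residual diagnostic plot.
    """

    W: np.ndarray
    k: int
    residuals: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.k < 1:
            raise DesignError("k must be >= 1")
        if self.W.shape[1] != self.k:
            raise DesignError("W has wrong number of columns")


def ruv_r(
    exp: CountExperiment,
    pair: ContrastPair,
    design: DesignMatrix | None = None,
    k: int = 1,
    norm: NormFactors | None = None,
) -> RUVFactors:
    """Estimate k unwanted-variation factors from first-pass GLM residuals.

    The supervised design (group + pairing, no W) is fitted as an NB GLM
    with TMM offsets at the common dispersion; deviance residuals are
    gene-centred and decomposed by SVD.  W holds the first k right-singular
    vectors (sample loadings).
    """
    if k < 1:
        raise DesignError("k must be >= 1")
    sub = subset_for_pair(exp, pair)
    if design is None:
        from .de_engines import build_design

        design = build_design(sub.sample_meta, pair)
    n = len(sub.sample_names)
    if design.n_samples != n:
        raise DesignError("design rows do not match contrast samples")
    max_k = n - np.linalg.matrix_rank(design.matrix)
    if k > max_k:
        raise DesignError(
            f"k={k} exceeds the residual dimension {max_k} "
            f"({n} samples, design rank {np.linalg.matrix_rank(design.matrix)})"
        )
    if norm is None:
        norm = tmm_factors(sub.counts)
    y = sub.counts.to_numpy(dtype=float)
    offsets = np.log(norm.effective_lib_sizes)
    tested = y.sum(axis=1) > 0
    yt = y[tested]

    _, common = estimate_tagwise_dispersion(yt, design, offsets)
    fit = _glm.fit_nb_glm(yt, design.matrix, offsets, common)
    resid = np.zeros_like(y)
    resid[tested] = _glm.deviance_residuals(yt, fit.mu, common)

    return factors_from_residuals(resid, k)


def factors_from_residuals(residuals: np.ndarray, k: int) -> RUVFactors:
    """Extract k sample-loading factors from a residual matrix.

    Genes (rows) are centred, then the first k right-singular vectors of the
    centred matrix become the columns of W.
    """
    resid = np.asarray(residuals, dtype=float)
    n = resid.shape[1]
    if k < 1:
        raise DesignError("k must be >= 1")
    centred = resid - resid.mean(axis=1, keepdims=True)
    if np.allclose(centred, 0.0):
        warnings.warn(
            "degenerate (all-zero) residual matrix; returning zero factors",
            RuntimeWarning,
            stacklevel=2,
        )
        return RUVFactors(W=np.zeros((n, k)), k=k, residuals=resid)

    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    W = vt[:k].T.copy()
    for j in range(k):
        if W[np.argmax(np.abs(W[:, j])), j] < 0:
            W[:, j] = -W[:, j]
    return RUVFactors(W=W, k=k, residuals=resid)


def augment_design(design: DesignMatrix, factors: RUVFactors) -> DesignMatrix:
    """Append the W columns to a design; the tested coefficient is unchanged."""
    if factors.W.shape[0] != design.n_samples:
        raise DesignError(
            f"W has {factors.W.shape[0]} rows but the design has "
            f"{design.n_samples} samples"
        )
    matrix = design.matrix
    columns = list(design.columns)
    for j in range(factors.k):
        candidate = np.column_stack([matrix, factors.W[:, j]])
        if np.linalg.matrix_rank(candidate) <= np.linalg.matrix_rank(matrix):
            raise DesignError(
                f"RUV factor W_{j + 1} is collinear with existing design "
                f"columns {columns}"
            )
        matrix = candidate
        columns.append(f"W_{j + 1}")
    return DesignMatrix(matrix=matrix, columns=columns, coef=design.coef)
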