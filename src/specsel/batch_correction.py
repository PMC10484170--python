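"""Surrogate-variable estimation and removal for expression matrices.

Model: on a log2(TPM + 1) scale, expression of gene *i* in sample *j* is

    y_ij = mu_i + f_i(t_j) + sum_k lambda_ki h_kj + e_ij

where f_i is a per-treatment-category mean deviation, the h_k are
surrogate variables — orthonormal sample-space vectors spanning the
dominant structure of the design residuals — and lambda_ki are their
per-gene loadings.  Surrogates are the top right singular vectors of the
residual matrix; the number K is chosen by a row-permutation test of
each singular value's variance share (Buja-Eyuboglu style): each
residual row is permuted independently, the permuted matrix is
re-projected onto the design's orthogonal complement, and a component is
kept while its observed share exceeds the permutation null at level
alpha.  This is a deliberate simplification of the iteratively
reweighted svaseq estimator: the model contract (design fit, surrogate
span, loading removal) is the same, the weighting scheme is not.

Loadings are estimated jointly with the design (least squares of each
gene on [intercept, treatment dummies, surrogates]) so removal does not
absorb treatment signal; corrected values are back-transformed with
2**y - 1 and clipped at 0.

The `SurrogateVariableModel` class follows the scikit-learn
fit/transform idiom (fitted attributes end in an underscore) and is also
usable through the three module-level functions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix


def log2_tpm(values: np.ndarray) -> np.ndarray:
    return np.log2(values + 1.0)


def inverse_log2_tpm(values: np.ndarray) -> np.ndarray:
    return np.clip(np.exp2(values) - 1.0, 0.0, None)


@dataclass
class DesignFit:
    """Per-gene treatment-mean decomposition of a transformed matrix."""

    treatment_labels: np.ndarray  # per sample
    categories: np.ndarray
    mu: np.ndarray  # per-gene grand mean
    deviations: np.ndarray  # gene x category: f(y)
    fitted: np.ndarray  # gene x sample
    residuals: np.ndarray  # gene x sample


def fit_treatment_design(y: np.ndarray, treatment_labels: np.ndarray) -> DesignFit:
    """Fit fitted_ij = mu_i + f_i(t_j) by per-category gene means.

    ``y`` is the transformed genes x samples matrix.  Every category in
    ``treatment_labels`` must be present among the samples.
    """
    treatment_labels = np.asarray(treatment_labels)
    if treatment_labels.shape[0] != y.shape[1]:
        raise ValueError("one treatment label per sample required")
    categories, codes = np.unique(treatment_labels, return_inverse=True)
    counts = np.bincount(codes, minlength=len(categories))
    if (counts == 0).any():
        missing = categories[counts == 0]
        raise ValueError(f"treatment categories absent from matrix: {missing}")
    # per-gene per-category means
    sums = np.zeros((y.shape[0], len(categories)))
    for k in range(len(categories)):
        sums[:, k] = y[:, codes == k].sum(axis=1)
    cat_means = sums / counts
    mu = y.mean(axis=1)
    deviations = cat_means - mu[:, None]
    fitted = cat_means[:, codes]
    return DesignFit(
        treatment_labels=treatment_labels,
        categories=categories,
        mu=mu,
        deviations=deviations,
        fitted=fitted,
        residuals=y - fitted,
    )


def _design_matrix(treatment_labels: np.ndarray) -> np.ndarray:
    categories, codes = np.unique(treatment_labels, return_inverse=True)
    x = np.zeros((len(treatment_labels), len(categories)))
    x[np.arange(len(codes)), codes] = 1.0
    return x  # full indicator basis (spans intercept)


def _residual_projector(design: np.ndarray) -> np.ndarray:
    """Projector onto the orthogonal complement of the design columns."""
    q, _ = np.linalg.qr(design)
    return np.eye(design.shape[0]) - q @ q.T


@dataclass
class SurrogateModel:
    """Fitted surrogate-variable model.

    ``surrogates`` is samples x K with orthonormal columns; ``loadings``
    is genes x K.  ``variance_shares`` and ``p_values`` describe the
    permutation test behind the choice of K.
    """

    treatment_labels: np.ndarray
    mu: np.ndarray
    surrogates: np.ndarray
    loadings: np.ndarray
    k_selected: int
    variance_shares: np.ndarray
    p_values: np.ndarray
    transform: str = "log2_tpm_plus_1"


def estimate_surrogates(
    residuals: np.ndarray,
    y: np.ndarray,
    treatment_labels: np.ndarray,
    k: int | str = "auto",
    n_permutations: int = 200,
    alpha: float = 0.05,
    rng: np.random.Generator | int | None = None,
) -> SurrogateModel:
    """Estimate surrogate vectors from design residuals.

    ``residuals`` and ``y`` are genes x samples (transformed scale).
    With ``k="auto"``, K is the number of leading singular values whose
    variance share beats its row-permutation null at level ``alpha``
    (p-values forced monotone non-decreasing, testing stops at the first
    acceptance).  The permutation RNG must be seeded by the caller.
    """
    treatment_labels = np.asarray(treatment_labels)
    design = _design_matrix(treatment_labels)
    rank = np.linalg.matrix_rank(design)
    k_max = min(residuals.shape) - rank
    if isinstance(k, int) and k > k_max:
        raise ValueError(f"k={k} exceeds min(genes, samples) - rank(design) = {k_max}")
    _, svals, vt = np.linalg.svd(residuals, full_matrices=False)
    shares = svals**2 / (svals**2).sum()

    if k == "auto":
        rng = np.random.default_rng(rng)
        proj = _residual_projector(design)
        n_test = min(k_max, len(svals))
        exceed = np.zeros(n_test)
        for _ in range(n_permutations):
            perm = _permute_rows(residuals, rng) @ proj.T
            ps = np.linalg.svd(perm, compute_uv=False)
            pshares = ps**2 / (ps**2).sum()
            exceed += pshares[:n_test] >= shares[:n_test]
        p = (1.0 + exceed) / (n_permutations + 1.0)
        p = np.maximum.accumulate(p)  # enforce monotone p-values
        k_sel = 0
        while k_sel < n_test and p[k_sel] <= alpha:
            k_sel += 1
        p_values = p
    elif isinstance(k, int):
        if k < 0:
            raise ValueError("k must be >= 0")
        k_sel = k
        p_values = np.full(len(svals), np.nan)
    else:
        raise ValueError(f"k must be an int or 'auto', got {k!r}")

    surrogates = vt[:k_sel].T  # samples x K, orthonormal
    loadings = _fit_loadings(y, design, surrogates)
    return SurrogateModel(
        treatment_labels=treatment_labels,
        mu=y.mean(axis=1),
        surrogates=surrogates,
        loadings=loadings,
        k_selected=k_sel,
        variance_shares=shares,
        p_values=p_values,
    )


def _permute_rows(mat: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independently permute the entries within each row."""
    idx = np.argsort(rng.random(mat.shape), axis=1)
    return np.take_along_axis(mat, idx, axis=1)


def _fit_loadings(y: np.ndarray, design: np.ndarray, surrogates: np.ndarray) -> np.ndarray:
    """Per-gene least-squares loadings on the surrogates, jointly with design."""
    k = surrogates.shape[1]
    if k == 0:
        return np.zeros((y.shape[0], 0))
    x = np.hstack([design, surrogates])
    coef, *_ = np.linalg.lstsq(x, y.T, rcond=None)
    return coef[design.shape[1] :].T  # genes x K


def remove_surrogates(matrix: ExpressionMatrix, model: SurrogateModel) -> ExpressionMatrix:
    """Subtract fitted surrogate effects and back-transform to TPM.

    corrected_ij = inverse(transform(x_ij) - sum_k lambda_ki h_kj),
    clipped at zero.  Sample count and order must match the fit.
    """
    if model.surrogates.shape[0] != matrix.values.shape[1]:
        raise ValueError("sample count differs between matrix and fitted model")
    y = log2_tpm(matrix.values.to_numpy(dtype=float))
    if model.loadings.shape[0] != y.shape[0]:
        raise ValueError("gene count differs between matrix and fitted model")
    corrected = y - model.loadings @ model.surrogates.T
    out = matrix.values.copy()
    out.iloc[:, :] = inverse_log2_tpm(corrected)
    return ExpressionMatrix(out, matrix.samples_meta.copy())


class SurrogateVariableModel:
    """Scikit-learn-style transformer wrapping the SVA workflow.

    Parameters
    ----------
    k : int or "auto"
        Number of surrogate variables, or permutation-test selection.
    n_permutations, alpha : permutation-test settings for ``k="auto"``.
    random_state : seed for the permutation RNG (required for "auto").

    Fitted attributes: ``surrogates_`` (samples x K), ``loadings_``
    (genes x K), ``k_selected_``, ``design_fit_``, ``model_``.
    """

    def __init__(
        self,
        k: int | str = "auto",
        n_permutations: int = 200,
        alpha: float = 0.05,
        random_state: int | None = None,
    ):
        self.k = k
        self.n_permutations = n_permutations
        self.alpha = alpha
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            "k": self.k,
            "n_permutations": self.n_permutations,
            "alpha": self.alpha,
            "random_state": self.random_state,
        }

    def set_params(self, **params) -> "SurrogateVariableModel":
        for key, val in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, val)
        return self

    def fit(self, matrix: ExpressionMatrix, by: str = "treatment_label") -> "SurrogateVariableModel":
        y = log2_tpm(matrix.values.to_numpy(dtype=float))
        labels = matrix.meta_of(by).to_numpy()
        self.design_fit_ = fit_treatment_design(y, labels)
        self.model_ = estimate_surrogates(
            self.design_fit_.residuals,
            y,
            labels,
            k=self.k,
            n_permutations=self.n_permutations,
            alpha=self.alpha,
            rng=self.random_state,
        )
        self.surrogates_ = self.model_.surrogates
        self.loadings_ = self.model_.loadings
        self.k_selected_ = self.model_.k_selected
        return self

    def transform(self, matrix: ExpressionMatrix) -> ExpressionMatrix:
        if not hasattr(self, "model_"):
            raise RuntimeError("fit must be called before transform")
        return remove_surrogates(matrix, self.model_)

    def fit_transform(self, matrix: ExpressionMatrix, by: str = "treatment_label") -> ExpressionMatrix:
        return self.fit(matrix, by=by).transform(matrix)


def subset_min_studies(matrix: ExpressionMatrix, min_studies: int = 2) -> ExpressionMatrix:
    """Keep treatments whose samples come from at least ``min_studies`` studies.

    Applied before SVA so between-treatment variation is not confounded
    with the technical between-study variation being removed.
    """
    meta = matrix.samples_meta.loc[list(matrix.values.columns)]
    n_studies = meta.groupby("treatment_label")["study_id"].nunique()
    keep_treat = set(n_studies[n_studies >= min_studies].index)
    keep = meta["treatment_label"].isin(keep_treat)
    if not keep.any():
        raise ValueError(f"no treatment has data from >= {min_studies} studies")
    return matrix.subset_samples(list(meta.index[keep]))


def model_sidecar(model: SurrogateModel) -> pd.DataFrame:
    """Surrogate vectors plus variance shares as a tidy frame."""
    k = model.k_selected
    df = pd.DataFrame(
        model.surrogates, columns=[f"sv{i+1}" for i in range(k)]
    )
    df.insert(0, "treatment_label", model.treatment_labels)
    return df
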