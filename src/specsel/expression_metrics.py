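"""Expression summaries: replicate collapsing, group means, tau, averages.

The specificity index tau for a gene with per-category mean expression
vector x (N >= 2 categories) is

    tau = sum_i (1 - x_i / max(x)) / (N - 1)

which is 0 when expression is uniform across categories and 1 when the
gene is expressed in exactly one category.  Group means for tau include
zeros; the separate *average expression* covariate excludes values
below a TPM threshold (default 5, boundary kept) so that rarely
expressed genes are not automatically assigned low average expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, FormatError


@dataclass(frozen=True)
class GroupMeanVector:
    gene_id: str
    group_labels: tuple[str, ...]
    means: np.ndarray

    @property
    def n_groups(self) -> int:
        return len(self.group_labels)


@dataclass(frozen=True)
class SpecificityResult:
    gene_id: str
    tau: float | None
    n_groups: int


def collapse_technical_replicates(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Average runs sharing an experiment ID into one column each.

    Runs with the same experiment ID are technical replicates of one
    biological sample; their metadata (study, tissue, treatment) must
    agree, otherwise the conflict is an error.
    """
    meta = matrix.samples_meta.loc[list(matrix.values.columns)]
    exp_ids = meta["experiment_id"]
    for exp_id, grp in meta.groupby("experiment_id", sort=False):
        for col in ("study_id", "tissue_label", "treatment_label"):
            if col in grp.columns and grp[col].nunique() > 1:
                raise FormatError(
                    f"conflicting {col} within experiment {exp_id}: "
                    f"{sorted(grp[col].unique())}"
                )
    collapsed = matrix.values.T.groupby(exp_ids, sort=False).mean().T
    new_meta = meta.drop_duplicates("experiment_id").set_index("experiment_id", drop=False)
    new_meta.index.name = None
    if "run_id" in new_meta.columns:
        new_meta = new_meta.assign(run_id=new_meta["experiment_id"])
    return ExpressionMatrix(collapsed, new_meta.loc[list(collapsed.columns)])


def group_means(matrix: ExpressionMatrix, label_field: str) -> pd.DataFrame:
    """Per-gene, per-category unweighted mean TPM (zeros included).

    ``label_field`` is a metadata column (``treatment_label`` or
    ``tissue_label``, or the short forms ``treatment``/``tissue``).
    Returns a genes x categories DataFrame.
    """
    field = {"treatment": "treatment_label", "tissue": "tissue_label"}.get(
        label_field, label_field
    )
    labels = matrix.meta_of(field)
    return matrix.values.T.groupby(labels.to_numpy(), sort=True).mean().T


def tau(means: np.ndarray | GroupMeanVector) -> float | None:
    """Expression specificity in [0, 1]; None for unexpressed genes or N < 2."""
    x = means.means if isinstance(means, GroupMeanVector) else np.asarray(means, dtype=float)
    n = x.size
    if n < 2:
        return None
    m = x.max()
    if m <= 0:
        return None
    return float(np.sum(1.0 - x / m) / (n - 1))


def tau_frame(group_mean_frame: pd.DataFrame) -> pd.Series:
    """tau per gene from a genes x categories mean frame (vectorized)."""
    x = group_mean_frame.to_numpy(dtype=float)
    n = x.shape[1]
    out = np.full(x.shape[0], np.nan)
    if n >= 2:
        m = x.max(axis=1)
        ok = m > 0
        out[ok] = (1.0 - x[ok] / m[ok, None]).sum(axis=1) / (n - 1)
    return pd.Series(out, index=group_mean_frame.index, name="tau")


def thresholded_average_expression(
    matrix: ExpressionMatrix, threshold_tpm: float = 5.0
) -> pd.Series:
    """Per-gene mean over experiments with TPM >= threshold; NaN if none pass."""
    vals = matrix.values.to_numpy(dtype=float)
    mask = vals >= threshold_tpm
    counts = mask.sum(axis=1)
    with np.errstate(invalid="ignore"):
        avg = np.where(counts > 0, (vals * mask).sum(axis=1) / np.maximum(counts, 1), np.nan)
    return pd.Series(avg, index=matrix.values.index, name="avg_expr")


def treatment_specificity(matrix: ExpressionMatrix) -> pd.DataFrame:
    """tau over treatment-category means, one row per gene."""
    gm = group_means(matrix, "treatment_label")
    t = tau_frame(gm)
    return pd.DataFrame({"tau": t, "n_groups": gm.shape[1]})


def tissue_specificity(
    matrix: ExpressionMatrix, condition_filter: str | None = "control"
) -> pd.DataFrame:
    """tau over tissue-category means, computed on one treatment condition.

    ``condition_filter`` keeps only samples with that treatment label
    (None keeps all); NaN tau when fewer than two tissue categories
    remain.
    """
    if condition_filter is not None:
        keep = matrix.meta_of("treatment_label") == condition_filter
        if not keep.any():
            raise FormatError(f"no samples with treatment {condition_filter!r}")
        matrix = matrix.subset_samples(list(matrix.values.columns[keep.to_numpy()]))
    gm = group_means(matrix, "tissue_label")
    t = tau_frame(gm)
    return pd.DataFrame({"tau": t, "n_groups": gm.shape[1]})
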