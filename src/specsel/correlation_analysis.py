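"""Partial Spearman correlations between specificity and selection measures.

The partial Spearman correlation of x and y given covariates Z is
computed by rank-transforming every variable (average ranks for ties),
forming the Pearson correlation matrix of the ranked columns, and
reading the partial correlation off the precision matrix:

    rho_xy.Z = -Omega_xy / sqrt(Omega_xx * Omega_yy)

The p-value uses the t statistic rho * sqrt((n - 2 - k) / (1 - rho^2))
on n - 2 - k degrees of freedom (k = number of covariates), matching
the convention of standard partial-correlation packages; no
multiple-testing correction is applied.

Analysis-table assembly applies the study's covariate and filter rules:
average expression, gene length, GC fraction and tissue specificity are
always controlled; gene family size is added for the within-species
targets (piN, Tajima's D); divergence-based targets (dN, DoS) are
restricted to 1:1 orthologs, and dN additionally drops genes with
saturating synonymous divergence (dS > 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class PartialCorrelationResult:
    var_x: str
    var_y: str
    covariates: tuple[str, ...]
    rho: float
    p_value: float
    n: int


class CollinearityError(ValueError):
    """Rank-degenerate covariates; names the offending pair when found."""


def _check_collinear(corr: np.ndarray, names: list[str]) -> None:
    # pairs involving a covariate make the precision matrix singular;
    # perfect x-y agreement is legitimate (rho = +-1) and handled upstream
    k = corr.shape[0]
    for i in range(k):
        for j in range(max(i + 1, 2), k):
            if abs(corr[i, j]) > 1.0 - 1e-12:
                raise CollinearityError(
                    f"collinear variables after ranking: {names[i]!r} and {names[j]!r}"
                )


def spearman_partial(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    names: tuple[str, str] = ("x", "y"),
    covariate_names: tuple[str, ...] = (),
) -> PartialCorrelationResult:
    """Partial Spearman correlation of x and y given covariate columns.

    Inputs must be complete cases (no NaN); with no covariates this
    reduces exactly to the ordinary Spearman rank correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None:
        covariates = np.empty((x.size, 0))
    covariates = np.asarray(covariates, dtype=float)
    if covariates.ndim == 1:
        covariates = covariates[:, None]
    n, k = covariates.shape[0], covariates.shape[1]
    if x.size != n or y.size != n:
        raise ValueError("x, y and covariates must have equal length")
    cols = np.column_stack([x, y, covariates])
    if np.isnan(cols).any():
        raise ValueError("complete cases required (NaN present)")
    if n <= k + 2:
        raise ValueError(f"need n > covariates + 2 (n={n}, k={k})")
    ranked = np.apply_along_axis(stats.rankdata, 0, cols)  # average ranks
    all_names = list(names) + list(
        covariate_names or tuple(f"z{i+1}" for i in range(k))
    )
    corr = np.corrcoef(ranked, rowvar=False)
    _check_collinear(corr, all_names)
    if abs(corr[0, 1]) > 1.0 - 1e-12:
        rho = float(np.sign(corr[0, 1]))
        return PartialCorrelationResult(
            var_x=names[0], var_y=names[1], covariates=tuple(all_names[2:]),
            rho=rho, p_value=0.0, n=n,
        )
    try:
        omega = np.linalg.inv(corr)
    except np.linalg.LinAlgError as exc:
        raise CollinearityError(f"singular rank-correlation matrix: {exc}") from exc
    rho = float(-omega[0, 1] / np.sqrt(omega[0, 0] * omega[1, 1]))
    rho = max(-1.0, min(1.0, rho))
    df = n - 2 - k
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt(df / (1.0 - rho**2))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return PartialCorrelationResult(
        var_x=names[0],
        var_y=names[1],
        covariates=tuple(all_names[2:]),
        rho=rho,
        p_value=p,
        n=n,
    )


TARGETS = ("dN", "piN", "tajimaD", "DoS")

_TARGET_COLUMN = {"dN": "d_n", "piN": "pi_n", "tajimaD": "tajima_d", "DoS": "dos"}
BASE_COVARIATES = ("avg_expr", "length_bp", "gc_fraction", "tau_tissue")


def build_analysis_table(
    table: pd.DataFrame, target: str, heatmap_extra: bool = False
) -> tuple[pd.DataFrame, list[str]]:
    """Per-target analysis slice of the gene table (complete cases).

    Returns the filtered frame and the covariate column list for the
    target.  Rules: family size joins the covariates for piN and
    Tajima's D; dN and DoS keep only 1:1 orthologs (``one_to_one``
    truthy); dN drops saturated genes.
    """
    if target not in TARGETS:
        raise ValueError(f"unknown target {target!r}; expected one of {TARGETS}")
    col = _TARGET_COLUMN[target]
    covs = list(BASE_COVARIATES)
    if target in ("piN", "tajimaD"):
        covs.append("family_size")
    df = table
    if target in ("dN", "DoS") and "one_to_one" in df.columns:
        df = df[df["one_to_one"].fillna(False).astype(bool)]
    if target == "dN" and "saturated" in df.columns:
        df = df[~df["saturated"].fillna(False).astype(bool)]
    needed = ["tau_treatment", col] + covs
    df = df.dropna(subset=[c for c in needed if c in df.columns])
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"gene table lacks columns {missing}")
    return df, covs


def target_correlation(table: pd.DataFrame, target: str) -> PartialCorrelationResult:
    """Partial Spearman of treatment specificity with one selection measure."""
    df, covs = build_analysis_table(table, target)
    col = _TARGET_COLUMN[target]
    return spearman_partial(
        df["tau_treatment"].to_numpy(),
        df[col].to_numpy(),
        df[covs].to_numpy(),
        names=("tau_treatment", col),
        covariate_names=tuple(covs),
    )


def correlation_heatmap(
    table: pd.DataFrame,
    variables: list[str],
    control: str = "remaining",
    fixed_covariates: list[str] | None = None,
) -> pd.DataFrame:
    """All-pairs partial Spearman matrix over the listed variables.

    ``control="remaining"`` conditions every pair on all other listed
    variables (the heatmap convention); ``control="fixed"`` conditions
    on ``fixed_covariates`` only.  Complete cases across every listed
    column.  Returns a long-format frame (var_x, var_y, rho, p, n).
    """
    if len(variables) < 3 and control == "remaining":
        raise ValueError("need at least 3 variables for a partial heatmap")
    cols = list(variables) + list(fixed_covariates or [])
    df = table.dropna(subset=sorted(set(cols)))
    rows = []
    for i, vx in enumerate(variables):
        for vy in variables[i + 1 :]:
            if control == "remaining":
                covs = [v for v in variables if v not in (vx, vy)]
            else:
                covs = [v for v in (fixed_covariates or []) if v not in (vx, vy)]
            res = spearman_partial(
                df[vx].to_numpy(),
                df[vy].to_numpy(),
                df[covs].to_numpy() if covs else None,
                names=(vx, vy),
                covariate_names=tuple(covs),
            )
            rows.append(
                {"var_x": vx, "var_y": vy, "rho": res.rho, "p": res.p_value, "n": res.n}
            )
    return pd.DataFrame(rows)


def assemble_gene_table(
    specificity: pd.DataFrame | None = None,
    tissue_tau: pd.Series | None = None,
    avg_expr: pd.Series | None = None,
    covariates: pd.DataFrame | None = None,
    selection: pd.DataFrame | None = None,
    divergence: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Outer-join the per-gene pieces into one analysis table.

    All inputs are indexed (or keyed) by gene ID; missing pieces leave
    NA columns, and the per-target filters handle them downstream.
    """
    parts: list[pd.DataFrame] = []
    if specificity is not None:
        parts.append(specificity[["tau"]].rename(columns={"tau": "tau_treatment"}))
    if tissue_tau is not None:
        parts.append(tissue_tau.rename("tau_tissue").to_frame())
    if avg_expr is not None:
        parts.append(avg_expr.rename("avg_expr").to_frame())
    if covariates is not None:
        parts.append(covariates)
    if selection is not None:
        parts.append(selection)
    if divergence is not None:
        parts.append(divergence)
    if not parts:
        raise ValueError("nothing to assemble")
    out = parts[0]
    for p in parts[1:]:
        out = out.join(p, how="outer")
    out.index.name = "gene_id"
    return out.reset_index()
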