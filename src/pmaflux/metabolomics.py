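"""Differential analysis of GC–MS metabolite intensity tables.

The procedure mirrors the standard untargeted-metabolomics workflow for a
two-condition (carbon source) × two-timepoint design with biological
replicates:

1. per-sample normalization by the geometric mean of spiked internal
   standards (corrects injection/extraction variation),
2. unit-variance scaling of each metabolite across samples,
3. PCA for overview, PLS-DA for supervised discrimination with VIP
   (variable importance in projection) scores,
4. per-metabolite two-sided pooled-variance Student's t on log intensities,
   Benjamini–Hochberg FDR,
5. log2 fold changes of group means,
6. multi-criterion selection: p < alpha AND VIP > vip_min AND q <= fdr,
7. Ward hierarchical clustering of scaled profiles.

Statistical tests run on log-transformed *normalized* intensities (unit
variance scaling would erase the mean differences they test); fold changes
are ratios of group means of normalized intensities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from statsmodels.stats.multitest import multipletests

__all__ = [
    "IntensityTable",
    "PcaResult",
    "DifferentialResult",
    "normalize_by_internal_standard",
    "uv_scale",
    "pca",
    "plsda_vip",
    "two_sample_t",
    "bh_fdr",
    "fold_change",
    "select_differential",
    "run_differential_analysis",
    "hierarchical_clustering",
]

#: default thresholds of the selection rule
ALPHA = 0.05
VIP_MIN = 1.0
FDR_LIMIT = 0.05


@dataclass
class IntensityTable:
    """Metabolites × samples intensity matrix with its sample design.

    ``values``: DataFrame indexed by metabolite id, columns = sample ids,
    strictly positive intensities (arbitrary units).
    ``design``: DataFrame indexed by sample id with columns ``carbon_source``,
    ``timepoint_h``, ``replicate``.
    ``internal_standard_ids``: metabolite ids of spiked standards; retained in
    the table but excluded from statistics.
    """

    values: pd.DataFrame
    design: pd.DataFrame
    internal_standard_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.internal_standard_ids = tuple(self.internal_standard_ids)
        self.validate()

    def validate(self) -> None:
        if not (self.values.to_numpy() > 0).all():
            raise ValueError("intensities must be strictly positive")
        if list(self.values.columns) != list(self.design.index):
            raise ValueError("design rows do not match sample columns")
        for col in ("carbon_source", "timepoint_h", "replicate"):
            if col not in self.design.columns:
                raise ValueError(f"design is missing column {col!r}")
        missing = set(self.internal_standard_ids) - set(self.values.index)
        if missing:
            raise ValueError(f"internal standards not in table: {sorted(missing)}")

    # -- helpers -----------------------------------------------------------
    def group_key(self) -> pd.Series:
        """Per-sample '<carbon_source>_<timepoint_h>' labels."""
        return (
            self.design["carbon_source"].astype(str)
            + "_"
            + self.design["timepoint_h"].astype(int).astype(str)
        )

    def samples_in_group(self, group: str) -> list[str]:
        key = self.group_key()
        samples = list(key.index[key == group])
        if not samples:
            raise KeyError(f"no samples in group {group!r}")
        return samples

    def analyte_values(self) -> pd.DataFrame:
        """Values without internal-standard rows."""
        return self.values.drop(index=list(self.internal_standard_ids))


def normalize_by_internal_standard(table: IntensityTable) -> IntensityTable:
    """Divide each sample column by the geometric mean of its internal
    standards.  Standard rows are retained (they become constant up to
    numerical noise) but stay excluded from statistics."""
    if not table.internal_standard_ids:
        raise ValueError("table declares no internal standards")
    standards = table.values.loc[list(table.internal_standard_ids)]
    bad = standards.columns[(standards <= 0).any(axis=0)]
    if len(bad):
        raise ValueError(
            f"non-positive internal-standard intensity in sample {bad[0]!r}"
        )
    geo_mean = np.exp(np.log(standards).mean(axis=0))
    return replace(table, values=table.values.div(geo_mean, axis=1))


def uv_scale(values: pd.DataFrame) -> pd.DataFrame:
    """Unit-variance scale: center each metabolite row and divide by its
    sample standard deviation (n−1).  Zero-variance rows are dropped with a
    warning."""
    if values.shape[1] < 2:
        raise ValueError("unit-variance scaling needs at least 2 samples")
    sd = values.std(axis=1, ddof=1)
    constant = sd.index[sd == 0]
    if len(constant):
        warnings.warn(
            f"dropping {len(constant)} zero-variance metabolite(s): "
            f"{list(constant[:5])}",
            stacklevel=2,
        )
        values = values.drop(index=constant)
        sd = sd.drop(index=constant)
    return values.sub(values.mean(axis=1), axis=0).div(sd, axis=0)


@dataclass
class PcaResult:
    scores: pd.DataFrame  # samples × components
    loadings: pd.DataFrame  # metabolites × components, orthonormal
    explained_variance: np.ndarray


def pca(scaled: pd.DataFrame, n_components: int | None = None) -> PcaResult:
    """PCA of samples in metabolite space via SVD of the scaled matrix.

    ``scaled`` is metabolites × samples with rows already centered (as
    produced by :func:`uv_scale`).  Component sign is fixed by making the
    largest-magnitude loading positive.
    """
    X = scaled.to_numpy().T  # samples × metabolites
    n, p = X.shape
    max_rank = min(n, p)
    k = max_rank if n_components is None else int(n_components)
    if k < 1 or k > max_rank:
        raise ValueError(f"n_components must be in [1, {max_rank}]")
    if not np.isfinite(X).all():
        raise ValueError("scaled matrix contains non-finite entries")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    # deterministic sign: largest |loading| per component is positive
    for a in range(max_rank):
        j = np.argmax(np.abs(Vt[a]))
        if Vt[a, j] < 0:
            Vt[a] *= -1.0
            U[:, a] *= -1.0
    scores = U[:, :k] * s[:k]
    loadings = Vt[:k].T
    explained = s**2 / (n - 1)
    return PcaResult(
        scores=pd.DataFrame(
            scores, index=scaled.columns, columns=[f"PC{i+1}" for i in range(k)]
        ),
        loadings=pd.DataFrame(
            loadings, index=scaled.index, columns=[f"PC{i+1}" for i in range(k)]
        ),
        explained_variance=explained[:k],
    )


def plsda_vip(
    scaled: pd.DataFrame,
    group_labels: pd.Series | np.ndarray,
    n_components: int = 2,
) -> pd.Series:
    """VIP scores from a PLS-DA model fit by NIPALS.

    ``scaled`` is metabolites × samples (unit-variance scaled); the group
    labels must take exactly two values.  The class indicator is regressed on
    the sample profiles by PLS1 (sequential deflation); the VIP of metabolite
    *j* is::

        VIP_j = sqrt( p * sum_a SSY_a w_aj^2 / sum_a SSY_a )

    with *p* the number of metabolites, SSY_a the response variance captured
    by component *a*, and *w_a* the unit-norm weight vectors — so that
    sum_j VIP_j^2 = p exactly.
    """
    labels = np.asarray(group_labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"PLS-DA needs exactly two groups, got {classes.size}")
    for c in classes:
        if (labels == c).sum() < 2:
            raise ValueError(f"group {c!r} has fewer than 2 samples")
    X = scaled.to_numpy().T.astype(float)  # samples × p
    y = np.where(labels == classes[1], 1.0, 0.0)
    y = y - y.mean()
    n, p = X.shape
    if labels.shape[0] != n:
        raise ValueError("group labels do not match sample count")

    max_rank = min(n - 1, p)
    if n_components > max_rank:
        warnings.warn(
            f"n_components={n_components} exceeds rank; truncated to {max_rank}",
            stacklevel=2,
        )
        n_components = max_rank

    weights = []
    ssy = []
    Xa, ya = X.copy(), y.copy()
    for _ in range(n_components):
        w = Xa.T @ ya
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            break  # response fully explained
        w /= norm
        t = Xa @ w
        tt = float(t @ t)
        if tt < 1e-12:
            break
        p_load = Xa.T @ t / tt
        q = float(ya @ t) / tt
        Xa = Xa - np.outer(t, p_load)
        ya = ya - q * t
        weights.append(w)
        ssy.append(q * q * tt)
    if not weights:
        # no covariance between X and the classes: all variables equally
        # (un)important; the normalization identity still holds
        return pd.Series(np.ones(p), index=scaled.index, name="vip")
    W = np.vstack(weights)  # a × p
    ssy_arr = np.asarray(ssy)
    vip = np.sqrt(p * (ssy_arr @ W**2) / ssy_arr.sum())
    return pd.Series(vip, index=scaled.index, name="vip")


def two_sample_t(
    log_values_a: pd.DataFrame, log_values_b: pd.DataFrame
) -> pd.DataFrame:
    """Two-sided pooled-variance Student's t per metabolite row.

    Inputs are log-transformed normalized intensities for the two groups
    (same row index).  Zero pooled variance yields t = 0, p = 1 (conservative)
    with a warning.
    """
    if list(log_values_a.index) != list(log_values_b.index):
        raise ValueError("groups carry different metabolite sets")
    if log_values_a.shape[1] < 2 or log_values_b.shape[1] < 2:
        raise ValueError("each group needs at least 2 replicates")
    a = log_values_a.to_numpy()
    b = log_values_b.to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=True)
    degenerate = ~np.isfinite(t)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} metabolite(s) with zero pooled variance; "
            "reporting t=0, p=1",
            stacklevel=2,
        )
        t = np.where(degenerate, 0.0, t)
        p = np.where(degenerate, 1.0, p)
    return pd.DataFrame(
        {"t_statistic": t, "p_value": p}, index=log_values_a.index
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1,
    order-preserving with the input)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fold_change(
    table: IntensityTable, control_group: str, treated_group: str
) -> pd.Series:
    """log2(mean treated / mean control) of normalized intensities, per
    metabolite (internal standards excluded)."""
    values = table.analyte_values()
    a = values[table.samples_in_group(control_group)].mean(axis=1)
    b = values[table.samples_in_group(treated_group)].mean(axis=1)
    if (a <= 0).any() or (b <= 0).any():
        raise ValueError("group means must be positive")
    return pd.Series(np.log2(b / a), index=values.index, name="fold_change_log2")


@dataclass
class DifferentialResult:
    """Per-metabolite differential table for one contrast, plus the rule
    that produced the ``selected`` flag."""

    table: pd.DataFrame  # mean_A mean_B fold_change_log2 t_statistic p_value q_value vip selected
    control_group: str
    treated_group: str
    alpha: float = ALPHA
    vip_min: float = VIP_MIN
    fdr_limit: float = FDR_LIMIT

    @property
    def n_selected(self) -> int:
        return int(self.table["selected"].sum())


def select_differential(
    fold_changes: pd.Series,
    t_table: pd.DataFrame,
    vip: pd.Series,
    means_a: pd.Series,
    means_b: pd.Series,
    control_group: str,
    treated_group: str,
    alpha: float = ALPHA,
    vip_min: float = VIP_MIN,
    fdr_limit: float = FDR_LIMIT,
) -> DifferentialResult:
    """Combine the per-metabolite statistics and apply the selection rule
    ``selected = (p < alpha) & (vip > vip_min) & (q <= fdr_limit)``."""
    index = fold_changes.index
    for other, name in ((t_table.index, "t table"), (vip.index, "VIP"),
                        (means_a.index, "means_A"), (means_b.index, "means_B")):
        if list(other) != list(index):
            raise ValueError(f"{name} computed on a different metabolite set")
    q = bh_fdr(t_table["p_value"].to_numpy())
    out = pd.DataFrame(
        {
            "mean_A": means_a,
            "mean_B": means_b,
            "fold_change_log2": fold_changes,
            "t_statistic": t_table["t_statistic"],
            "p_value": t_table["p_value"],
            "q_value": q,
            "vip": vip,
        },
        index=index,
    )
    out["selected"] = (
        (out["p_value"] < alpha) & (out["vip"] > vip_min) & (out["q_value"] <= fdr_limit)
    )
    return DifferentialResult(
        table=out,
        control_group=control_group,
        treated_group=treated_group,
        alpha=alpha,
        vip_min=vip_min,
        fdr_limit=fdr_limit,
    )


def run_differential_analysis(
    table: IntensityTable,
    control_group: str,
    treated_group: str,
    alpha: float = ALPHA,
    vip_min: float = VIP_MIN,
    fdr_limit: float = FDR_LIMIT,
    n_components: int = 2,
    normalize: bool = True,
) -> DifferentialResult:
    """The full pipeline for one contrast: normalize, test, score, select."""
    if normalize and table.internal_standard_ids:
        table = normalize_by_internal_standard(table)
    samples_a = table.samples_in_group(control_group)
    samples_b = table.samples_in_group(treated_group)
    values = table.analyte_values()
    sub = values[samples_a + samples_b]
    log_sub = np.log(sub)
    t_table = two_sample_t(log_sub[samples_a], log_sub[samples_b])
    scaled = uv_scale(sub)
    labels = np.array(["A"] * len(samples_a) + ["B"] * len(samples_b))
    vip = plsda_vip(scaled, labels, n_components=n_components)
    vip = vip.reindex(values.index, fill_value=1.0)  # dropped constant rows
    fc = fold_change(table, control_group, treated_group)
    return select_differential(
        fold_changes=fc,
        t_table=t_table,
        vip=vip,
        means_a=values[samples_a].mean(axis=1),
        means_b=values[samples_b].mean(axis=1),
        control_group=control_group,
        treated_group=treated_group,
        alpha=alpha,
        vip_min=vip_min,
        fdr_limit=fdr_limit,
    )


def hierarchical_clustering(scaled: pd.DataFrame) -> pd.DataFrame:
    """Agglomerative clustering (Ward linkage, Euclidean) of metabolite
    profiles.

    Returns the merge list as a DataFrame with columns ``left``, ``right``
    (cluster indices: 0..n−1 are leaves in row order, n+k is the cluster
    formed at merge k), ``height`` and ``size``.  Ties are resolved toward
    the lowest-index pair (scipy's deterministic ordering).
    """
    if scaled.shape[0] < 2:
        raise ValueError("clustering needs at least 2 metabolite rows")
    Z = linkage(scaled.to_numpy(), method="ward")
    return pd.DataFrame(
        {
            "left": Z[:, 0].astype(int),
            "right": Z[:, 1].astype(int),
            "height": Z[:, 2],
            "size": Z[:, 3].astype(int),
        }
    )
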