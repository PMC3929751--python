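"""Gene-selection stage for a matched two-group expression study.

Reproduces the selection cascade used on matched-biopsy microarray
data: present-call filtering, probe-to-gene merging, per-gene paired
t-tests, Benjamini-Hochberg q-values, variance-ranked top-N selection
with the selected-variance fraction, PCA of the selected genes, a
paired SAM permutation statistic as an independent verification, and
Pavlidis template matching against a chosen template gene.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

GROUPS = ("control", "wounded")
PRESENT_CALL_THRESHOLD = 6.0  # log2 proxy threshold when no call table exists


class DegenerateInputError(ValueError):
    """Raised when a statistic is undefined on its input (e.g. zero-variance
    paired differences)."""


@dataclasses.dataclass
class ExpressionMatrix:
    """Log2 expression values plus the matched two-group design.

    ``values``: rows are probes or genes, columns are sample ids.
    ``design``: indexed by sample, with columns ``group`` (control /
    wounded) and ``pair``; every pair id must appear exactly once per
    group.
    """

    values: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self):
        missing = set(self.values.columns) - set(self.design.index)
        if missing:
            raise ValueError(f"samples without design rows: {sorted(missing)}")
        self.design = self.design.loc[list(self.values.columns)]
        groups = set(self.design["group"])
        if not groups <= set(GROUPS):
            raise ValueError(f"unknown groups {groups - set(GROUPS)}; expected {GROUPS}")
        counts = self.design.groupby(["pair", "group"]).size()
        if (counts != 1).any():
            raise ValueError("matched design violated: each pair needs exactly one sample per group")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")

    @property
    def n_pairs(self) -> int:
        return self.design["pair"].nunique()

    def paired_columns(self) -> tuple[list[str], list[str], list[str]]:
        """(pair ids, control columns, wounded columns) in matched order."""
        pairs = sorted(self.design["pair"].unique())
        by = {(r.pair, r.group): s for s, r in self.design.iterrows()}
        return (
            pairs,
            [by[(p, "control")] for p in pairs],
            [by[(p, "wounded")] for p in pairs],
        )

    def paired_differences(self) -> pd.DataFrame:
        """Per-pair wounded minus control differences (rows x pairs)."""
        pairs, ctrl, wnd = self.paired_columns()
        diff = self.values[wnd].to_numpy() - self.values[ctrl].to_numpy()
        return pd.DataFrame(diff, index=self.values.index, columns=pairs)


@dataclasses.dataclass
class SelectionResult:
    q_pass: set
    top_genes: list
    p_values: pd.Series
    q_values: pd.Series
    variance: pd.Series
    variance_fraction: float
    max_p_in_top: float


# ---------------------------------------------------------------------------
# filtering and merging
# ---------------------------------------------------------------------------

def filter_present(
    matrix: ExpressionMatrix,
    calls: Optional[pd.DataFrame] = None,
    k: int = 3,
    threshold: float = PRESENT_CALL_THRESHOLD,
    annotation: Optional[dict] = None,
    rule: str = "or",
) -> ExpressionMatrix:
    """Keep probes with at least ``k`` present calls in either group.

    ``calls`` is a probe x sample table over {P, M, A}; when absent a
    proxy rule marks a cell present iff its log2 value >= ``threshold``.
    With ``rule="and"`` both groups must reach ``k``.  When an
    ``annotation`` map is given, probes mapping to no gene (None) are
    dropped as non-annotated.
    """
    if rule not in ("or", "and"):
        raise ValueError(f"rule must be 'or' or 'and', got {rule!r}")
    group_sizes = matrix.design.groupby("group").size()
    if (k > group_sizes).any():
        raise ValueError(f"k={k} exceeds a group size ({group_sizes.to_dict()})")
    if calls is None:
        present = matrix.values >= threshold
    else:
        calls = calls.loc[matrix.values.index, matrix.values.columns]
        present = calls == "P"
    keep = None
    for group in GROUPS:
        samples = matrix.design.index[matrix.design["group"] == group]
        enough = present[samples].sum(axis=1) >= k
        keep = enough if keep is None else (keep | enough if rule == "or" else keep & enough)
    if annotation is not None:
        annotated = matrix.values.index.map(lambda p: annotation.get(p) is not None)
        keep = keep & annotated
    return ExpressionMatrix(matrix.values.loc[keep], matrix.design)


def merge_probes(matrix: ExpressionMatrix, annotation: dict) -> ExpressionMatrix:
    """Average redundant probes of the same gene into one row per gene."""
    genes = matrix.values.index.map(annotation.get)
    if genes.isna().any():
        missing = matrix.values.index[genes.isna()].tolist()
        raise ValueError(f"probes without gene annotation: {missing[:5]}")
    merged = matrix.values.groupby(genes).mean()
    merged.index.name = "gene"
    return ExpressionMatrix(merged, matrix.design)


# ---------------------------------------------------------------------------
# testing
# ---------------------------------------------------------------------------

def paired_test(gene_row: pd.Series, design: pd.DataFrame) -> float:
    """Two-sided paired t-test p-value on per-pair (wounded - control)
    differences for a single gene."""
    em = ExpressionMatrix(gene_row.to_frame().T, design)
    diffs = em.paired_differences().to_numpy()[0]
    return _paired_p_from_diffs(diffs)


def _paired_p_from_diffs(diffs: np.ndarray) -> float:
    if diffs.size < 2:
        raise DegenerateInputError("need at least 2 complete pairs")
    if np.std(diffs, ddof=1) == 0.0:
        raise DegenerateInputError("zero variance of paired differences")
    t, p = stats.ttest_rel(diffs, np.zeros_like(diffs))
    return float(p)


def paired_tests(matrix: ExpressionMatrix) -> pd.Series:
    """Vectorised paired t-test over all rows; rows with zero-variance
    differences get p = NaN with a warning."""
    diffs = matrix.paired_differences().to_numpy()
    if diffs.shape[1] < 2:
        raise DegenerateInputError("need at least 2 complete pairs")
    sd = diffs.std(axis=1, ddof=1)
    degenerate = sd == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_rel(diffs.T, np.zeros_like(diffs.T))
        p = np.asarray(res.pvalue, dtype=float)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} rows have zero-variance paired differences; p set to NaN",
            stacklevel=2,
        )
        p[degenerate] = np.nan
    return pd.Series(p, index=matrix.values.index, name="p")


def bh_qvalues(p_list) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order."""
    p = np.asarray(p_list, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


# ---------------------------------------------------------------------------
# variance ranking
# ---------------------------------------------------------------------------

def gene_variance(matrix: ExpressionMatrix) -> pd.Series:
    """Per-gene unbiased variance across all samples (log2 scale)."""
    return matrix.values.var(axis=1, ddof=1)


def select_top_variance(
    matrix: ExpressionMatrix,
    q_values: pd.Series,
    q_max: float = 0.05,
    n: int = 100,
    p_values: Optional[pd.Series] = None,
) -> SelectionResult:
    """Among genes with q <= q_max, take the ``n`` with the highest
    variance across all samples (ties broken lexicographically by gene).

    If fewer than ``n`` genes pass the q cutoff, all of them are
    returned with a warning.
    """
    var = gene_variance(matrix)
    q_values = q_values.reindex(var.index)
    passing = var.index[q_values <= q_max]
    if len(passing) < n:
        warnings.warn(
            f"only {len(passing)} genes pass q <= {q_max}; returning all of them",
            stacklevel=2,
        )
    ranked = sorted(passing, key=lambda g: (-var[g], g))
    top = ranked[:n]
    if p_values is not None and len(top):
        max_p = float(p_values.reindex(top).max())
    else:
        max_p = float("nan")
    return SelectionResult(
        q_pass=set(passing),
        top_genes=list(top),
        p_values=p_values if p_values is not None else pd.Series(dtype=float),
        q_values=q_values,
        variance=var,
        variance_fraction=variance_fraction(top, matrix),
        max_p_in_top=max_p,
    )


def variance_fraction(selected, matrix: ExpressionMatrix) -> float:
    """Share of the total per-gene variance carried by ``selected``."""
    var = gene_variance(matrix)
    if len(var) == 0:
        raise ValueError("empty expression matrix")
    selected = list(selected)
    if not set(selected) <= set(var.index):
        raise ValueError("selected genes not all present in the matrix")
    total = float(var.sum())
    if total == 0.0:
        raise ValueError("total variance is zero")
    return float(var.loc[selected].sum()) / total


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca_scores(matrix: ExpressionMatrix, n_components: int = 2):
    """SVD-based PCA of the row-centred matrix.

    Samples are observations, genes are variables.  Returns
    ``(sample_scores, gene_loadings, explained_variance_ratio)`` for the
    first ``n_components`` components.  Sign convention: each
    component's gene-loading vector has a non-negative sum.
    """
    X = matrix.values.to_numpy(dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("PCA needs at least 2 genes and 2 samples")
    centred = X - X.mean(axis=1, keepdims=True)
    if np.allclose(centred, 0.0):
        raise DegenerateInputError("constant matrix: no variance to decompose")
    # columns of U are gene loadings; rows of S*Vt are sample scores
    U, S, Vt = np.linalg.svd(centred, full_matrices=False)
    k = min(n_components, S.size)
    signs = np.where(U[:, :k].sum(axis=0) >= 0, 1.0, -1.0)
    loadings = U[:, :k] * signs
    scores = (S[:k, None] * Vt[:k]).T * signs
    evr = S**2 / np.sum(S**2)
    cols = [f"PC{i + 1}" for i in range(k)]
    return (
        pd.DataFrame(scores, index=matrix.values.columns, columns=cols),
        pd.DataFrame(loadings, index=matrix.values.index, columns=cols),
        evr[:k],
    )


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

def sam_statistic(
    matrix: ExpressionMatrix, n_perm: int = 100, seed: int = 0
) -> pd.DataFrame:
    """Paired SAM: moderated d statistic with a sign-flip permutation FDR.

    d_g = mean(diff_g) / (s_g + s0) with s_g = sd(diff_g)/sqrt(n_pairs)
    and the fudge factor s0 taken as the median of s_g over genes (a
    deterministic simplification of the percentile search).  The null
    distribution of d comes from random sign flips of the per-pair
    differences; q_sam at each gene is the permutation-estimated FDR at
    the threshold |d_g|, made monotone in |d|.
    """
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10")
    diffs = matrix.paired_differences().to_numpy()
    n_pairs = diffs.shape[1]
    if n_pairs < 2:
        raise DegenerateInputError("SAM needs at least 2 pairs")

    def d_stat(dd: np.ndarray) -> np.ndarray:
        s = dd.std(axis=1, ddof=1) / np.sqrt(n_pairs)
        s0 = np.median(s)
        return dd.mean(axis=1) / (s + s0)

    d = d_stat(diffs)
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_pairs))
    null_abs = np.empty((n_perm, diffs.shape[0]))
    for i in range(n_perm):
        null_abs[i] = np.abs(d_stat(diffs * signs[i]))

    abs_d = np.abs(d)
    order = np.argsort(-abs_d, kind="stable")
    # expected false calls and observed calls at threshold |d_(i)|
    thresholds = abs_d[order]
    called = np.arange(1, abs_d.size + 1)
    expected = np.array(
        [np.mean(np.sum(null_abs >= t, axis=1)) for t in thresholds]
    )
    q_sorted = np.minimum(expected / called, 1.0)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]  # monotone in |d|
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return pd.DataFrame({"d": d, "q_sam": q}, index=matrix.values.index)


# ---------------------------------------------------------------------------
# template matching and dendrogram export
# ---------------------------------------------------------------------------

def template_match(
    matrix: ExpressionMatrix, template_gene: str, r_min: float = 0.9
) -> dict[str, list]:
    """Pavlidis template matching: genes whose profile correlates with
    the template gene's profile at |r| >= r_min, split by sign."""
    if template_gene not in matrix.values.index:
        raise KeyError(f"template gene {template_gene!r} not in matrix")
    X = matrix.values.to_numpy(dtype=float)
    template = matrix.values.loc[template_gene].to_numpy(dtype=float)
    if np.std(template) == 0.0:
        raise DegenerateInputError("template profile has zero variance")
    sd = X.std(axis=1)
    flat = sd == 0.0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance profiles skipped in template matching",
            stacklevel=2,
        )
    tc = template - template.mean()
    xc = X - X.mean(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ tc) / (np.linalg.norm(xc, axis=1) * np.linalg.norm(tc))
    genes = matrix.values.index
    positive = [g for g, ri, fl in zip(genes, r, flat) if not fl and ri >= r_min]
    negative = [g for g, ri, fl in zip(genes, r, flat) if not fl and ri <= -r_min]
    return {"positive": positive, "negative": negative}


def dendrogram_newick(matrix: ExpressionMatrix) -> str:
    """Average-linkage, correlation-distance dendrogram of the genes,
    exported as a Newick string (heat-map companion output)."""
    X = matrix.values.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 genes to cluster")
    corr = np.corrcoef(X)
    dist = squareform(np.clip(1.0 - corr, 0.0, 2.0), checks=False)
    Z = hierarchy.linkage(dist, method="average")
    tree = hierarchy.to_tree(Z)
    labels = list(matrix.values.index)

    def _newick(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left, right = node.get_left(), node.get_right()
        return (
            f"({_newick(left)}:{node.dist - left.dist:.6f},"
            f"{_newick(right)}:{node.dist - right.dist:.6f})"
        )

    return _newick(tree) + ";"
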