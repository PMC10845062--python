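"""Mass-univariate edge-wise OLS and ROI-row-wise Benjamini-Hochberg FDR.

The longitudinal model regresses the follow-up symptom score on each edge's
connectivity change, adjusting for the same edge's baseline connectivity and
sex::

    symptoms_tp2 ~ delta_edge + rsfc_tp1_edge + sex + intercept

All edges are fitted in one vectorized pass over stacked normal equations;
tests assert bitwise-level agreement with a per-edge solve.

Multiple-comparison correction is applied independently to each ROI's row of
the edge matrix, so every edge (a, b) carries two adjusted p-values — one in
ROI a's row and one in ROI b's row. Per-ROI counts and downstream summaries
always use the row of the ROI under report.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .cohort import CohortDataset
from .connectome import edge_index
from .parcellation import ParcellationScheme

ZERO_VARIANCE_TOL = 1e-12
CONDITION_LIMIT = 1e12


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EdgeModelSpec:
    """Declarative description of one mass-univariate edge model.

    ``standardize`` z-scores the outcome and all continuous regressors
    (edge terms); the binary sex code is never standardized, so its
    coefficient is reported per the documented 0/1 coding.
    """

    outcome: str = "symptoms_tp2"
    edge_regressor: str = "delta"
    covariates: tuple[str, ...] = ("rsfc_tp1_same_edge", "sex")
    standardize: bool = True

    _SAME_EDGE = {
        "rsfc_tp1_same_edge": "rsfc_tp1",
        "rsfc_tp2_same_edge": "rsfc_tp2",
    }

    @property
    def term_names(self) -> list[str]:
        return [self.edge_regressor, *self.covariates, "intercept"]


def delta_model_spec(standardize: bool = True) -> EdgeModelSpec:
    """The primary longitudinal model (delta + same-edge baseline + sex)."""
    return EdgeModelSpec(standardize=standardize)


def cross_sectional_spec(time_point: str, standardize: bool = True) -> EdgeModelSpec:
    """Concurrent-symptom model at one time point (rsfc + sex)."""
    tp = time_point.lower()
    if tp not in ("tp1", "tp2"):
        raise ValueError("time_point must be 'TP1' or 'TP2'")
    return EdgeModelSpec(
        outcome=f"symptoms_{tp}",
        edge_regressor=f"rsfc_{tp}",
        covariates=("sex",),
        standardize=standardize,
    )


# ---------------------------------------------------------------------------
# result container
# ---------------------------------------------------------------------------

@dataclass
class EdgeResultTable:
    """Per-edge, per-term OLS statistics plus row-wise adjusted p-values."""

    scheme: ParcellationScheme
    terms: list[str]
    beta: np.ndarray  # E x k
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    df_resid: int
    degenerate: np.ndarray  # E bools
    spec: EdgeModelSpec | None = None
    # filled by rowwise_bh:
    q: float | None = None
    tested_term: str | None = None
    p_adj_a: np.ndarray | None = None  # row of edge's first (smaller-id) ROI
    p_adj_b: np.ndarray | None = None
    sig_a: np.ndarray | None = None
    sig_b: np.ndarray | None = None
    edge_idx: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.edge_idx = edge_index(self.scheme.n_rois)
        e, k = len(self.edge_idx), len(self.terms)
        for name in ("beta", "se", "t", "p"):
            if getattr(self, name).shape != (e, k):
                raise ValueError(f"{name} must have shape {(e, k)}")

    @property
    def n_edges(self) -> int:
        return len(self.edge_idx)

    def term_column(self, term: str) -> int:
        try:
            return self.terms.index(term)
        except ValueError:
            raise KeyError(f"unknown model term: {term!r}") from None

    @property
    def focus_term(self) -> str:
        return self.terms[0]

    def row_edges(self, roi: int) -> np.ndarray:
        """Indices of edges incident to `roi` (its row of the edge matrix)."""
        if not 0 <= roi < self.scheme.n_rois:
            raise KeyError(f"roi {roi} not in parcellation")
        return np.flatnonzero((self.edge_idx[:, 0] == roi) | (self.edge_idx[:, 1] == roi))

    def row_padj(self, roi: int) -> np.ndarray:
        """Adjusted p-values of `roi`'s row, aligned with :meth:`row_edges`."""
        self._require_bh()
        edges = self.row_edges(roi)
        is_a = self.edge_idx[edges, 0] == roi
        return np.where(is_a, self.p_adj_a[edges], self.p_adj_b[edges])

    def row_flags(self, roi: int) -> np.ndarray:
        self._require_bh()
        edges = self.row_edges(roi)
        is_a = self.edge_idx[edges, 0] == roi
        return np.where(is_a, self.sig_a[edges], self.sig_b[edges])

    def _require_bh(self) -> None:
        if self.p_adj_a is None:
            raise ValueError("row-wise BH has not been applied; call rowwise_bh first")

    def to_long_frame(self):
        """Long-format export: one row per edge, ROI row and term."""
        import pandas as pd

        names = self.scheme.roi_names
        rows = []
        has_bh = self.p_adj_a is not None
        for e, (a, b) in enumerate(self.edge_idx):
            edge_id = f"{names[a]}__{names[b]}"
            for side, roi in (("a", a), ("b", b)):
                padj = getattr(self, f"p_adj_{side}")[e] if has_bh else np.nan
                sig = bool(getattr(self, f"sig_{side}")[e]) if has_bh else False
                for j, term in enumerate(self.terms):
                    rows.append(
                        {
                            "edge_id": edge_id,
                            "roi_row": names[roi],
                            "term": term,
                            "beta": self.beta[e, j],
                            "se": self.se[e, j],
                            "t": self.t[e, j],
                            "p": self.p[e, j],
                            "p_adj": padj if term == self.tested_term else np.nan,
                            "significant": sig if term == self.tested_term else False,
                            "degenerate": bool(self.degenerate[e]),
                        }
                    )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# vectorized OLS core
# ---------------------------------------------------------------------------

def _zscore(x: np.ndarray, axis: int = 0) -> np.ndarray:
    sd = x.std(axis=axis, ddof=1, keepdims=True)
    sd = np.where(sd < ZERO_VARIANCE_TOL, 1.0, sd)
    return (x - x.mean(axis=axis, keepdims=True)) / sd


def _stack_normal_equations(y, columns, n_edges):
    """XtX (E,k,k), Xty (E,k), yty (E,) from shared/per-edge design columns.

    Each column is an (n,) shared vector or an (n, E) per-edge matrix; ``y``
    may be shared or per-edge. This avoids materializing the E dense design
    matrices while remaining algebraically identical to a per-edge solve.
    """
    k = len(columns)
    e_ones = np.ones(n_edges)

    def cross(u, v):
        if u.ndim == 1 and v.ndim == 1:
            return float(u @ v) * e_ones
        if u.ndim == 1:
            return u @ v
        if v.ndim == 1:
            return v @ u
        return np.einsum("ne,ne->e", u, v)

    xtx = np.empty((n_edges, k, k))
    for i in range(k):
        for j in range(i, k):
            xtx[:, i, j] = xtx[:, j, i] = cross(columns[i], columns[j])
    xty = np.empty((n_edges, k))
    for i in range(k):
        xty[:, i] = cross(columns[i], y)
    yty = cross(y, y)
    return xtx, xty, yty


def _batch_solve(xtx, xty, yty, n, degenerate):
    """Solve stacked normal equations; NaN statistics for degenerate edges."""
    n_edges, k = xty.shape
    df = n - k
    if df <= 0:
        raise ValueError(f"not enough subjects: n={n} for {k} parameters")

    with np.errstate(all="ignore"):
        cond = np.linalg.cond(xtx)
    degenerate = degenerate | ~np.isfinite(cond) | (cond > CONDITION_LIMIT)
    valid = ~degenerate

    beta = np.full((n_edges, k), np.nan)
    se = np.full((n_edges, k), np.nan)
    if valid.any():
        sol = np.linalg.solve(xtx[valid], xty[valid][..., None])[..., 0]
        beta[valid] = sol
        ssr = yty[valid] - np.einsum("ek,ek->e", sol, xty[valid])
        sigma2 = np.maximum(ssr, 0.0) / df
        xtx_inv = np.linalg.inv(xtx[valid])
        diag = np.einsum("ekk->ek", xtx_inv)
        se[valid] = np.sqrt(np.maximum(sigma2[:, None] * diag, 0.0))
    with np.errstate(all="ignore"):
        t = beta / se
    p = np.full_like(t, np.nan)
    finite = np.isfinite(t)
    p[finite] = 2.0 * stats.t.sf(np.abs(t[finite]), df)
    return beta, se, t, p, df, degenerate


def fit_edge_models(
    dataset: CohortDataset,
    spec: EdgeModelSpec | None = None,
    extra_covariates: dict[str, np.ndarray] | None = None,
) -> EdgeResultTable:
    """Fit the edge model at every edge of the cohort in one vectorized pass.

    Degenerate edges (zero-variance or collinear design) get NaN statistics
    and a ``degenerate`` flag; they are never silently dropped and are
    excluded from each BH row's test count.
    """
    spec = spec or EdgeModelSpec()
    y = dataset.edge_values(spec.outcome) if spec.outcome in (
        "delta", "rsfc_tp1", "rsfc_tp2") else getattr(dataset, spec.outcome)
    if y is None:
        raise ValueError(f"cohort has no outcome '{spec.outcome}'")
    y = np.asarray(y, dtype=float)
    n, n_edges = dataset.n_subjects, dataset.n_edges

    degenerate = np.zeros(n_edges, dtype=bool)

    def edge_column(which: str) -> np.ndarray:
        m = dataset.edge_values(which)
        flat = m.std(axis=0, ddof=1) < ZERO_VARIANCE_TOL
        nonlocal degenerate
        degenerate = degenerate | flat
        return _zscore(m) if spec.standardize else m

    columns: list[np.ndarray] = [edge_column(spec.edge_regressor)]
    for cov in spec.covariates:
        if cov in EdgeModelSpec._SAME_EDGE:
            columns.append(edge_column(EdgeModelSpec._SAME_EDGE[cov]))
        elif cov == "sex":
            columns.append(dataset.sex.astype(float))
        elif extra_covariates and cov in extra_covariates:
            v = np.asarray(extra_covariates[cov], dtype=float)
            columns.append(_zscore(v) if spec.standardize else v)
        else:
            raise ValueError(f"unknown covariate: {cov!r}")
    columns.append(np.ones(n))

    if spec.standardize:
        y = _zscore(y)

    xtx, xty, yty = _stack_normal_equations(y, columns, n_edges)
    beta, se, t, p, df, degenerate = _batch_solve(xtx, xty, yty, n, degenerate)
    return EdgeResultTable(
        scheme=dataset.scheme,
        terms=spec.term_names,
        beta=beta,
        se=se,
        t=t,
        p=p,
        df_resid=df,
        degenerate=degenerate,
        spec=spec,
    )


def fit_cross_sectional(
    dataset: CohortDataset, time_point: str, standardize: bool = True
) -> EdgeResultTable:
    """Edge-wise concurrent model: symptoms(tp) ~ rsfc(tp) + sex + intercept."""
    return fit_edge_models(dataset, cross_sectional_spec(time_point, standardize))


# ---------------------------------------------------------------------------
# Benjamini-Hochberg, row-wise
# ---------------------------------------------------------------------------

def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up, monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def rowwise_bh(
    results: EdgeResultTable, q: float = 0.05, term: str | None = None
) -> EdgeResultTable:
    """Apply BH independently to each ROI's row of the edge matrix.

    Edge (a, b) receives two adjusted p-values — one from a's row (over a's
    P-1 incident edges) and one from b's row. The row test count m excludes
    degenerate edges. Flags use p_adj <= q.
    """
    if not 0.0 < q < 1.0:
        raise ValueError(f"q must be in (0, 1), got {q}")
    term = term or results.focus_term
    col = results.term_column(term)
    raw = results.p[:, col]

    e = results.n_edges
    p_adj_a = np.full(e, np.nan)
    p_adj_b = np.full(e, np.nan)
    valid = ~results.degenerate & np.isfinite(raw)
    for roi in range(results.scheme.n_rois):
        edges = results.row_edges(roi)
        row_valid = edges[valid[edges]]
        if row_valid.size == 0:
            continue
        adj = bh_adjust(raw[row_valid])
        is_a = results.edge_idx[row_valid, 0] == roi
        p_adj_a[row_valid[is_a]] = adj[is_a]
        p_adj_b[row_valid[~is_a]] = adj[~is_a]

    out = replace(results)
    out.q = q
    out.tested_term = term
    out.p_adj_a = p_adj_a
    out.p_adj_b = p_adj_b
    with np.errstate(invalid="ignore"):
        out.sig_a = p_adj_a <= q
        out.sig_b = p_adj_b <= q
    return out


def count_significant(
    results: EdgeResultTable, roi: int, sign: str = "both", term: str | None = None
) -> int:
    """Number of flagged edges in `roi`'s row, optionally filtered by sign."""
    if sign not in ("positive", "negative", "both"):
        raise ValueError(f"sign must be positive/negative/both, got {sign!r}")
    term = term or results.tested_term or results.focus_term
    col = results.term_column(term)
    edges = results.row_edges(roi)
    flags = results.row_flags(roi)
    betas = results.beta[edges, col]
    if sign == "positive":
        flags = flags & (betas > 0)
    elif sign == "negative":
        flags = flags & (betas < 0)
    return int(flags.sum())
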