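"""Two-group contrasts (e.g. patients vs controls) with sex control.

Each edge (or the cortical-integration scalar) is modeled with a
main-effects design ``value ~ group + sex`` and the group factor is tested
with an F statistic. With a two-level factor and Type-II sums of squares the
group F equals the squared t of the dummy-coded OLS coefficient, which is
how it is computed here (asserted against an explicit ANOVA in tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortDataset
from .connectome import edge_index
from .cwas import ZERO_VARIANCE_TOL, bh_adjust
from .integration import IntegrationProfile
from .parcellation import ParcellationScheme

PATIENT_LABEL = "patient"


def _group_dummy(group: np.ndarray, patient_label: str = PATIENT_LABEL) -> np.ndarray:
    levels = sorted(set(map(str, group)))
    if len(levels) != 2:
        raise ValueError(f"need exactly two non-empty groups, got {levels}")
    if patient_label in levels:
        positive = patient_label
    else:  # fall back to second level alphabetically, documented in output
        positive = levels[1]
    dummy = (np.asarray(group, dtype=str) == positive).astype(float)
    if dummy.sum() in (0, len(dummy)):
        raise ValueError("one group is empty")
    return dummy


@dataclass
class GroupContrastResult:
    """Per-edge (or single-row) group-factor F tests with row-wise BH."""

    scheme: ParcellationScheme
    f: np.ndarray
    p: np.ndarray
    direction: np.ndarray  # sign of patient-minus-control adjusted mean
    df_num: int
    df_den: int
    degenerate: np.ndarray
    label: str = "edge"
    q: float | None = None
    p_adj_a: np.ndarray | None = None
    p_adj_b: np.ndarray | None = None
    sig_a: np.ndarray | None = None
    sig_b: np.ndarray | None = None
    edge_idx: np.ndarray | None = field(default=None)

    def row_edges(self, roi: int) -> np.ndarray:
        if not 0 <= roi < self.scheme.n_rois:
            raise KeyError(f"roi {roi} not in parcellation")
        return np.flatnonzero(
            (self.edge_idx[:, 0] == roi) | (self.edge_idx[:, 1] == roi)
        )

    def row_flags(self, roi: int) -> np.ndarray:
        if self.sig_a is None:
            raise ValueError("row-wise BH has not been applied")
        edges = self.row_edges(roi)
        is_a = self.edge_idx[edges, 0] == roi
        return np.where(is_a, self.sig_a[edges], self.sig_b[edges])

    def count_significant(self, roi: int) -> int:
        return int(self.row_flags(roi).sum())

    def to_frame(self) -> pd.DataFrame:
        names = self.scheme.roi_names
        if self.edge_idx is None:
            return pd.DataFrame(
                {
                    "unit": [self.label],
                    "F": self.f,
                    "p": self.p,
                    "direction": self.direction,
                }
            )
        df = pd.DataFrame(
            {
                "edge_id": [f"{names[a]}__{names[b]}" for a, b in self.edge_idx],
                "F": self.f,
                "p": self.p,
                "direction": self.direction,
                "degenerate": self.degenerate,
            }
        )
        if self.p_adj_a is not None:
            df["p_adj_a"] = self.p_adj_a
            df["p_adj_b"] = self.p_adj_b
            df["sig_a"] = self.sig_a
            df["sig_b"] = self.sig_b
        return df


def _shared_design_ftest(values: np.ndarray, dummy: np.ndarray, sex: np.ndarray):
    """F for the group dummy in value ~ group + sex, vectorized over columns.

    Computed as the squared t of the dummy coefficient in the dummy-coded
    OLS, which for a single-df factor in a main-effects model equals the
    Type-II ANOVA F.
    """
    n, m = values.shape
    x = np.column_stack([dummy, sex, np.ones(n)])
    k = x.shape[1]
    df_den = n - k
    if df_den <= 0:
        raise ValueError(f"not enough subjects: n={n} for {k} parameters")
    xtx = x.T @ x
    if np.linalg.cond(xtx) > 1e12:
        raise ValueError("design matrix is rank-deficient (group confounded with sex?)")
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ (x.T @ values)  # k x m
    resid = values - x @ beta
    ssr = np.einsum("nm,nm->m", resid, resid)
    degenerate = values.std(axis=0, ddof=1) < ZERO_VARIANCE_TOL
    sigma2 = ssr / df_den
    with np.errstate(all="ignore"):
        se = np.sqrt(sigma2 * xtx_inv[0, 0])
        t = beta[0] / se
    f = t**2
    p = stats.f.sf(f, 1, df_den)
    f[degenerate] = np.nan
    p[degenerate] = np.nan
    return f, p, np.sign(beta[0]), 1, df_den, degenerate


def fit_group_edge_anova(
    dataset: CohortDataset,
    scheme: ParcellationScheme | None = None,
    which: str = "rsfc_tp1",
    q: float | None = 0.05,
) -> GroupContrastResult:
    """Per-edge group contrast on a single-session cohort with row-wise BH."""
    scheme = scheme or dataset.scheme
    if dataset.group is None:
        raise ValueError("cohort has no group labels")
    if dataset.is_longitudinal and which == "rsfc_tp1":
        pass  # contrasting baselines of a longitudinal cohort is allowed
    values = dataset.edge_values(which)
    dummy = _group_dummy(dataset.group)
    f, p, direction, df_num, df_den, degenerate = _shared_design_ftest(
        values, dummy, dataset.sex.astype(float)
    )
    result = GroupContrastResult(
        scheme=scheme,
        f=f,
        p=p,
        direction=direction,
        df_num=df_num,
        df_den=df_den,
        degenerate=degenerate,
        edge_idx=edge_index(scheme.n_rois),
    )
    if q is not None:
        result = rowwise_bh_group(result, q)
    return result


def rowwise_bh_group(result: GroupContrastResult, q: float = 0.05) -> GroupContrastResult:
    """ROI-row-wise BH over the group-factor p-values."""
    if not 0.0 < q < 1.0:
        raise ValueError(f"q must be in (0, 1), got {q}")
    e = len(result.p)
    p_adj_a = np.full(e, np.nan)
    p_adj_b = np.full(e, np.nan)
    valid = ~result.degenerate & np.isfinite(result.p)
    for roi in range(result.scheme.n_rois):
        edges = result.row_edges(roi)
        row_valid = edges[valid[edges]]
        if row_valid.size == 0:
            continue
        adj = bh_adjust(result.p[row_valid])
        is_a = result.edge_idx[row_valid, 0] == roi
        p_adj_a[row_valid[is_a]] = adj[is_a]
        p_adj_b[row_valid[~is_a]] = adj[~is_a]
    result.q = q
    result.p_adj_a = p_adj_a
    result.p_adj_b = p_adj_b
    with np.errstate(invalid="ignore"):
        result.sig_a = p_adj_a <= q
        result.sig_b = p_adj_b <= q
    return result


def integration_group_anova(
    dataset: CohortDataset, target_rois, profile: IntegrationProfile | None = None
) -> GroupContrastResult:
    """Group contrast on the cortical-integration level of a target ROI set."""
    from .integration import cortical_integration

    if dataset.group is None:
        raise ValueError("cohort has no group labels")
    if profile is None:
        profile = cortical_integration(dataset, target_rois)
    values = profile.mean_tp1[:, None]
    dummy = _group_dummy(dataset.group)
    f, p, direction, df_num, df_den, degenerate = _shared_design_ftest(
        values, dummy, dataset.sex.astype(float)
    )
    return GroupContrastResult(
        scheme=dataset.scheme,
        f=f,
        p=p,
        direction=direction,
        df_num=df_num,
        df_den=df_den,
        degenerate=degenerate,
        label=f"integration[{','.join(map(str, np.atleast_1d(target_rois)))}]",
    )
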