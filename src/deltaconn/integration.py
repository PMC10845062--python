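"""Cortical integration of subcortical ROI sets and related models.

"Cortical integration" of a subcortical ROI set is the mean connectivity
(level or change) of its edges to all cortical ROIs. The module provides the
per-subject statistic, the OLS of symptoms on integration change with
baseline and sex covariates, the integration ratio with a behavioral
correlation, and the percentile-sweep ROC of the integration score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortDataset
from .connectome import edge_index
from .cwas import _stack_normal_equations, _zscore
from .parcellation import ParcellationScheme


@dataclass(frozen=True)
class IntegrationProfile:
    """Per-subject mean connectivity of a target ROI set to all cortex."""

    subject_ids: list[str]
    target_rois: tuple[int, ...]
    mean_tp1: np.ndarray
    mean_delta: np.ndarray | None  # None for single-session cohorts
    n_block_edges: int

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)


@dataclass(frozen=True)
class ModelReport:
    """Full coefficient table plus model-level fit statistics."""

    terms: list[str]
    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    r_squared: float
    f_stat: float
    f_p: float
    df_model: int
    df_resid: int
    n: int
    warnings: tuple[str, ...] = ()

    def coefficient_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "beta": self.beta,
                "se": self.se,
                "t": self.t,
                "p": self.p,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )

    def to_dict(self) -> dict:
        out = self.coefficient_frame().to_dict(orient="records")
        return {
            "coefficients": out,
            "r_squared": self.r_squared,
            "f_stat": self.f_stat,
            "f_p": self.f_p,
            "df_model": self.df_model,
            "df_resid": self.df_resid,
            "n": self.n,
            "warnings": list(self.warnings),
        }


def _target_block(scheme: ParcellationScheme, target_rois) -> np.ndarray:
    """Edge-universe indices of all target-to-cortical edges."""
    targets = np.atleast_1d(np.asarray(target_rois, dtype=int))
    if targets.size == 0:
        raise ValueError("target ROI set is empty")
    classes = scheme.table["roi_class"].to_numpy()
    if np.any(classes[targets] != "subcortical"):
        bad = [scheme.roi_names[i] for i in targets if classes[i] != "subcortical"]
        raise ValueError(f"target ROIs must be subcortical, got cortical: {bad}")
    cortical = set(scheme.cortical_ids.tolist())
    if not cortical:
        raise ValueError("parcellation has no cortical ROIs")
    tset = set(targets.tolist())
    idx = edge_index(scheme.n_rois)
    mask = np.array(
        [
            (a in tset and b in cortical) or (b in tset and a in cortical)
            for a, b in idx
        ]
    )
    block = np.flatnonzero(mask)
    assert block.size == len(tset) * len(cortical)
    return block


def cortical_integration(
    dataset: CohortDataset, target_rois, scheme: ParcellationScheme | None = None
) -> IntegrationProfile:
    """Per-subject mean TP1 and mean delta over the target-to-cortical block."""
    scheme = scheme or dataset.scheme
    block = _target_block(scheme, target_rois)
    mean_tp1 = dataset.rsfc_tp1[:, block].mean(axis=1)
    mean_delta = (
        dataset.delta[:, block].mean(axis=1) if dataset.delta is not None else None
    )
    return IntegrationProfile(
        subject_ids=list(dataset.subject_ids),
        target_rois=tuple(np.atleast_1d(target_rois).tolist()),
        mean_tp1=mean_tp1,
        mean_delta=mean_delta,
        n_block_edges=block.size,
    )


def _ols_report(y: np.ndarray, columns: list[np.ndarray], terms: list[str],
                warnings: tuple[str, ...] = ()) -> ModelReport:
    n, k = len(y), len(columns)
    x = np.column_stack(columns)
    xtx, xty, yty = _stack_normal_equations(y, [c for c in x.T], 1)
    cond = np.linalg.cond(xtx[0])
    if cond > 1e8:
        warnings = warnings + (f"ill-conditioned design (cond={cond:.3g})",)
    beta = np.linalg.solve(xtx[0], xty[0])
    df_resid = n - k
    resid = y - x @ beta
    ssr = float(resid @ resid)
    sigma2 = ssr / df_resid
    se = np.sqrt(sigma2 * np.diag(np.linalg.inv(xtx[0])))
    t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df_resid)
    tcrit = stats.t.ppf(0.975, df_resid)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ssr / sst if sst > 0 else np.nan
    df_model = k - 1  # non-intercept terms
    f_stat = (r2 / df_model) / ((1.0 - r2) / df_resid) if df_model > 0 else np.nan
    f_p = stats.f.sf(f_stat, df_model, df_resid) if df_model > 0 else np.nan
    return ModelReport(
        terms=terms,
        beta=beta,
        se=se,
        t=t,
        p=p,
        ci_low=beta - tcrit * se,
        ci_high=beta + tcrit * se,
        r_squared=r2,
        f_stat=float(f_stat),
        f_p=float(f_p),
        df_model=df_model,
        df_resid=df_resid,
        n=n,
        warnings=warnings,
    )


def fit_integration_model(
    profile: IntegrationProfile,
    dataset: CohortDataset,
    standardize: bool = True,
) -> ModelReport:
    """OLS: symptoms_tp2 ~ mean_delta + mean_tp1 + sex + intercept.

    Continuous variables are z-scored when ``standardize`` (the default,
    matching the standardized coefficient scale of the reference analysis);
    sex stays on its 0/1 coding.
    """
    if profile.mean_delta is None:
        raise ValueError("profile has no delta component (single-session cohort?)")
    if profile.subject_ids != list(dataset.subject_ids):
        raise ValueError("profile and dataset subjects are not aligned")
    y = np.asarray(dataset.symptoms_tp2, dtype=float)
    md, mt = profile.mean_delta, profile.mean_tp1
    if standardize:
        y, md, mt = (_zscore(v) for v in (y, md, mt))
    columns = [md, mt, dataset.sex.astype(float), np.ones(len(y))]
    terms = ["mean_delta", "mean_tp1", "sex", "intercept"]
    return _ols_report(y, columns, terms)


def integration_ratio(
    dataset: CohortDataset,
    numerator_rois,
    denominator_rois,
    behavior: np.ndarray,
    method: str = "pearson",
    eps: float = 1e-12,
):
    """Ratio of two cortical-integration levels, correlated with behavior.

    Uses connectivity *levels* (mean TP1/single-session rsFC), not change.
    Subjects whose denominator integration is ~0 are flagged and excluded
    from the correlation; df = n_valid - 2.
    """
    num = cortical_integration(dataset, numerator_rois).mean_tp1
    den = cortical_integration(dataset, denominator_rois).mean_tp1
    behavior = np.asarray(behavior, dtype=float)
    if len(behavior) != dataset.n_subjects:
        raise ValueError("behavior length does not match cohort")
    valid = np.abs(den) > eps
    if not valid.any():
        raise ValueError("denominator integration is ~0 for every subject")
    ratio = np.full(dataset.n_subjects, np.nan)
    ratio[valid] = num[valid] / den[valid]
    if method == "pearson":
        r, p = stats.pearsonr(ratio[valid], behavior[valid])
    elif method == "spearman":
        r, p = stats.spearmanr(ratio[valid], behavior[valid])
    else:
        raise ValueError(f"unknown correlation method: {method!r}")
    df = int(valid.sum()) - 2
    return ratio, float(r), float(p), df


# ---------------------------------------------------------------------------
# ROC percentile sweep
# ---------------------------------------------------------------------------

def rank_auc(score: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC of `score` for binary `labels` (ties mid-ranked)."""
    score = np.asarray(score, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be non-empty")
    ranks = stats.rankdata(score)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_percentile_sweep(
    score: np.ndarray,
    outcome: np.ndarray,
    percentiles=tuple(range(50, 100, 5)),
) -> pd.DataFrame:
    """AUC of `score` against outcome dichotomized at each percentile.

    Positives are subjects with outcome strictly above the percentile
    threshold. A percentile that leaves an empty class yields a NaN row and
    the sweep continues.
    """
    score = np.asarray(score, dtype=float)
    outcome = np.asarray(outcome, dtype=float)
    if len(score) != len(outcome):
        raise ValueError("score and outcome must be aligned")
    rows = []
    for c in percentiles:
        thr = float(np.percentile(outcome, c))
        pos = outcome > thr
        n_pos, n_neg = int(pos.sum()), int((~pos).sum())
        auc = rank_auc(score, pos) if n_pos and n_neg else np.nan
        rows.append(
            {"percentile": c, "threshold": thr, "n_pos": n_pos, "n_neg": n_neg, "auc": auc}
        )
    return pd.DataFrame(rows)
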