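"""Synthetic longitudinal and two-group connectome cohorts with known truth.

The generative model mirrors the statistical structure the edge-wise
regression assumes: per-subject baseline connectomes around a population
mean, connectivity changes that are pure noise except at a sparse planted
edge set, and a follow-up symptom score built from the planted standardized
effects plus a sex shift and residual noise. With the default auto-scaled
symptom noise, the outcome has unit variance, so a planted effect b is
recovered as a standardized regression coefficient of b.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .cohort import CohortDataset
from .connectome import build_connectome, devectorize_edges, edge_index
from .parcellation import ParcellationScheme, make_parcellation

GENERATOR_VERSION = "deltaconn-sim-1"
CLIP_LIMIT = 0.999
MAX_CLIP_RATE = 0.01

CORTICAL_NETWORKS = (
    "control",
    "default_mode",
    "dorsal_attention",
    "limbic",
    "salience",
    "somatomotor",
)
SUBCORTICAL_NAMES = (
    "subthalamic_nucleus_RH",
    "red_nucleus_LH",
    "thalamus_middle",
    "thalamus_inferior",
    "caudate_inferior",
    "hippocampus_anterior",
)


def default_scheme(
    n_cortical: int = 48, n_subcortical: int = 6, networks=CORTICAL_NETWORKS
) -> ParcellationScheme:
    """Desk-scale stand-in parcellation: cortical networks + basal ganglia."""
    import pandas as pd

    rows = []
    per_net = int(np.ceil(n_cortical / len(networks)))
    for i in range(n_cortical):
        net = networks[i // per_net] if i // per_net < len(networks) else networks[-1]
        rows.append(
            {
                "roi_name": f"{net}_{i % per_net:02d}_{'LR'[i % 2]}",
                "hemisphere": "LR"[i % 2],
                "roi_class": "cortical",
                "network": net,
            }
        )
    for j in range(n_subcortical):
        name = (
            SUBCORTICAL_NAMES[j]
            if j < len(SUBCORTICAL_NAMES)
            else f"basal_ganglia_{j:02d}"
        )
        rows.append(
            {
                "roi_name": name,
                "hemisphere": "bilateral",
                "roi_class": "subcortical",
                "network": "basal_ganglia",
            }
        )
    return make_parcellation(pd.DataFrame(rows))


def edge_id(n_rois: int, a: int, b: int) -> int:
    """Index of edge (a, b), a < b, in the row-major upper-triangle order."""
    if not 0 <= a < b < n_rois:
        raise ValueError(f"invalid edge ({a}, {b}) for P={n_rois}")
    return a * (2 * n_rois - a - 1) // 2 + (b - a - 1)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic cohort generator. ``seed`` is mandatory."""

    seed: int
    n_subjects: int = 200
    n_cortical: int = 48
    n_subcortical: int = 6
    planted_edges: tuple[tuple[int, int, float], ...] = ()  # (roi_a, roi_b, effect)
    sex_effect: float = -0.24
    baseline_sd: float = 0.1
    delta_sd: float = 0.1
    symptom_noise_sd: float | None = None  # None -> auto (unit-variance outcome)
    plant_target: str = "delta"  # "delta" | "tp1"
    mode: str = "connectome"  # "connectome" | "timeseries"
    T: int = 500
    scheme: ParcellationScheme | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.baseline_sd <= 0 or self.delta_sd <= 0:
            raise ValueError("all noise sds must be > 0")
        if self.plant_target not in ("delta", "tp1"):
            raise ValueError("plant_target must be 'delta' or 'tp1'")
        if self.mode not in ("connectome", "timeseries"):
            raise ValueError("mode must be 'connectome' or 'timeseries'")

    def resolved_scheme(self) -> ParcellationScheme:
        return self.scheme or default_scheme(self.n_cortical, self.n_subcortical)


@dataclass(frozen=True)
class TruthRecord:
    """Planted structure of a simulated cohort, sufficient for power math."""

    planted: tuple[tuple[int, int, int, float], ...]  # (edge_id, roi_a, roi_b, effect)
    sex_effect: float
    symptom_noise_sd: float
    baseline_sd: float
    delta_sd: float
    plant_target: str
    seed: int
    generator_version: str = GENERATOR_VERSION
    clip_rate: float = 0.0
    group_shifts: tuple[tuple[int, int, int, float], ...] = ()

    @property
    def planted_edge_ids(self) -> list[int]:
        return [e for e, _, _, _ in self.planted]

    def to_json(self, path) -> None:
        from pathlib import Path

        payload = {
            "planted": [list(t) for t in self.planted],
            "sex_effect": self.sex_effect,
            "symptom_noise_sd": self.symptom_noise_sd,
            "baseline_sd": self.baseline_sd,
            "delta_sd": self.delta_sd,
            "plant_target": self.plant_target,
            "seed": self.seed,
            "generator_version": self.generator_version,
            "clip_rate": self.clip_rate,
            "group_shifts": [list(t) for t in self.group_shifts],
        }
        Path(path).write_text(json.dumps(payload, indent=2))


# ---------------------------------------------------------------------------
# population structure
# ---------------------------------------------------------------------------

def population_connectome(scheme: ParcellationScheme) -> np.ndarray:
    """Deterministic block-structured population correlation matrix.

    Within-network cortical edges 0.3, between-network cortical 0.1,
    subcortico-cortical 0.05, subcortico-subcortical 0.15; projected to the
    nearest valid correlation matrix.
    """
    p = scheme.n_rois
    net = scheme.table["network"].to_numpy()
    cls = scheme.table["roi_class"].to_numpy()
    m = np.empty((p, p))
    cortical = cls == "cortical"
    same_net = net[:, None] == net[None, :]
    both_cort = cortical[:, None] & cortical[None, :]
    both_sub = ~cortical[:, None] & ~cortical[None, :]
    m[:] = 0.05
    m[both_cort] = 0.1
    m[both_cort & same_net] = 0.3
    m[both_sub] = 0.15
    np.fill_diagonal(m, 1.0)
    return nearest_correlation(m)


def nearest_correlation(
    a: np.ndarray, tol: float = 1e-10, max_iter: int = 200
) -> np.ndarray:
    """Nearest valid correlation matrix (Higham alternating projections).

    Alternates projection onto the PSD cone and onto the unit-diagonal
    affine set with a Dykstra correction; already-valid inputs are fixed
    points up to `tol`.
    """
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("input must be square")
    if np.max(np.abs(a - a.T)) > 1e-8:
        raise ValueError("input must be symmetric")
    y = a.copy()
    ds = np.zeros_like(a)
    for _ in range(max_iter):
        r = y - ds
        w, v = np.linalg.eigh((r + r.T) / 2)
        x = (v * np.clip(w, 0.0, None)) @ v.T
        x = (x + x.T) / 2
        ds = x - r
        y_next = x.copy()
        np.fill_diagonal(y_next, 1.0)
        if np.linalg.norm(y_next - y, "fro") <= tol * max(1.0, np.linalg.norm(y, "fro")):
            y = y_next
            break
        y = y_next
    # finishing step: eigen-clip then renormalize the diagonal by congruence,
    # which preserves PSD and restores an exact unit diagonal
    y = (y + y.T) / 2
    w, v = np.linalg.eigh(y)
    y = (v * np.clip(w, 0.0, None)) @ v.T
    d = np.sqrt(np.clip(np.diag(y), 1e-12, None))
    y = y / np.outer(d, d)
    y = (y + y.T) / 2
    np.fill_diagonal(y, 1.0)
    return y


# ---------------------------------------------------------------------------
# cohort generators
# ---------------------------------------------------------------------------

def _resolve_planted(scheme: ParcellationScheme, planted) -> list[tuple[int, int, int, float]]:
    p = scheme.n_rois
    out = []
    for a, b, effect in planted:
        a, b = int(min(a, b)), int(max(a, b))
        out.append((edge_id(p, a, b), a, b, float(effect)))
    return out


def _symptom_noise_sd(config: SimulationConfig, effects: np.ndarray) -> float:
    if config.symptom_noise_sd is not None:
        return config.symptom_noise_sd
    explained = float(np.sum(effects**2)) + config.sex_effect**2 * 0.25
    resid = 1.0 - explained
    if resid <= 0:
        raise ValueError(
            f"planted effects explain variance {explained:.3f} >= 1; "
            "set symptom_noise_sd explicitly or shrink the effects"
        )
    return float(np.sqrt(resid))


def simulate_cohort(config: SimulationConfig) -> tuple[CohortDataset, TruthRecord]:
    """Two-time-point cohort with symptom-linked planted connectivity change.

    Deterministic given ``config.seed``. Raises if correlation clipping
    would touch more than 1% of entries (advise smaller noise sds).
    """
    rng = np.random.default_rng(config.seed)
    scheme = config.resolved_scheme()
    p, n = scheme.n_rois, config.n_subjects
    n_edges = scheme.n_edges
    planted = _resolve_planted(scheme, config.planted_edges)
    effects = np.array([t[3] for t in planted])
    sigma_y = _symptom_noise_sd(config, effects)

    pop = population_connectome(scheme)
    idx = edge_index(p)
    pop_edges = pop[idx[:, 0], idx[:, 1]]

    sex = rng.binomial(1, 0.5, n)
    tp1_noise = rng.standard_normal((n, n_edges))
    delta_noise = rng.standard_normal((n, n_edges))

    tp1 = pop_edges[None, :] + config.baseline_sd * tp1_noise
    delta = config.delta_sd * delta_noise

    # symptom score built from the standardized planted components
    planted_ids = np.array([t[0] for t in planted], dtype=int)
    source = delta_noise if config.plant_target == "delta" else tp1_noise
    signal = source[:, planted_ids] @ effects if planted else np.zeros(n)
    symptoms_tp2 = signal + config.sex_effect * sex + sigma_y * rng.standard_normal(n)
    symptoms_tp1 = config.sex_effect * sex + sigma_y * rng.standard_normal(n)

    n_clipped = int(np.sum(np.abs(tp1) > CLIP_LIMIT))
    tp1 = np.clip(tp1, -CLIP_LIMIT, CLIP_LIMIT)
    tp2_raw = tp1 + delta
    n_clipped += int(np.sum(np.abs(tp2_raw) > CLIP_LIMIT))
    tp2 = np.clip(tp2_raw, -CLIP_LIMIT, CLIP_LIMIT)
    clip_rate = n_clipped / (2 * n * n_edges)
    if clip_rate > MAX_CLIP_RATE:
        raise ValueError(
            f"clip rate {clip_rate:.2%} exceeds {MAX_CLIP_RATE:.0%}; "
            "reduce baseline_sd/delta_sd or planted effects"
        )

    truth = TruthRecord(
        planted=tuple(planted),
        sex_effect=config.sex_effect,
        symptom_noise_sd=sigma_y,
        baseline_sd=config.baseline_sd,
        delta_sd=config.delta_sd,
        plant_target=config.plant_target,
        seed=config.seed,
        clip_rate=clip_rate,
    )

    subject_ids = [f"sub-{i:04d}" for i in range(n)]
    if config.mode == "timeseries":
        tp1, tp2 = _timeseries_edges(scheme, pop, tp2 - tp1, config.T, rng)
    dataset = CohortDataset(
        subject_ids=subject_ids,
        scheme=scheme,
        rsfc_tp1=tp1,
        rsfc_tp2=tp2,
        symptoms_tp1=symptoms_tp1,
        symptoms_tp2=symptoms_tp2,
        sex=sex,
        sex_coding={"F": 0, "M": 1},
    )
    return dataset, truth


def _timeseries_edges(scheme, pop, delta, T, rng):
    """Rebuild both time points' edges from sampled ROI time series."""
    n = delta.shape[0]
    p = scheme.n_rois
    tp1_edges = np.empty_like(delta)
    tp2_edges = np.empty_like(delta)
    for i in range(n):
        raw2 = np.clip(pop + devectorize_edges(delta[i], p), -CLIP_LIMIT, CLIP_LIMIT)
        np.fill_diagonal(raw2, 1.0)
        target2 = nearest_correlation(raw2)
        ts1 = sample_timeseries(pop, T, rng)
        ts2 = sample_timeseries(target2, T, rng)
        tp1_edges[i] = build_connectome(ts1, scheme, "TP1").edges().values
        tp2_edges[i] = build_connectome(ts2, scheme, "TP2").edges().values
    return tp1_edges, tp2_edges


def sample_timeseries(correlation: np.ndarray, T: int, rng) -> np.ndarray:
    """T x P Gaussian series with the given population correlation."""
    p = correlation.shape[0]
    w, v = np.linalg.eigh((correlation + correlation.T) / 2)
    root = (v * np.sqrt(np.clip(w, 0.0, None))) @ v.T
    return rng.standard_normal((T, p)) @ root.T


def simulate_two_group(
    config: SimulationConfig,
    group_shifts: tuple[tuple[int, int, float], ...] = (),
    n_patients: int | None = None,
    n_controls: int | None = None,
) -> tuple[CohortDataset, TruthRecord]:
    """Single-session two-group cohort; patients' planted edges are shifted.

    Shifts are expressed in units of the between-subject edge sd
    (``baseline_sd``), so a shift of 1.5 moves patients 1.5 pooled-SD.
    """
    rng = np.random.default_rng(config.seed)
    scheme = config.resolved_scheme()
    p = scheme.n_rois
    n_pat = n_patients if n_patients is not None else config.n_subjects // 2
    n_con = n_controls if n_controls is not None else config.n_subjects - n_pat
    n = n_pat + n_con
    if n_pat == 0 or n_con == 0:
        raise ValueError("both groups must be non-empty")

    pop = population_connectome(scheme)
    idx = edge_index(p)
    pop_edges = pop[idx[:, 0], idx[:, 1]]

    shifts = _resolve_planted(scheme, group_shifts)
    sex = rng.binomial(1, 0.5, n)
    values = pop_edges[None, :] + config.baseline_sd * rng.standard_normal(
        (n, scheme.n_edges)
    )
    group = np.array(["patient"] * n_pat + ["control"] * n_con, dtype=object)
    for eid, _, _, shift in shifts:
        values[:n_pat, eid] += shift * config.baseline_sd

    n_clipped = int(np.sum(np.abs(values) > CLIP_LIMIT))
    values = np.clip(values, -CLIP_LIMIT, CLIP_LIMIT)
    clip_rate = n_clipped / values.size
    if clip_rate > MAX_CLIP_RATE:
        raise ValueError(
            f"clip rate {clip_rate:.2%} exceeds {MAX_CLIP_RATE:.0%}; reduce noise/shifts"
        )

    behavior = rng.standard_normal(n)  # free-standing behavioral score
    truth = TruthRecord(
        planted=(),
        sex_effect=0.0,
        symptom_noise_sd=1.0,
        baseline_sd=config.baseline_sd,
        delta_sd=config.delta_sd,
        plant_target="tp1",
        seed=config.seed,
        clip_rate=clip_rate,
        group_shifts=tuple(shifts),
    )
    dataset = CohortDataset(
        subject_ids=[f"sub-{i:04d}" for i in range(n)],
        scheme=scheme,
        rsfc_tp1=values,
        symptoms_tp1=behavior,
        sex=sex,
        sex_coding={"F": 0, "M": 1},
        group=group,
    )
    return dataset, truth
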