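"""Cohort assembly: subjects x edges matrices plus phenotypes, with TSV I/O.

Assembly is complete-case: a subject enters the dataset only if every
required field (both time points for longitudinal cohorts, all phenotype
columns) is present. Dropped subjects are logged, never imputed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectome import ConnectomeMatrix, edge_names, vectorize_edges
from .parcellation import ParcellationScheme, load_parcellation

logger = logging.getLogger(__name__)

DEFAULT_SEX_CODING: dict[str, int] | None = None  # first level alphabetically -> 0


@dataclass
class CohortDataset:
    """Aligned per-subject edge matrices and phenotypes.

    Longitudinal cohorts carry both time points and ``delta``; single-session
    group cohorts carry only ``rsfc_tp1`` plus ``group``.
    """

    subject_ids: list[str]
    scheme: ParcellationScheme
    rsfc_tp1: np.ndarray  # n x E
    symptoms_tp1: np.ndarray
    sex: np.ndarray  # 0/1 ints
    sex_coding: dict[str, int]
    rsfc_tp2: np.ndarray | None = None
    symptoms_tp2: np.ndarray | None = None
    group: np.ndarray | None = None  # strings, e.g. patient/control
    delta: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        n = len(self.subject_ids)
        if len(set(self.subject_ids)) != n:
            raise ValueError("duplicate subject_id in cohort")
        e = self.scheme.n_edges
        for name in ("rsfc_tp1", "rsfc_tp2", "delta"):
            m = getattr(self, name)
            if m is not None and m.shape != (n, e):
                raise ValueError(f"{name} has shape {m.shape}, expected {(n, e)}")
        for name in ("symptoms_tp1", "symptoms_tp2", "sex", "group"):
            v = getattr(self, name)
            if v is not None and len(v) != n:
                raise ValueError(f"{name} has length {len(v)}, expected {n}")
        if self.rsfc_tp2 is not None:
            expected = self.rsfc_tp2 - self.rsfc_tp1
            if self.delta is None:
                self.delta = expected
            elif not np.array_equal(self.delta, expected):
                raise ValueError("delta != rsfc_tp2 - rsfc_tp1")
        for name in ("rsfc_tp1", "rsfc_tp2", "delta", "symptoms_tp1", "symptoms_tp2"):
            v = getattr(self, name)
            if v is not None and not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite values in {name}")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_edges(self) -> int:
        return self.scheme.n_edges

    @property
    def is_longitudinal(self) -> bool:
        return self.rsfc_tp2 is not None

    def edge_values(self, which: str) -> np.ndarray:
        """n x E matrix for 'delta', 'rsfc_tp1' or 'rsfc_tp2'."""
        m = getattr(self, which, None)
        if m is None:
            raise ValueError(f"cohort has no '{which}' matrix")
        return m

    # -- I/O -------------------------------------------------------------

    def write(self, outdir, prefix: str = "") -> None:
        """Write wide edge TSVs, a phenotype TSV and a JSON sidecar."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cols = edge_names(self.scheme)
        for name in ("rsfc_tp1", "rsfc_tp2", "delta"):
            m = getattr(self, name)
            if m is None:
                continue
            df = pd.DataFrame(m, columns=cols)
            df.insert(0, "subject_id", self.subject_ids)
            df.to_csv(outdir / f"{prefix}{name}.tsv", sep="\t", index=False)
        pheno = self.phenotype_frame()
        pheno.to_csv(outdir / f"{prefix}phenotypes.tsv", sep="\t", index=False)
        self.scheme.to_tsv(outdir / f"{prefix}parcellation.tsv")
        sidecar = {
            "n_subjects": self.n_subjects,
            "n_edges": self.n_edges,
            "parcellation_hash": parcellation_hash(self.scheme),
            "sex_coding": self.sex_coding,
            "longitudinal": self.is_longitudinal,
        }
        (outdir / f"{prefix}cohort.json").write_text(json.dumps(sidecar, indent=2))

    def phenotype_frame(self) -> pd.DataFrame:
        inv = {v: k for k, v in self.sex_coding.items()}
        df = pd.DataFrame(
            {
                "subject_id": self.subject_ids,
                "sex": [inv[s] for s in self.sex],
                "symptoms_tp1": self.symptoms_tp1,
            }
        )
        if self.symptoms_tp2 is not None:
            df["symptoms_tp2"] = self.symptoms_tp2
        if self.group is not None:
            df["group"] = self.group
        return df


def parcellation_hash(scheme: ParcellationScheme) -> str:
    import hashlib

    payload = scheme.table.to_csv(index=False).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _encode_sex(values: pd.Series, coding: dict[str, int] | None) -> tuple[np.ndarray, dict[str, int]]:
    levels = sorted(set(values.astype(str)))
    if coding is None:
        if len(levels) > 2:
            raise ValueError(f"sex has more than two levels: {levels}")
        coding = {lev: i for i, lev in enumerate(levels)}  # alphabetical -> 0,1
    unknown = set(values.astype(str)) - set(coding)
    if unknown:
        raise ValueError(f"unparseable sex code(s): {sorted(unknown)}")
    return values.astype(str).map(coding).to_numpy(dtype=int), dict(coding)


def assemble_cohort(
    connectomes: dict[str, dict[str, ConnectomeMatrix]],
    phenotypes: pd.DataFrame,
    scheme: ParcellationScheme,
    sex_coding: dict[str, int] | None = DEFAULT_SEX_CODING,
    require_tp2: bool = True,
) -> CohortDataset:
    """Complete-case assembly of per-subject connectome pairs and phenotypes.

    Parameters
    ----------
    connectomes
        Mapping subject_id -> {"tp1": ConnectomeMatrix, "tp2": ConnectomeMatrix}
        ("tp2" optional when ``require_tp2`` is False).
    phenotypes
        Table keyed by subject_id with columns sex, symptoms_tp1 and, for
        longitudinal cohorts, symptoms_tp2 (optional: group).
    """
    if phenotypes["subject_id"].duplicated().any():
        dups = phenotypes.loc[phenotypes["subject_id"].duplicated(), "subject_id"]
        raise ValueError(f"duplicated subject_id in phenotypes: {sorted(set(dups))}")
    pheno = phenotypes.set_index(phenotypes["subject_id"].astype(str))

    needed = ["sex", "symptoms_tp1"] + (["symptoms_tp2"] if require_tp2 else [])
    kept, dropped = [], []
    for sid in pheno.index:
        pair = connectomes.get(sid, {})
        ok = "tp1" in pair and (not require_tp2 or "tp2" in pair)
        ok = ok and not pheno.loc[sid, needed].isna().any()
        (kept if ok else dropped).append(sid)
    for sid, pair in connectomes.items():
        if sid not in pheno.index:
            dropped.append(sid)
    if dropped:
        logger.info("assemble_cohort: dropped %d incomplete subject(s): %s",
                    len(dropped), sorted(set(dropped)))
    if not kept:
        raise ValueError("no subjects with complete data")
    logger.info("assemble_cohort: retained %d of %d subjects",
                len(kept), len(set(pheno.index) | set(connectomes)))

    tp1 = np.vstack([connectomes[s]["tp1"].edges().values for s in kept])
    tp2 = None
    if require_tp2:
        tp2 = np.vstack([connectomes[s]["tp2"].edges().values for s in kept])
    sex, coding = _encode_sex(pheno.loc[kept, "sex"], sex_coding)
    return CohortDataset(
        subject_ids=list(kept),
        scheme=scheme,
        rsfc_tp1=tp1,
        rsfc_tp2=tp2,
        symptoms_tp1=pheno.loc[kept, "symptoms_tp1"].to_numpy(dtype=float),
        symptoms_tp2=(
            pheno.loc[kept, "symptoms_tp2"].to_numpy(dtype=float) if require_tp2 else None
        ),
        sex=sex,
        sex_coding=coding,
        group=(
            pheno.loc[kept, "group"].to_numpy(dtype=object)
            if "group" in pheno.columns and pheno.loc[kept, "group"].notna().all()
            else None
        ),
    )


def load_cohort(indir, prefix: str = "") -> CohortDataset:
    """Read a cohort written by :meth:`CohortDataset.write`."""
    from pathlib import Path

    indir = Path(indir)
    scheme = load_parcellation(indir / f"{prefix}parcellation.tsv")
    sidecar = json.loads((indir / f"{prefix}cohort.json").read_text())

    def read_matrix(name):
        path = indir / f"{prefix}{name}.tsv"
        if not path.exists():
            return None, None
        df = pd.read_csv(path, sep="\t")
        sids = df["subject_id"].astype(str).tolist()
        expected = edge_names(scheme)
        if list(df.columns[1:]) != expected:
            raise ValueError(f"{name}.tsv edge columns do not match parcellation")
        return df[expected].to_numpy(dtype=float), sids

    tp1, sids = read_matrix("rsfc_tp1")
    if tp1 is None:
        raise FileNotFoundError(indir / f"{prefix}rsfc_tp1.tsv")
    tp2, sids2 = read_matrix("rsfc_tp2")
    if tp2 is not None and sids2 != sids:
        raise ValueError("subject order differs between rsfc_tp1 and rsfc_tp2")
    pheno = pd.read_csv(indir / f"{prefix}phenotypes.tsv", sep="\t", dtype={"subject_id": str})
    pheno = pheno.set_index("subject_id").loc[sids].reset_index()
    coding = {str(k): int(v) for k, v in sidecar["sex_coding"].items()}
    sex, coding = _encode_sex(pheno["sex"], coding)
    return CohortDataset(
        subject_ids=sids,
        scheme=scheme,
        rsfc_tp1=tp1,
        rsfc_tp2=tp2,
        symptoms_tp1=pheno["symptoms_tp1"].to_numpy(dtype=float),
        symptoms_tp2=(
            pheno["symptoms_tp2"].to_numpy(dtype=float)
            if "symptoms_tp2" in pheno.columns
            else None
        ),
        sex=sex,
        sex_coding=coding,
        group=pheno["group"].to_numpy(dtype=object) if "group" in pheno.columns else None,
    )


def load_timeseries(path, scheme: ParcellationScheme) -> np.ndarray:
    """Read one subject/time-point T x P time-series TSV (header = roi_name)."""
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != scheme.roi_names:
        raise ValueError(f"{path}: columns do not match parcellation ROI names")
    return df.to_numpy(dtype=float)
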