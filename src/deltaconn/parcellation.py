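"""Parcellation tables: ROI metadata, class/network bookkeeping, edge universe."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_HEMISPHERES = frozenset({"L", "R", "bilateral"})
VALID_CLASSES = frozenset({"cortical", "subcortical"})


@dataclass(frozen=True)
class ParcellationScheme:
    """ROI metadata table defining the edge universe and aggregation groups.

    ROI ids are 0-based and contiguous, assigned in table order. Every
    cortical ROI must carry a non-empty network label.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"roi_id", "roi_name", "hemisphere", "roi_class", "network"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"parcellation table missing columns: {sorted(missing)}")
        ids = self.table["roi_id"].to_numpy()
        if not np.array_equal(ids, np.arange(len(ids))):
            raise ValueError("roi_id must be 0-based and contiguous in table order")
        if self.table["roi_name"].duplicated().any():
            dups = self.table.loc[self.table["roi_name"].duplicated(), "roi_name"]
            raise ValueError(f"duplicate roi_name values: {sorted(set(dups))}")
        bad_hemi = set(self.table["hemisphere"]) - VALID_HEMISPHERES
        if bad_hemi:
            raise ValueError(f"unknown hemisphere values: {sorted(bad_hemi)}")
        bad_class = set(self.table["roi_class"]) - VALID_CLASSES
        if bad_class:
            raise ValueError(f"unknown roi_class values: {sorted(bad_class)}")
        cortical = self.table["roi_class"] == "cortical"
        net = self.table.loc[cortical, "network"]
        if net.isna().any() or (net.astype(str).str.strip() == "").any():
            raise ValueError("every cortical ROI needs a non-empty network label")

    # -- basic queries ---------------------------------------------------

    @property
    def n_rois(self) -> int:
        return len(self.table)

    @property
    def n_edges(self) -> int:
        p = self.n_rois
        return p * (p - 1) // 2

    @property
    def roi_names(self) -> list[str]:
        return self.table["roi_name"].tolist()

    @property
    def cortical_ids(self) -> np.ndarray:
        return self.table.loc[self.table["roi_class"] == "cortical", "roi_id"].to_numpy()

    @property
    def subcortical_ids(self) -> np.ndarray:
        return self.table.loc[
            self.table["roi_class"] == "subcortical", "roi_id"
        ].to_numpy()

    def networks(self, roi_class: str | None = "cortical") -> list[str]:
        """Distinct network labels, in first-appearance order."""
        sub = self.table
        if roi_class is not None:
            sub = sub[sub["roi_class"] == roi_class]
        return list(dict.fromkeys(sub["network"].dropna()))

    def network_ids(self, network: str) -> np.ndarray:
        """ROI ids carrying a network label."""
        return self.table.loc[self.table["network"] == network, "roi_id"].to_numpy()

    def ids_by_name(self, names) -> np.ndarray:
        lookup = {n: i for i, n in enumerate(self.roi_names)}
        try:
            return np.array([lookup[n] for n in names], dtype=int)
        except KeyError as exc:
            raise KeyError(f"ROI name not in parcellation: {exc.args[0]}") from None

    def class_counts(self) -> dict[str, int]:
        return self.table["roi_class"].value_counts().to_dict()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def make_parcellation(table: pd.DataFrame) -> ParcellationScheme:
    """Build a scheme from a table without roi_id (assigned in row order)."""
    table = table.reset_index(drop=True).copy()
    table.insert(0, "roi_id", np.arange(len(table)))
    return ParcellationScheme(table)


def load_parcellation(path) -> ParcellationScheme:
    """Read a parcellation TSV with columns roi_name, hemisphere, roi_class, network.

    ROI ids are assigned contiguously in file order.
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    required = {"roi_name", "hemisphere", "roi_class", "network"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"parcellation file missing columns: {sorted(missing)}")
    return make_parcellation(table[["roi_name", "hemisphere", "roi_class", "network"]])
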