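"""Aggregation of edge-wise results: network frequency tables and hub scores.

All aggregations read the row of the ROI under report, consistent with the
row-wise FDR convention (each edge carries one adjusted p per endpoint).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cwas import EdgeResultTable
from .parcellation import ParcellationScheme


@dataclass(frozen=True)
class FrequencyTable:
    """Per (subcortical ROI, network) share of significant edges.

    ``frequency = n_sig / n_total`` where n_total is the number of scheme
    ROIs carrying the network label (the row ROI has exactly one edge to each
    of them). Cells with n_total = 0 are empty (NaN).
    """

    frequency: pd.DataFrame  # rows = ROI names, columns = networks
    n_sig: pd.DataFrame
    n_total: pd.DataFrame

    def to_tsv(self, path, transpose: bool = False) -> None:
        table = self.frequency.T if transpose else self.frequency
        table.to_csv(path, sep="\t", index_label="roi" if not transpose else "network")


def network_frequency(
    results: EdgeResultTable,
    scheme: ParcellationScheme | None = None,
    rois=None,
    networks=None,
    network_map: dict[str, str] | None = None,
) -> FrequencyTable:
    """Frequency of significant edges from each subcortical ROI to each network.

    ``network_map`` optionally collapses fine-grained labels (e.g. 16
    sub-networks onto 7 reporting columns); it is applied to the scheme's
    labels before counting, never hardcoded.
    """
    scheme = scheme or results.scheme
    results._require_bh()
    if rois is None:
        rois = scheme.subcortical_ids
    rois = np.atleast_1d(np.asarray(rois, dtype=int))
    for roi in rois:
        if not 0 <= roi < scheme.n_rois:
            raise ValueError(f"roi {roi} not in parcellation")

    labels = scheme.table["network"].astype(object).copy()
    if network_map:
        labels = labels.map(lambda s: network_map.get(s, s))
    cortical_mask = (scheme.table["roi_class"] == "cortical").to_numpy()
    if networks is None:
        networks = list(dict.fromkeys(labels[cortical_mask]))

    roi_names = [scheme.roi_names[r] for r in rois]
    freq = pd.DataFrame(index=roi_names, columns=list(networks), dtype=float)
    nsig = freq.copy()
    ntot = freq.copy()
    label_arr = labels.to_numpy()
    for roi, roi_name in zip(rois, roi_names):
        edges = results.row_edges(roi)
        partner = np.where(
            results.edge_idx[edges, 0] == roi,
            results.edge_idx[edges, 1],
            results.edge_idx[edges, 0],
        )
        flags = results.row_flags(roi)
        for net in networks:
            members = cortical_mask & (label_arr == net)
            n_total = int(members.sum())
            in_net = members[partner]
            n_sig = int(flags[in_net].sum())
            ntot.loc[roi_name, net] = n_total
            if n_total == 0:
                continue
            nsig.loc[roi_name, net] = n_sig
            freq.loc[roi_name, net] = n_sig / n_total
    return FrequencyTable(frequency=freq, n_sig=nsig, n_total=ntot)


def hub_scores(
    results: EdgeResultTable, scheme: ParcellationScheme | None = None
) -> pd.DataFrame:
    """Signed per-ROI hub score: n significant positive minus negative edges."""
    scheme = scheme or results.scheme
    results._require_bh()
    col = results.term_column(results.tested_term)
    rows = []
    for roi in range(scheme.n_rois):
        edges = results.row_edges(roi)
        flags = results.row_flags(roi)
        betas = results.beta[edges, col]
        n_pos = int((flags & (betas > 0)).sum())
        n_neg = int((flags & (betas < 0)).sum())
        rows.append(
            {
                "roi_id": roi,
                "roi_name": scheme.roi_names[roi],
                "n_pos": n_pos,
                "n_neg": n_neg,
                "score": n_pos - n_neg,
            }
        )
    return pd.DataFrame(rows)
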