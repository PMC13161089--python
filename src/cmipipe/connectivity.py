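"""Resting-state functional connectivity summaries.

From parcellated BOLD time-series (parcels x timepoints) this module
builds the Fisher-z connectivity matrix, extracts mean within-network
connectivity for the networks of interest (visual, sensorimotor control,
dorsal attention, salience ventral attention, frontoparietal control and
default mode; the limbic network is excluded from analysis), splits the
frontoparietal control network into a/b/c subnetworks by nearest-centroid
matching against a finer parcellation, and computes the parcel-homogeneity
QC metric (mean pairwise temporal correlation of the vertices inside a
parcel).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = [
    "ConnectivityMatrix",
    "ANALYSIS_NETWORKS",
    "connectivity_matrix",
    "within_network_mean",
    "within_network_table",
    "assign_fpcn_subnetworks",
    "parcel_homogeneity",
]

ANALYSIS_NETWORKS = ["VN", "SMN", "DAN", "SVAN", "FPCN", "DMN"]
EXCLUDED_NETWORKS = {"limbic"}

_FISHER_EPS = 1e-7  # |r| -> 1 guard before arctanh


@dataclass
class ConnectivityMatrix:
    """Symmetric Fisher-z matrix; the diagonal is undefined (NaN)."""

    z: np.ndarray
    parcel_ids: np.ndarray
    flagged: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def n_parcels(self) -> int:
        return self.z.shape[0]


def connectivity_matrix(ts: np.ndarray, parcel_ids=None) -> ConnectivityMatrix:
    """Pairwise Pearson correlations mapped through Fisher's r-to-z.

    ``ts`` is parcels x timepoints.  Zero-variance parcels are flagged and
    their pair entries set missing; correlations at |r| = 1 are clamped to
    1 - 1e-7 before arctanh so the matrix stays finite.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2 or ts.shape[1] < 3:
        raise ValueError("need a parcels x timepoints matrix with T >= 3")
    P = ts.shape[0]
    sd = ts.std(axis=1)
    flagged = np.flatnonzero(sd == 0)
    safe = ts.copy()
    safe[flagged] = np.random.default_rng(0).standard_normal(
        (flagged.size, ts.shape[1])
    )  # placeholder rows; overwritten with NaN below
    r = np.corrcoef(safe)
    r = np.clip(r, -1.0 + _FISHER_EPS, 1.0 - _FISHER_EPS)
    z = np.arctanh(r)
    np.fill_diagonal(z, np.nan)
    z[flagged, :] = np.nan
    z[:, flagged] = np.nan
    ids = np.arange(P) if parcel_ids is None else np.asarray(parcel_ids)
    return ConnectivityMatrix(z=z, parcel_ids=ids, flagged=flagged)


def within_network_mean(
    m: ConnectivityMatrix, labels: pd.DataFrame, network: str
) -> float:
    """Mean Fisher-z over all distinct parcel pairs inside one network.

    The diagonal and any flagged (zero-variance) parcels are excluded;
    the mean is over the surviving unordered pairs.
    """
    idx = labels.loc[labels["network"] == network, "parcel_id"].to_numpy()
    pos = np.flatnonzero(np.isin(m.parcel_ids, idx))
    if pos.size < 2:
        raise ValueError(f"network {network!r} has fewer than 2 parcels")
    sub = m.z[np.ix_(pos, pos)]
    iu = np.triu_indices(pos.size, k=1)
    vals = sub[iu]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError(f"no finite pairs in network {network!r}")
    return float(vals.mean())


def within_network_table(
    timeseries: dict[str, np.ndarray],
    labels: pd.DataFrame,
    networks: list[str] | None = None,
    fpcn_sublabels: bool = True,
) -> pd.DataFrame:
    """Participant x network table of mean within-network connectivity.

    ``networks`` defaults to the six analysis networks; when the label
    table carries FPCN sublabels, FPCNa/b/c columns are added.
    """
    networks = list(ANALYSIS_NETWORKS) if networks is None else networks
    rows = []
    for pid, ts in timeseries.items():
        m = connectivity_matrix(ts, labels["parcel_id"].to_numpy())
        row: dict = {"participant": pid}
        for net in networks:
            row[f"rsfc_{net}"] = within_network_mean(m, labels, net)
        if fpcn_sublabels and "sublabel" in labels.columns:
            for sub in ("a", "b", "c"):
                sub_labels = labels[
                    (labels["network"] == "FPCN") & (labels["sublabel"] == sub)
                ]
                if len(sub_labels) >= 2:
                    fake = sub_labels.assign(network=f"FPCN{sub}")
                    row[f"rsfc_FPCN{sub}"] = within_network_mean(
                        m, fake, f"FPCN{sub}"
                    )
        rows.append(row)
    return pd.DataFrame(rows)


def assign_fpcn_subnetworks(
    centroids7: pd.DataFrame,
    centroids17: pd.DataFrame,
    labels: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Split coarse-parcellation FPCN parcels into a/b/c subnetworks.

    Each FPCN centroid of the 7-network table receives the sublabel of
    its nearest (Euclidean, MNI mm) FPCN centroid in the 17-network
    table.  Ties break deterministically toward the lowest candidate
    parcel id.  Expects columns parcel_id, x, y, z (+ sublabel on the
    17-network side); returns parcel_id, sublabel, distance_mm.
    """
    if centroids7.empty or centroids17.empty:
        raise ValueError("centroid tables must be non-empty")
    if "sublabel" not in centroids17.columns:
        raise ValueError("17-network centroids must carry a/b/c sublabels")
    c17 = centroids17.sort_values("parcel_id").reset_index(drop=True)
    A = centroids7[["x", "y", "z"]].to_numpy(dtype=float)
    B = c17[["x", "y", "z"]].to_numpy(dtype=float)
    D = cdist(A, B)
    # argmin returns the first (lowest-index) minimum: with candidates
    # sorted by parcel_id this is the documented tie-break.
    nearest = D.argmin(axis=1)
    out = pd.DataFrame(
        {
            "parcel_id": centroids7["parcel_id"].to_numpy(),
            "sublabel": c17["sublabel"].to_numpy()[nearest],
            "distance_mm": D[np.arange(len(A)), nearest],
        }
    )
    if labels is not None:
        labels = labels.copy()
        sub_map = dict(zip(out["parcel_id"], out["sublabel"]))
        mask = labels["network"] == "FPCN"
        labels.loc[mask, "sublabel"] = labels.loc[mask, "parcel_id"].map(sub_map)
        return labels
    return out


def parcel_homogeneity(
    vertex_ts: np.ndarray, parcel_labels: np.ndarray
) -> tuple[pd.DataFrame, float]:
    """Mean pairwise temporal correlation of the vertices in each parcel.

    Constant vertex series are excluded from the pairs (and counted).
    Returns (per-parcel table, whole-brain mean across parcels).
    """
    vertex_ts = np.asarray(vertex_ts, dtype=float)
    parcel_labels = np.asarray(parcel_labels)
    rows = []
    for parcel in np.unique(parcel_labels):
        idx = np.flatnonzero(parcel_labels == parcel)
        if idx.size < 2:
            raise ValueError(f"parcel {parcel!r} has fewer than 2 vertices")
        sub = vertex_ts[idx]
        ok = sub.std(axis=1) > 0
        n_const = int((~ok).sum())
        sub = sub[ok]
        if sub.shape[0] < 2:
            rows.append(
                {"parcel": parcel, "homogeneity": np.nan, "n_vertices": idx.size,
                 "n_constant": n_const}
            )
            continue
        r = np.corrcoef(sub)
        iu = np.triu_indices(sub.shape[0], k=1)
        rows.append(
            {"parcel": parcel, "homogeneity": float(r[iu].mean()),
             "n_vertices": idx.size, "n_constant": n_const}
        )
    table = pd.DataFrame(rows)
    whole = float(np.nanmean(table["homogeneity"]))
    return table, whole
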