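"""Per-subject Fisher-z functional connectivity from parcel time series.

The functional connectome of one subject is the matrix of pairwise
Pearson correlations between parcel time series, variance-stabilized by
the Fisher z-transform z = atanh(r). The diagonal is fixed at 0 (not
atanh(1) = inf) so the matrix can be thresholded and averaged — the
standard connectome-toolbox convention. No further normalization by
sqrt(T - 3) is applied; z values are used directly as connectivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: the seven canonical resting-state networks of the 400-parcel scheme
SEVEN_NETWORKS = ("FPN", "DMN", "SN", "LN", "DAN", "SMN", "VN")


@dataclass
class SubjectTimeSeries:
    """T x N matrix of parcel signals for one subject (rows = volumes)."""

    values: np.ndarray
    parcel_ids: tuple[str, ...]
    subject_id: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.parcel_ids = tuple(str(p) for p in self.parcel_ids)
        if self.values.ndim != 2:
            raise ValueError("time series must be a 2-D (T x N) matrix")
        t, n = self.values.shape
        if t < 3:
            raise ValueError(f"need at least 3 time points, got {t}")
        if n != len(self.parcel_ids):
            raise ValueError("column count does not match number of parcel ids")
        if len(set(self.parcel_ids)) != n:
            raise ValueError("parcel ids must be unique")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.values.shape[1]


@dataclass
class ParcelAtlas:
    """Ordered parcels with their assignment to named functional networks."""

    parcel_ids: tuple[str, ...]
    network_of: dict[str, str]

    def __post_init__(self):
        self.parcel_ids = tuple(str(p) for p in self.parcel_ids)
        missing = [p for p in self.parcel_ids if p not in self.network_of]
        if missing:
            raise ValueError(f"atlas does not map parcels: {missing[:5]}")

    @property
    def networks(self) -> tuple[str, ...]:
        seen: list[str] = []
        for p in self.parcel_ids:
            nw = self.network_of[p]
            if nw not in seen:
                seen.append(nw)
        return tuple(seen)

    def parcels_in(self, network: str) -> list[str]:
        return [p for p in self.parcel_ids if self.network_of[p] == network]


@dataclass
class ConnectivityMatrix:
    """N x N symmetric Fisher-z correlation matrix with zero diagonal."""

    z: np.ndarray
    parcel_ids: tuple[str, ...]
    subject_id: str

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        self.parcel_ids = tuple(str(p) for p in self.parcel_ids)
        n = len(self.parcel_ids)
        if self.z.shape != (n, n):
            raise ValueError("matrix shape does not match parcel ids")
        if not np.allclose(self.z, self.z.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        if np.any(np.diagonal(self.z) != 0.0):
            raise ValueError("diagonal must be exactly 0")
        off = self.z[~np.eye(n, dtype=bool)]
        if not np.all(np.isfinite(off)):
            raise ValueError("off-diagonal entries must be finite")

    @property
    def n_parcels(self) -> int:
        return len(self.parcel_ids)


def compute_fc(ts: SubjectTimeSeries) -> ConnectivityMatrix:
    """Fisher-z Pearson connectivity: z[i,j] = atanh(r(column_i, column_j)).

    Raises if any column is constant (correlation undefined) or any
    off-diagonal |r| reaches 1 (atanh diverges; usually a duplicated
    parcel).
    """
    x = ts.values
    constant = np.ptp(x, axis=0) == 0  # exact, unlike a std-based check
    if np.any(constant):
        bad = ts.parcel_ids[int(np.argmax(constant))]
        raise ValueError(f"subject {ts.subject_id}: parcel {bad!r} has a constant time series")
    r = np.corrcoef(x, rowvar=False)
    n = ts.n_parcels
    offmask = ~np.eye(n, dtype=bool)
    amax = np.abs(r[offmask]).max() if n > 1 else 0.0
    if amax >= 1.0 - 1e-12:
        ii, jj = np.unravel_index(np.argmax(np.abs(np.where(offmask, r, 0.0))), r.shape)
        raise ValueError(
            f"subject {ts.subject_id}: |r| = 1 between parcels "
            f"{ts.parcel_ids[ii]!r} and {ts.parcel_ids[jj]!r} (duplicated signal?)"
        )
    np.fill_diagonal(r, 0.0)  # keep atanh off the r=1 diagonal
    z = np.arctanh(r)
    z = (z + z.T) / 2.0  # enforce exact symmetry against rounding
    return ConnectivityMatrix(z=z, parcel_ids=ts.parcel_ids, subject_id=ts.subject_id)


def network_mean_fc(cm: ConnectivityMatrix, atlas: ParcelAtlas) -> dict[str, float]:
    """Mean z over within-network edges, per network.

    Only unordered parcel pairs with BOTH endpoints inside the network
    count; cross-network edges are excluded. A single-parcel network has
    no within edges and yields NaN with a warning.
    """
    if set(atlas.parcel_ids) != set(cm.parcel_ids):
        raise ValueError("atlas parcels do not match connectivity matrix parcels")
    idx = {p: i for i, p in enumerate(cm.parcel_ids)}
    out: dict[str, float] = {}
    for nw in atlas.networks:
        members = np.array([idx[p] for p in atlas.parcels_in(nw)])
        if members.size < 2:
            warnings.warn(f"network {nw!r} has a single parcel; within-network mean undefined")
            out[nw] = float("nan")
            continue
        sub = cm.z[np.ix_(members, members)]
        iu = np.triu_indices(members.size, 1)
        out[nw] = float(sub[iu].mean())
    return out


def upper_triangle(cm: ConnectivityMatrix):
    """Vectorize the unique off-diagonal entries in row-major (i < j) order.

    Returns ``(labels, values)`` where labels are (parcel_i, parcel_j)
    tuples; length N(N-1)/2 — e.g. 79,800 edges for 400 parcels.
    """
    n = cm.n_parcels
    ii, jj = np.triu_indices(n, 1)
    labels = [(cm.parcel_ids[i], cm.parcel_ids[j]) for i, j in zip(ii, jj)]
    return labels, cm.z[ii, jj].copy()


# ---------------------------------------------------------------------------
# TSV I/O


def read_timeseries_tsv(path: str | Path, subject_id: str | None = None) -> SubjectTimeSeries:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    return SubjectTimeSeries(
        values=df.to_numpy(dtype=float),
        parcel_ids=tuple(df.columns),
        subject_id=subject_id or path.stem,
    )


def write_timeseries_tsv(ts: SubjectTimeSeries, path: str | Path, header_comment: str | None = None):
    _write_df(pd.DataFrame(ts.values, columns=list(ts.parcel_ids)), path, header_comment, index=False)


def read_atlas_tsv(path: str | Path) -> ParcelAtlas:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if list(df.columns[:2]) != ["parcel_id", "network_name"]:
        raise ValueError(f"{path}: expected columns parcel_id, network_name")
    return ParcelAtlas(
        parcel_ids=tuple(df["parcel_id"]),
        network_of=dict(zip(df["parcel_id"], df["network_name"])),
    )


def write_atlas_tsv(atlas: ParcelAtlas, path: str | Path, header_comment: str | None = None):
    df = pd.DataFrame(
        {"parcel_id": atlas.parcel_ids, "network_name": [atlas.network_of[p] for p in atlas.parcel_ids]}
    )
    _write_df(df, path, header_comment, index=False)


def read_fc_tsv(path: str | Path, subject_id: str | None = None) -> ConnectivityMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return ConnectivityMatrix(
        z=df.to_numpy(dtype=float),
        parcel_ids=tuple(df.columns),
        subject_id=subject_id or path.stem,
    )


def write_fc_tsv(cm: ConnectivityMatrix, path: str | Path, header_comment: str | None = None):
    df = pd.DataFrame(cm.z, index=list(cm.parcel_ids), columns=list(cm.parcel_ids))
    _write_df(df, path, header_comment, index=True)


def _write_df(df: pd.DataFrame, path: str | Path, header_comment: str | None, index: bool):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=index, lineterminator="\n")
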