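"""Synthetic benchmark graphs and two-group modular time-series datasets.

Stands in for parcellated resting-state scans that cannot be shipped:
every downstream stage (connectivity, thresholding, group statistics)
is exercised on data whose generating structure — and hence the expected
direction of every group effect — is known exactly.

The time-series model is a zero-mean multivariate normal whose
correlation matrix is compound-symmetric per block: ``within_r`` on
same-module off-diagonals, ``between_r`` across modules, 1 on the
diagonal. Volumes are i.i.d. in time (static Pearson connectivity is the
only consumer, so temporal autocorrelation would change nothing but the
effective sample size).

Choosing the group effect deserves care. Proportional thresholding
binarizes by *rank order* of edge weights, so if both groups' within-
module correlations exceed the between-module level by much more than
the sampling noise of a group-averaged z-matrix (roughly
(1 - r^2) / sqrt(T * n_subjects) per edge), the ranked edge list is the
same "all within first, then between" sequence in both groups and the
binary graphs are identically distributed — no effect survives
binarization no matter how large the correlation difference. The default
case group therefore sits near the noise margin: its within/between gap
is comparable to that noise, so cross-module edges genuinely displace
within-module edges at threshold, which is what weakened functional
segregation means for a binary connectome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import (
    SEVEN_NETWORKS,
    ParcelAtlas,
    SubjectTimeSeries,
    write_atlas_tsv,
    write_timeseries_tsv,
)
from .graph import BinaryGraph

GRAPH_KINDS = ("complete", "star", "path", "ring", "triangle_pendant", "erdos_renyi")

#: default demonstration conditions: 15 subjects per group, 640 volumes,
#: 100 parcels in 7 modules; case group's within-module correlation
#: reduced by 0.15 (weakened segregation near the binarization noise floor).
DEFAULT_N_PARCELS = 100
DEFAULT_N_TIMEPOINTS = 640
DEFAULT_N_PER_GROUP = 15
DEFAULT_WITHIN_R_CONTROL = 0.23
DEFAULT_WITHIN_R_CASE = 0.08
DEFAULT_BETWEEN_R = 0.05


def make_benchmark_graph(kind: str, n: int, seed: int | None = None) -> BinaryGraph:
    """Named graphs with known metric values, for validating the metrics.

    ``triangle_pendant`` is the 4-node triangle with one pendant node
    (edges 0-1, 0-2, 1-2, 2-3); ``erdos_renyi`` draws each edge with
    probability 0.5 under the given seed.
    """
    if kind not in GRAPH_KINDS:
        raise ValueError(f"unknown graph kind {kind!r}; choose from {GRAPH_KINDS}")
    if kind == "triangle_pendant":
        if n != 4:
            raise ValueError("triangle_pendant is defined on exactly 4 nodes")
        return BinaryGraph(4, edges=[(0, 1), (0, 2), (1, 2), (2, 3)])
    if n < 3:
        raise ValueError(f"{kind} graph needs at least 3 nodes, got {n}")
    if kind == "complete":
        edges = [(i, j) for i in range(n) for j in range(i + 1, n)]
    elif kind == "star":
        edges = [(0, i) for i in range(1, n)]
    elif kind == "path":
        edges = [(i, i + 1) for i in range(n - 1)]
    elif kind == "ring":
        edges = [(i, (i + 1) % n) for i in range(n)]
    else:  # erdos_renyi
        rng = np.random.default_rng(seed)
        ii, jj = np.triu_indices(n, 1)
        keep = rng.random(ii.size) < 0.5
        edges = list(zip(ii[keep].tolist(), jj[keep].tolist()))
    return BinaryGraph(n, edges=edges)


@dataclass(frozen=True)
class ModularCovSpec:
    """Block compound-symmetric correlation structure for one group.

    ``module_assignment`` maps each parcel index 0..n_parcels-1 to a
    module id; every module needs at least 2 parcels. The implied
    correlation matrix must be positive semi-definite — rejected at
    construction rather than clipped, because clipping would silently
    change the effect size asked for.
    """

    n_parcels: int
    module_assignment: tuple[int, ...]
    within_r: float
    between_r: float
    n_timepoints: int

    def __post_init__(self):
        if self.n_parcels < 2:
            raise ValueError("need at least 2 parcels")
        if self.n_timepoints < 3:
            raise ValueError("need at least 3 time points")
        ma = tuple(int(m) for m in self.module_assignment)
        if len(ma) != self.n_parcels:
            raise ValueError("module_assignment must cover every parcel")
        _, counts = np.unique(ma, return_counts=True)
        if counts.min() < 2:
            raise ValueError("every module needs at least 2 parcels")
        for name, r in (("within_r", self.within_r), ("between_r", self.between_r)):
            if not -1.0 < r < 1.0:
                raise ValueError(f"{name} must lie in (-1, 1), got {r}")
        object.__setattr__(self, "module_assignment", ma)
        ev = np.linalg.eigvalsh(self.correlation_matrix())
        if ev.min() < -1e-10:
            raise ValueError(
                f"implied correlation matrix is not positive semi-definite "
                f"(min eigenvalue {ev.min():.3g})"
            )

    @property
    def is_segregated(self) -> bool:
        return self.within_r > self.between_r >= 0.0

    def correlation_matrix(self) -> np.ndarray:
        m = np.asarray(self.module_assignment)
        same = m[:, None] == m[None, :]
        r = np.where(same, self.within_r, self.between_r)
        np.fill_diagonal(r, 1.0)
        return r

    @classmethod
    def balanced(
        cls,
        n_parcels: int = DEFAULT_N_PARCELS,
        n_modules: int = len(SEVEN_NETWORKS),
        within_r: float = DEFAULT_WITHIN_R_CONTROL,
        between_r: float = DEFAULT_BETWEEN_R,
        n_timepoints: int = DEFAULT_N_TIMEPOINTS,
    ) -> "ModularCovSpec":
        """Near-equal module sizes, mirroring a parcellation's networks."""
        return cls(
            n_parcels=n_parcels,
            module_assignment=tuple(balanced_modules(n_parcels, n_modules)),
            within_r=within_r,
            between_r=between_r,
            n_timepoints=n_timepoints,
        )


def balanced_modules(n_parcels: int, n_modules: int) -> np.ndarray:
    """Assign parcels to modules with sizes differing by at most one."""
    if n_parcels < 2 * n_modules:
        raise ValueError("need at least 2 parcels per module")
    sizes = np.full(n_modules, n_parcels // n_modules)
    sizes[: n_parcels % n_modules] += 1
    return np.repeat(np.arange(n_modules), sizes)


@dataclass(frozen=True)
class GroupDesign:
    """Two-group sampling design sharing one parcellation."""

    control_spec: ModularCovSpec
    case_spec: ModularCovSpec
    n_per_group: int = DEFAULT_N_PER_GROUP
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.control_spec.n_parcels != self.case_spec.n_parcels:
            raise ValueError("both specs must share n_parcels")
        if self.control_spec.module_assignment != self.case_spec.module_assignment:
            raise ValueError("both specs must share the module assignment")

    @classmethod
    def default(cls, seed: int = 0, n_per_group: int = DEFAULT_N_PER_GROUP) -> "GroupDesign":
        """The package's demonstration design: a segregation deficit.

        The case group's within-module correlation is reduced by 0.15
        relative to controls; between-module correlation is shared.
        """
        return cls(
            control_spec=ModularCovSpec.balanced(within_r=DEFAULT_WITHIN_R_CONTROL),
            case_spec=ModularCovSpec.balanced(within_r=DEFAULT_WITHIN_R_CASE),
            n_per_group=n_per_group,
            seed=seed,
        )


def _parcel_ids(n_parcels: int) -> tuple[str, ...]:
    width = len(str(n_parcels - 1))
    return tuple(f"parcel_{i:0{width}d}" for i in range(n_parcels))


def spec_atlas(spec: ModularCovSpec, network_names: tuple[str, ...] | None = None) -> ParcelAtlas:
    """Atlas naming the spec's modules after the seven canonical networks."""
    modules = sorted(set(spec.module_assignment))
    if network_names is None:
        if len(modules) == len(SEVEN_NETWORKS):
            network_names = SEVEN_NETWORKS
        else:
            network_names = tuple(f"NET{m}" for m in modules)
    if len(network_names) != len(modules):
        raise ValueError("one network name per module required")
    name_of = dict(zip(modules, network_names))
    ids = _parcel_ids(spec.n_parcels)
    return ParcelAtlas(
        parcel_ids=ids,
        network_of={p: name_of[m] for p, m in zip(ids, spec.module_assignment)},
    )


def sample_subject_timeseries(
    spec: ModularCovSpec, seed, subject_id: str = "subject"
) -> SubjectTimeSeries:
    """Draw one subject's T x N time series from the spec's MVN model."""
    rng = np.random.default_rng(seed)
    corr = spec.correlation_matrix()
    try:
        factor = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        # PSD but singular: eigen factorization
        ev, u = np.linalg.eigh(corr)
        factor = u * np.sqrt(np.clip(ev, 0.0, None))
    x = rng.standard_normal((spec.n_timepoints, spec.n_parcels)) @ factor.T
    return SubjectTimeSeries(values=x, parcel_ids=_parcel_ids(spec.n_parcels), subject_id=subject_id)


def sample_group_dataset(design: GroupDesign):
    """Sample both groups; returns ``(controls, cases)`` lists.

    Per-subject seeds are counter-based — ``SeedSequence([master, group,
    index])`` — so adding subjects or reordering groups never perturbs
    previously generated subjects' data.
    """
    groups = []
    for g, (label, spec) in enumerate(
        [("control", design.control_spec), ("case", design.case_spec)]
    ):
        subjects = []
        for i in range(design.n_per_group):
            ss = np.random.SeedSequence([int(design.seed), g, i])
            subjects.append(
                sample_subject_timeseries(spec, ss, subject_id=f"{label}_{i:02d}")
            )
        groups.append(subjects)
    return groups[0], groups[1]


def write_dataset(
    design: GroupDesign,
    out_dir: str | Path,
    network_names: tuple[str, ...] | None = None,
    header_comment: str | None = None,
) -> Path:
    """Write a full synthetic dataset bundle as plain TSV files.

    Layout: ``timeseries/<subject>.tsv`` (header row = parcel ids),
    ``labels.tsv`` (subject_id, group), ``atlas.tsv`` (parcel_id,
    network_name).
    """
    out_dir = Path(out_dir)
    (out_dir / "timeseries").mkdir(parents=True, exist_ok=True)
    controls, cases = sample_group_dataset(design)
    rows = []
    for label, subjects in (("control", controls), ("case", cases)):
        for ts in subjects:
            write_timeseries_tsv(ts, out_dir / "timeseries" / f"{ts.subject_id}.tsv", header_comment)
            rows.append({"subject_id": ts.subject_id, "group": label})
    labels = pd.DataFrame(rows)
    with open(out_dir / "labels.tsv", "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        labels.to_csv(fh, sep="\t", index=False, lineterminator="\n")
    write_atlas_tsv(spec_atlas(design.control_spec, network_names), out_dir / "atlas.tsv", header_comment)
    return out_dir
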