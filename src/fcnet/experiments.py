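"""Validation experiments run on the synthetic generator.

These procedures characterize what the pipeline can and cannot recover
under known ground truth: a segregation-deficit design whose expected
metric directions are fixed by construction (weaker modular segregation
means fewer triangles, hence lower transitivity and clustering, and more
cross-module shortcuts, hence higher global efficiency), and a null
design where both groups share one generating distribution.
"""

from __future__ import annotations

import numpy as np

from .connectivity import compute_fc
from .graph import DEFAULT_GRID, DensityGrid
from .stats import BootstrapConfig, compare_graph_metrics, compare_networks
from .synthetic import GroupDesign, ModularCovSpec, sample_group_dataset, spec_atlas


def segregation_recovery_trial(
    seed: int,
    n_boot: int = 200,
    grid: DensityGrid = DEFAULT_GRID,
    alpha: float = 0.05,
    n_per_group: int = 15,
):
    """One case-vs-control bootstrap AUC comparison on the default design.

    Contrast direction is case - control, so a recovered segregation
    deficit shows t < 0 for transitivity/clustering and t > 0 for global
    efficiency. Returns the per-metric results dict.
    """
    design = GroupDesign.default(seed=seed, n_per_group=n_per_group)
    controls, cases = sample_group_dataset(design)
    fc_controls = [compute_fc(ts) for ts in controls]
    fc_cases = [compute_fc(ts) for ts in cases]
    cfg = BootstrapConfig(n_boot=n_boot, seed=seed, grid=grid, alpha=alpha)
    results, _ = compare_graph_metrics(fc_cases, fc_controls, cfg)
    return results


def segregation_recovery_rate(
    seeds, n_boot: int = 200, grid: DensityGrid = DEFAULT_GRID, alpha: float = 0.05
) -> float:
    """Fraction of master seeds recovering the designed effect.

    A seed counts as recovered when the case group shows significantly
    (Bonferroni-corrected) lower transitivity AND higher global
    efficiency, i.e. both signs correct and both corrected p < alpha.
    """
    hits = 0
    for seed in seeds:
        res = segregation_recovery_trial(int(seed), n_boot=n_boot, grid=grid, alpha=alpha)
        ok = (
            res["transitivity"].t < 0
            and res["transitivity"].p_corrected < alpha
            and res["global_efficiency"].t > 0
            and res["global_efficiency"].p_corrected < alpha
        )
        hits += ok
    return hits / len(list(seeds))


def network_null_trial(seed: int, alpha: float = 0.05) -> int:
    """Network-level comparison of two groups drawn from one distribution.

    Both groups use the control spec of the default design; returns the
    number of Bonferroni-significant networks (expected 0 in ~95% of
    seeds at alpha = 0.05 over seven networks).
    """
    spec = ModularCovSpec.balanced()
    design = GroupDesign(control_spec=spec, case_spec=spec, seed=seed)
    g1, g2 = sample_group_dataset(design)
    fc1 = [compute_fc(ts) for ts in g1]
    fc2 = [compute_fc(ts) for ts in g2]
    df = compare_networks(fc1, fc2, spec_atlas(spec), alpha=alpha)
    return int(df["significant"].sum())


def network_null_clean_rate(seeds, alpha: float = 0.05) -> float:
    """Fraction of seeds with zero corrected network-level rejections."""
    seeds = list(seeds)
    clean = sum(network_null_trial(int(s), alpha=alpha) == 0 for s in seeds)
    return clean / len(seeds)
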