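"""Benchmark orchestration: the package's standard evaluation experiments.

Each function generates its synthetic inputs, runs the protocol end to end
and returns plain dictionaries of measured quantities. Problem sizes are the
10-30-residue fixture suite; the relax configuration used throughout the
benchmarks caps minimizer iterations accordingly (see docs/methods.md).
"""

from __future__ import annotations

import numpy as np

from .design import DesignConfig, ShellDefinition, design, recovery_experiment
from .energy import high_energy_residues, score
from .fixtures import case_study_fixture, fixture_suite
from .pareto import aggregate, pareto_front
from .relax import RelaxConfig, fast_relax, relax_replicates
from .restraints import build_coordinate_restraints

#: restraint-width settings of the standard frontier scan, tightest first
FRONTIER_SETTINGS = (("sd=1e-06", 1e-6), ("sd=0.1", 0.1), ("sd=0.5", 0.5),
                     ("sd=2.0", 2.0), ("unrestrained", None))


def benchmark_config(seed: int = 0) -> RelaxConfig:
    """Relax configuration used by the benchmarks (mini-protein scale)."""
    return RelaxConfig(max_min_iters=80, min_tolerance=1e-2, seed=seed)


def strain_relief_benchmark(seed: int = 0, cfg: RelaxConfig | None = None,
                            threshold: float = 5.0) -> dict:
    """Restrained relax (all-atom harmonic sd = 0.5) on every defective
    fixture: total-energy change and per-residue fate of the residues flagged
    above `threshold` units on the input."""
    cfg = cfg or benchmark_config(seed)
    rows = []
    for f in fixture_suite(seed):
        if not f.defective:
            continue
        before = score(f.structure)
        rs = build_coordinate_restraints(f.structure, "all_heavy",
                                         "harmonic", 0.5)
        res = fast_relax(f.structure, rs, cfg)
        after = res.final_score
        flagged = sorted(high_energy_residues(before, threshold))
        rows.append({
            "fixture": f.name,
            "energy_before": before.total,
            "energy_after": after.total,
            "flagged": flagged,
            "flagged_before": [float(before.by_residue[i - 1]) for i in flagged],
            "flagged_after": [float(after.by_residue[i - 1]) for i in flagged],
            "rmsd_to_input": res.rmsd_to_input,
        })
    return {"rows": rows, "threshold": threshold}


def frontier_benchmark(seed: int = 0, cfg: RelaxConfig | None = None,
                       n_replicates: int = 10) -> dict:
    """The restraint-tightness scan: settings sd = 1e-6, 0.1, 0.5, 2.0 and
    unrestrained over the fixture suite, n_replicates relax replicates each,
    aggregated median-then-mean. Returns the points (in scan order), the
    Pareto front, and the mean per-fixture RMSD/energy replicate ranges."""
    cfg = cfg or benchmark_config(seed)
    suite = fixture_suite(seed)
    points, ranges = [], {}
    for label, sd in FRONTIER_SETTINGS:
        per_structure = []
        rmsd_ranges, energy_ranges = [], []
        for si, f in enumerate(suite):
            rs = None if sd is None else build_coordinate_restraints(
                f.structure, "all_heavy", "harmonic", sd)
            seeds = [seed + 7919 * si + 104729 * k for k in range(n_replicates)]
            summary = relax_replicates(f.structure, rs, cfg,
                                       n=n_replicates, seeds=seeds)
            per_structure.append(summary.results)
            rmsd_ranges.append(summary.rmsd_range)
            energy_ranges.append(summary.energy_range)
        points.append(aggregate(label, per_structure))
        ranges[label] = {"rmsd_range": float(np.mean(rmsd_ranges)),
                         "energy_range": float(np.mean(energy_ranges))}
    front = pareto_front(list(points))
    return {
        "order": [label for label, _ in FRONTIER_SETTINGS],
        "points": {p.label: p for p in points},
        "front": [p.label for p in front],
        "ranges": ranges,
    }


def convergence_contrast(frontier: dict) -> float:
    """Unrestrained-to-restrained (sd = 0.5) ratio of mean replicate RMSD
    ranges, from a frontier_benchmark result."""
    restrained = frontier["ranges"]["sd=0.5"]["rmsd_range"]
    free = frontier["ranges"]["unrestrained"]["rmsd_range"]
    return float(free / max(restrained, 1e-12))


RECOVERY_CONDITIONS = ("none", "bb+sccoord", "unrestrained")


def recovery_benchmark(seed: int = 0, cfg: RelaxConfig | None = None,
                       n_runs: int = 10) -> dict:
    """Sequence-recovery direction on the clash fixtures: no relax vs
    restrained relax (sd = 0.5) vs unrestrained relax, n_runs designs each,
    shells around the planted-clash sites."""
    cfg = cfg or benchmark_config(seed)
    suite = {f.name: f for f in fixture_suite(seed)}
    cases = [("helix_clash", [8]), ("helix30_two_clash", [8, 21])]
    per_condition: dict[str, list[float]] = {c: [] for c in RECOVERY_CONDITIONS}
    for name, site in cases:
        shell = ShellDefinition(site=site, cut_design=6.0, cut_repack=12.0)
        df = recovery_experiment(suite[name].structure,
                                 list(RECOVERY_CONDITIONS),
                                 DesignConfig(n_runs=n_runs, seed=seed),
                                 shell, cfg)
        for _, row in df.iterrows():
            per_condition[row["pretreatment"]].append(row["mean_recovery"])
    return {c: float(np.mean(v)) for c, v in per_condition.items()}


def case_study_benchmark(seed: int = 0, cfg: RelaxConfig | None = None,
                         n_runs: int = 10) -> dict:
    """The buried-pocket case: how often fixed-backbone design keeps the
    native phenylalanine, before vs after restrained relax (with constraint
    ramping, so the late stages can clear the planted pocket blocker)."""
    cfg = cfg or benchmark_config(seed)
    cs = case_study_fixture(seed)
    rs = build_coordinate_restraints(cs.structure, "all_heavy", "harmonic", 0.5)
    relax_cfg = RelaxConfig(max_min_iters=cfg.max_min_iters,
                            min_tolerance=cfg.min_tolerance,
                            seed=cfg.seed, ramp_constraints=True)
    relaxed = fast_relax(cs.structure, rs, relax_cfg).final
    shell = ShellDefinition(site=[cs.position], cut_design=5.0, cut_repack=12.0)
    out = {"position": cs.position, "native": cs.native_aa, "n_runs": n_runs}
    for label, st in (("unrelaxed", cs.structure), ("relaxed", relaxed)):
        kept = 0
        for k in range(n_runs):
            fin, _ = design(st, shell, DesignConfig(seed=seed + 31 * k),
                            rng=np.random.default_rng(seed + 500 + k))
            kept += fin.residue(cs.position).aa == cs.native_aa
        out[f"retained_{label}"] = kept
    return out
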