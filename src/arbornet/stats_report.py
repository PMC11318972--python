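"""Cohort statistics and the end-to-end analysis pipeline.

The test battery mirrors common usage for this kind of morphometry study:
Mann-Whitney U for two-group comparisons of continuous per-neuromast
metrics, one-sided two-sample Kolmogorov-Smirnov tests for distributional
shifts (node-degree heights, nodes per loop, loop lengths — the one-sided
direction must be supplied and is recorded in the output), Pearson
chi-square for loop-vs-terminal occurrence tables, Spearman rank correlation
for monotone association, and an ordinary least-squares R² for the scaled
terminal-vs-loop relation.  No multiple-testing correction is applied by
default; Benjamini-Hochberg is available as an option.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError

logger = logging.getLogger("arbornet")

__all__ = [
    "TestResult",
    "ks_one_sided",
    "chi_square",
    "spearman",
    "mann_whitney",
    "percent_reduction",
    "benjamini_hochberg",
    "run_pipeline",
]


@dataclass
class TestResult:
    test: str
    statistic: float
    p_value: float
    n: tuple
    detail: str = ""

    def __post_init__(self):
        if np.isfinite(self.p_value) and not 0.0 <= self.p_value <= 1.0 + 1e-12:
            raise ValidationError(f"p-value {self.p_value} outside [0, 1]")


def ks_one_sided(sample_a, sample_b, alternative: str = "less") -> TestResult:
    """One-sided two-sample Kolmogorov-Smirnov test.

    ``alternative="less"`` tests whether the empirical CDF of ``sample_a``
    lies below that of ``sample_b`` (i.e. ``a`` stochastically larger);
    ``"greater"`` the converse.  The exact distribution is used for small
    samples.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("KS test requires non-empty samples")
    if alternative not in ("less", "greater"):
        raise ValidationError("alternative must be 'less' or 'greater'")
    res = sps.ks_2samp(a, b, alternative=alternative, method="auto")
    return TestResult(
        test="ks_1sided",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=(len(a), len(b)),
        detail=f"alternative={alternative}",
    )


def chi_square(contingency) -> TestResult:
    """Pearson chi-square on an r x k count table (no continuity correction)."""
    table = np.asarray(contingency, dtype=float)
    if table.ndim != 2 or np.any(table < 0):
        raise ValidationError("contingency must be a 2D non-negative table")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValidationError("contingency table has an all-zero row or column")
    res = sps.chi2_contingency(table, correction=False)
    return TestResult(
        test="chi_square",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=tuple(int(x) for x in table.sum(axis=1)),
        detail=f"df={res.dof}",
    )


def spearman(x, y) -> TestResult:
    """Spearman rank correlation with average ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValidationError("spearman requires paired samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("spearman undefined for constant input")
    rho, p = sps.spearmanr(x, y)
    return TestResult(test="spearman", statistic=float(rho), p_value=float(p), n=(len(x),))


def mann_whitney(sample_a, sample_b, alternative: str = "two-sided") -> TestResult:
    """Mann-Whitney U, the default two-group comparison for continuous
    per-neuromast metrics."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("Mann-Whitney requires non-empty samples")
    res = sps.mannwhitneyu(a, b, alternative=alternative)
    return TestResult(
        test="mannwhitney",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=(len(a), len(b)),
        detail=f"alternative={alternative}",
    )


def percent_reduction(control_mean: float, test_mean: float, ndigits: int | None = 0) -> float:
    """Percent reduction of ``test_mean`` relative to ``control_mean``:
    100 (control - test) / control, rounded to ``ndigits`` (None disables)."""
    if not control_mean > 0:
        raise ValidationError("control mean must be positive")
    value = 100.0 * (control_mean - test_mean) / control_mean
    return value if ndigits is None else round(value, ndigits)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional; off by default)."""
    p = np.asarray(p_values, dtype=float)
    return sps.false_discovery_control(p, method="bh")


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

def _analyze_neuromast(cluster, trace, puncta, merge_tol, assign_cutoff):
    """All per-neuromast metrics; returns (metrics dict, features rows)."""
    from .arbor_graph import (
        build_graph,
        find_arborization_point,
        node_degree_distribution,
    )
    from .curvature import curvature_class_proportions
    from .spatial_metrics import contact_fraction
    from .synapse_mapping import assign_puncta_to_features, loop_vs_terminal_counts
    from .topology_features import (
        extract_bare_terminals,
        minimum_cycle_basis,
        relative_height,
    )

    graph = build_graph(trace, merge_tol=merge_tol)
    root = find_arborization_point(graph, trace, cluster)
    loops = minimum_cycle_basis(graph)
    terminals = extract_bare_terminals(graph)
    degrees = node_degree_distribution(graph)
    root_pos = graph.position(root)
    heights = {
        n: relative_height(graph.position(n), root_pos, cluster.apex_center)
        for n in graph.junctions
    }
    metrics = {
        "n_hair_cells": cluster.n_cells,
        "n_nodes": len(graph.junctions),
        "n_loops": len(loops),
        "n_terminals": len(terminals),
        "contact_percent": contact_fraction(trace, cluster),
    }
    for d in range(3, 8):
        metrics[f"degree_{d}"] = degrees.get(d, 0)
    if terminals:
        frac_low, frac_high = curvature_class_proportions(terminals)
        metrics["fraction_low_curvature"] = frac_low
        metrics["fraction_high_curvature"] = frac_high
    features = []
    for lp in loops:
        features.append(
            {"kind": "loop", "feature_id": lp.loop_id,
             "contour_length": lp.contour_length, "node_count": lp.node_count,
             "total_curvature": np.nan, "curvature_class": ""}
        )
    for t in terminals:
        features.append(
            {"kind": "bare_terminal", "feature_id": t.terminal_id,
             "contour_length": t.contour_length, "node_count": np.nan,
             "total_curvature": t.total_curvature,
             "curvature_class": t.curvature_class}
        )
    extras = {"heights": heights, "loops": loops, "terminals": terminals}
    if puncta is not None and len(puncta) and graph.n_edges:
        assignments = assign_puncta_to_features(
            puncta, graph, loops, terminals, cutoff=assign_cutoff
        )
        n_l, n_t, n_u = loop_vs_terminal_counts(assignments)
        metrics["puncta_on_loops"] = n_l
        metrics["puncta_on_terminals"] = n_t
        metrics["puncta_unassigned"] = n_u
        extras["assignments"] = assignments
    return metrics, features, extras


def _cohort_tests(per_genotype, ks_alternative):
    """Table-style cross-genotype test matrix from collected features."""
    from .topology_features import feature_length_occurrence

    rows = []
    genos = sorted(per_genotype)
    for i in range(len(genos)):
        for j in range(i + 1, len(genos)):
            ga, gb = genos[i], genos[j]
            A, B = per_genotype[ga], per_genotype[gb]
            pair = f"{ga} vs {gb}"

            def _try(name, fn):
                try:
                    r = fn()
                    rows.append(
                        {"comparison": pair, "quantity": name, "test": r.test,
                         "statistic": r.statistic, "p_value": r.p_value,
                         "n": str(r.n), "detail": r.detail}
                    )
                except ValidationError as exc:
                    logger.warning("%s / %s skipped: %s", pair, name, exc)

            for metric in ("n_loops", "n_terminals", "n_nodes", "contact_percent"):
                a = [m[metric] for m in A["metrics"] if metric in m]
                b = [m[metric] for m in B["metrics"] if metric in m]
                if a and b:
                    _try(metric, lambda a=a, b=b: mann_whitney(a, b))
            for q in ("node_heights", "nodes_per_loop", "loop_lengths"):
                a, b = A[q], B[q]
                if len(a) and len(b):
                    _try(q, lambda a=a, b=b: ks_one_sided(a, b, ks_alternative))
            # loop-vs-terminal occurrence per length bin
            occ_a = feature_length_occurrence(A["loops"], A["terminals"])
            occ_b = feature_length_occurrence(B["loops"], B["terminals"])
            for k in range(len(occ_a)):
                table = np.array(
                    [[occ_a["n_loops"][k], occ_a["n_terminals"][k]],
                     [occ_b["n_loops"][k], occ_b["n_terminals"][k]]]
                )
                name = f"occurrence_{occ_a['bin_lo'][k]:.0f}_{occ_a['bin_hi'][k]:.0f}um"
                _try(name, lambda t=table: chi_square(t))
            # curvature class occurrence
            ca = [t.curvature_class for t in A["terminals"]]
            cb = [t.curvature_class for t in B["terminals"]]
            if ca and cb:
                table = np.array(
                    [[ca.count("low"), ca.count("high")],
                     [cb.count("low"), cb.count("high")]]
                )
                _try("curvature_class", lambda t=table: chi_square(t))
    return pd.DataFrame(rows)


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> dict:
    """Run the full analysis over a cohort described by a config mapping.

    The config (a dict or a YAML file path) lists neuromasts either as file
    inputs (``neuromasts: [{trace, cluster, puncta, genotype, age_dpf, id}]``)
    or as synthetic cohorts
    (``synthetic: {cohorts: [{preset, n, seed_start}], ...}``), plus optional
    ``params`` (``merge_tol``, ``assign_cutoff``, ``ks_alternative``).
    Writes ``metrics.csv``, ``features.csv``, ``tests.csv`` and
    ``report.json`` to ``out_dir``; failures in one neuromast are logged and
    the rest continue.
    """
    import yaml

    from .synthetic_data import generate_neuromast, preset_config
    from .trace_io import read_cluster_json, read_puncta_csv, read_snt_csv, read_swc

    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    params = config.get("params", {})
    merge_tol = float(params.get("merge_tol", 0.5))
    assign_cutoff = float(params.get("assign_cutoff", 1.0))
    ks_alternative = str(params.get("ks_alternative", "less"))

    jobs = []  # (id, genotype, age, loader)
    for nm in config.get("neuromasts", []):
        def load(nm=nm):
            tr = nm["trace"]
            trace = read_swc(tr) if str(tr).endswith(".swc") else read_snt_csv(tr)
            cluster = read_cluster_json(nm["cluster"])
            puncta = read_puncta_csv(nm["puncta"]) if nm.get("puncta") else None
            return cluster, trace, puncta
        jobs.append(
            (nm.get("id", nm["trace"]), nm.get("genotype", "unknown"),
             nm.get("age_dpf", np.nan), load)
        )
    syn = config.get("synthetic")
    if syn:
        for cohort in syn.get("cohorts", []):
            n = int(cohort.get("n", 10))
            s0 = int(cohort.get("seed_start", 0))
            for k in range(n):
                cfg = preset_config(cohort["preset"], seed=s0 + k)

                def load(cfg=cfg):
                    cluster, trace, puncta, _ = generate_neuromast(cfg)
                    return cluster, trace, puncta
                jobs.append(
                    (f"{cohort['preset']}-{s0 + k}", cohort["preset"], 4.0, load)
                )

    metrics_rows, feature_rows = [], []
    per_genotype: dict[str, dict] = {}
    n_failed = 0
    for nm_id, genotype, age, load in jobs:
        try:
            cluster, trace, puncta = load()
            metrics, features, extras = _analyze_neuromast(
                cluster, trace, puncta, merge_tol, assign_cutoff
            )
        except Exception as exc:  # continue with the remaining neuromasts
            logger.error("neuromast %s failed: %s", nm_id, exc)
            n_failed += 1
            continue
        metrics.update({"neuromast_id": nm_id, "genotype": genotype, "age_dpf": age})
        metrics_rows.append(metrics)
        for f in features:
            feature_rows.append({**f, "neuromast_id": nm_id, "genotype": genotype})
        g = per_genotype.setdefault(
            genotype,
            {"metrics": [], "loops": [], "terminals": [],
             "node_heights": [], "nodes_per_loop": [], "loop_lengths": []},
        )
        g["metrics"].append(metrics)
        g["loops"].extend(extras["loops"])
        g["terminals"].extend(extras["terminals"])
        g["node_heights"].extend(extras["heights"].values())
        g["nodes_per_loop"].extend(lp.node_count for lp in extras["loops"])
        g["loop_lengths"].extend(lp.contour_length for lp in extras["loops"])

    if jobs and n_failed == len(jobs):
        raise ValidationError("all neuromasts failed; see log")
    if len(per_genotype) < 2:
        logger.info("fewer than two genotypes: cohort tests skipped")
        tests = pd.DataFrame()
    else:
        tests = _cohort_tests(per_genotype, ks_alternative)

    metrics_df = pd.DataFrame(metrics_rows)
    features_df = pd.DataFrame(feature_rows)
    report = {
        "params": {"merge_tol": merge_tol, "assign_cutoff": assign_cutoff,
                   "ks_alternative": ks_alternative},
        "n_neuromasts": len(metrics_rows),
        "n_failed": n_failed,
        "genotypes": {
            g: {"n": len(d["metrics"]),
                "n_loops": int(sum(m["n_loops"] for m in d["metrics"])),
                "n_terminals": int(sum(m["n_terminals"] for m in d["metrics"]))}
            for g, d in per_genotype.items()
        },
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        metrics_df.to_csv(out / "metrics.csv", index=False)
        features_df.to_csv(out / "features.csv", index=False)
        tests.to_csv(out / "tests.csv", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1)
    return {"metrics": metrics_df, "features": features_df, "tests": tests,
            "report": report}
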