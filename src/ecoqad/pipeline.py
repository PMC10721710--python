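"""End-to-end workflow: normalization -> screen -> classification ->
profiles -> coupling, with every artifact written as plain text.

Artifacts (all under the configured output directory):

* ``edges.tsv``            — directed association table (two records per pair)
* ``proportions.tsv``      — class counts/proportions per association type
* ``gtests.tsv``           — pairwise G-tests of class proportions
* ``stage_comparison.tsv`` — paired Wilcoxon early vs late stage (optional)
* ``profile_port.tsv``     — pairwise dynRB overlap (port) matrix
* ``profile_dissimilarity.tsv`` / ``profiles.nwk`` — clustering inputs/tree
* ``profile_tests.tsv``    — pairwise per-type q/m tests
* ``coupling.tsv``         — per-type coupling summary
* ``coupling_network.graphml`` / ``coupling_edges.tsv`` — directed network
* ``config.yaml`` / ``run.log`` — config echo and run log (seed, counts)

Reruns with the same config are byte-identical.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import networkx as nx
import pandas as pd

from . import coupling as cp
from . import profiles as pf
from . import screening as sc
from .config import RunConfig
from .containers import AbundanceTable
from .io import read_abundance, write_table

logger = logging.getLogger(__name__)


def run_pipeline(config: RunConfig, tbl: AbundanceTable | None = None) -> dict[str, Path]:
    """Run the full workflow; returns a name -> path map of the artifacts."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    log_lines: list[str] = []

    if tbl is None:
        tbl = read_abundance(config.values, config.variables, config.plots)
    config_yaml = config.to_yaml(outdir / "config.yaml")
    artifacts["config"] = outdir / "config.yaml"
    log_lines.append(f"seed: {config.seed}")
    log_lines.append(f"config_sha256: {hashlib.sha256(config_yaml.encode()).hexdigest()}")
    log_lines.append(f"plots: {tbl.n_plots}  variables: {tbl.n_variables}")

    # --- screening ---------------------------------------------------
    norm = sc.normalize_table(tbl, config.css_quantile)
    kept = sc.prune_variables(norm, config.min_unique)
    log_lines.append(f"variables_retained: {len(kept)}")
    screen_cfg = sc.ScreenConfig(
        min_unique=config.min_unique, min_co_occurrence=config.min_co_occurrence,
        n_perm=config.n_perm, alpha=config.alpha, seed=config.seed,
        css_quantile=config.css_quantile, use_all_plots=config.use_all_plots)
    assocs = sc.screen_all(norm, screen_cfg)
    n_sig = int((assocs["klass"] != "not-significant").sum())
    log_lines.append(f"pairs_tested: {len(assocs) // 2}")
    log_lines.append(f"directed_records: {len(assocs)}")
    log_lines.append(f"significant_records: {n_sig}")
    artifacts["edges"] = write_table(assocs, outdir / "edges.tsv")

    props, gtests = sc.proportions_by_type(assocs)
    artifacts["proportions"] = write_table(props.reset_index(), outdir / "proportions.tsv")
    artifacts["gtests"] = write_table(gtests, outdir / "gtests.tsv")

    if config.stage_split:
        early, late = sc.split_stages(norm)
        cfg_e = sc.ScreenConfig(**{**screen_cfg.__dict__, "seed": config.seed + 1})
        cfg_l = sc.ScreenConfig(**{**screen_cfg.__dict__, "seed": config.seed + 2})
        try:
            comparison = sc.compare_stages(sc.screen_all(early, cfg_e),
                                           sc.screen_all(late, cfg_l))
            artifacts["stage_comparison"] = write_table(
                comparison, outdir / "stage_comparison.tsv")
        except ValueError as exc:
            log_lines.append(f"stage_comparison_skipped: {exc}")

    # --- profiles ----------------------------------------------------
    profiles = pf.build_profiles(assocs, min_points=config.min_profile_points)
    if len(profiles) >= 2:
        names = [p.assoc_type for p in profiles]
        port = pd.DataFrame(
            [[pf.dynrb_port(a, b, config.gamma_grid) for b in profiles] for a in profiles],
            index=names, columns=names)
        artifacts["profile_port"] = write_table(
            port.rename_axis("assoc_type").reset_index(), outdir / "profile_port.tsv")
        d = pf.profile_dissimilarity(profiles, config.gamma_grid)
        artifacts["profile_dissimilarity"] = write_table(
            d.rename_axis("assoc_type").reset_index(),
            outdir / "profile_dissimilarity.tsv")
        try:
            tests, letters = pf.per_type_tests(assocs, alpha=config.alpha)
            tests["letters_q"] = tests["type_a"].map(letters["q"])
            artifacts["profile_tests"] = write_table(tests, outdir / "profile_tests.tsv")
        except ValueError as exc:
            log_lines.append(f"profile_tests_skipped: {exc}")
        if len(profiles) >= 3:
            tree = pf.cluster_profiles(profiles, n_boot=config.n_boot,
                                       seed=config.seed + 3,
                                       gamma_grid=config.gamma_grid)
            (outdir / "profiles.nwk").write_text(tree.newick + "\n")
            artifacts["dendrogram"] = outdir / "profiles.nwk"
        else:
            log_lines.append("clustering_skipped: fewer than 3 profiles")
    else:
        log_lines.append("profiles_skipped: fewer than 2 non-empty profiles")

    # --- coupling ----------------------------------------------------
    coupling_cfg = cp.CouplingConfig(
        n_perm=config.coupling_n_perm, alpha=config.alpha,
        seed=config.seed + 4, test=config.deviation_test,
        significant_only=config.significant_only)
    results = cp.coupling_analysis(norm, assocs, coupling_cfg)
    ctable = cp.coupling_table(results)
    artifacts["coupling"] = write_table(ctable, outdir / "coupling.tsv")
    sig_results = [r for r in results if r.n_significant > 0]
    if sig_results:
        G = cp.coupling_network(sig_results)
        nx.write_graphml(G, outdir / "coupling_network.graphml")
        artifacts["coupling_network"] = outdir / "coupling_network.graphml"
        edges = pd.DataFrame(
            [{"source": u, "target": v, **attrs} for u, v, attrs in G.edges(data=True)])
        artifacts["coupling_edges"] = write_table(edges, outdir / "coupling_edges.tsv")

    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    artifacts["log"] = outdir / "run.log"
    return artifacts
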