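"""Orchestrate the full coevolution scan and emit the per-site evidence table.

The scan intersects independent lines of evidence about sites coevolving
with a focal residue (122 by default): structural proximity, per-site
posterior-mean dN/dS under M8, clade-model divergent-class posteriors
(CmC vs M2a_rel), corrected mutual-information z-scores against a
randomization cutoff, and Monte-Carlo Pagel tests of correlated binary
variation.  Evidence synthesis is a join, not a combined statistic: each
line keeps its own threshold, as in qualitative multi-evidence practice.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ancestral import marginal_reconstruct, motif_report, reconstruction_table
from .codon_models import (
    LikelihoodEngine,
    fit_clade_model_C,
    fit_site_model,
    lrt,
    lrt_df,
)
from .correlated_evo import UntestableTraitError, bonferroni, pagel_mc_test
from .covariation import mi_scan
from .io_core import CodonAlignment, encode_binary_trait, read_codon_alignment
from .structure import distance_table, load_structure, neighborhood
from .trees import CladeTree


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


DEFAULTS = {
    "focal_site": 122,
    "chain": "A",
    "radius": 6.0,
    "ref_start": 1,
    "seed": 0,
    "models": {"n_beta_cat": 10, "n_starts": 2, "maxiter": 200},
    "mi": {"n_random": 150, "n_shuffles": 100, "identity_threshold": 0.62,
           "pseudocount": 0.05},
    "pagel": {"n_sim": 1000, "alpha": 0.05, "optimizer": "nm",
              "n_starts": 2, "maxiter": 300},
}


def _merged_config(config: dict) -> dict:
    cfg = {**DEFAULTS, **config}
    for key in ("models", "mi", "pagel"):
        cfg[key] = {**DEFAULTS[key], **(config.get(key) or {})}
    return cfg


def load_inputs(cfg: dict) -> tuple[CodonAlignment, CladeTree]:
    aln = read_codon_alignment(cfg["alignment"], ref_start=cfg["ref_start"])
    parts = (
        CladeTree.load_partitions_yaml(cfg["partitions"])
        if cfg.get("partitions")
        else []
    )
    tree = CladeTree.from_newick(Path(cfg["tree"]), partitions=parts)
    return aln, tree


def run_scan(config: dict, out_dir: str | Path) -> pd.DataFrame:
    """Execute every stage and return the joined per-site evidence table.

    Writes per-stage CSV intermediates plus ``evidence.csv`` and a JSON
    manifest to ``out_dir``.  Any stage failure aborts with the stage name;
    earlier outputs are retained.
    """
    cfg = _merged_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": cfg["seed"],
        "config": {k: v for k, v in cfg.items()},
        "stages": {},
    }
    focal = cfg["focal_site"]

    def _record(stage, path):
        manifest["stages"][stage] = str(path)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      default=str))

    # ---------------------------------------------------------- inputs
    try:
        aln, tree = load_inputs(cfg)
    except Exception as exc:
        raise PipelineStageError("load_inputs", exc) from exc

    # ------------------------------------------------ structure stage
    try:
        if cfg.get("structure"):
            st = load_structure(cfg["structure"])
            rmap = neighborhood(st, cfg["chain"], focal=focal,
                                radius=cfg["radius"])
            dist_df = distance_table(rmap, focal=focal)
            scan_sites = [
                s for s in dist_df["site"] if s in set(aln.ref_map)
            ]
        else:
            dist_df = pd.DataFrame(
                columns=["site", "focal", "distance_A", "within_radius",
                         "sequence_neighbor"]
            )
            scan_sites = cfg.get("sites") or [
                int(s) for s in aln.ref_map if s != focal
            ]
        dist_df.to_csv(out / "distances.csv", index=False)
        _record("structure_distance", out / "distances.csv")
    except Exception as exc:
        raise PipelineStageError("structure_distance", exc) from exc

    # ------------------------------------------------------- M8 stage
    try:
        mopts = cfg["models"]
        fit_m8 = fit_site_model(
            aln, tree, "M8",
            n_starts=mopts["n_starts"], seed=cfg["seed"],
            n_beta_cat=mopts["n_beta_cat"], maxiter=mopts["maxiter"],
        )
        m8_df = pd.DataFrame(
            {"site": aln.ref_map, "m8_mean_omega": fit_m8.site_mean_omega,
             "p_positive": fit_m8.site_posteriors[:, -1]}
        )
        m8_df.to_csv(out / "m8_site_omegas.csv", index=False)
        _record("m8", out / "m8_site_omegas.csv")
    except Exception as exc:
        raise PipelineStageError("m8", exc) from exc

    # ----------------------------------------------------- CmC stage
    try:
        if tree.partitions:
            fit_null = fit_site_model(
                aln, tree, "M2a_rel", n_starts=mopts["n_starts"],
                seed=cfg["seed"], maxiter=mopts["maxiter"],
            )
            fit_cmc = fit_clade_model_C(
                aln, tree, n_starts=mopts["n_starts"], seed=cfg["seed"],
                maxiter=mopts["maxiter"],
            )
            df = lrt_df(fit_cmc, fit_null)
            stat, p = lrt(fit_cmc, fit_null, df)
            cmc_df = pd.DataFrame(
                {"site": aln.ref_map,
                 "p_divergent": fit_cmc.site_posteriors[:, -1]}
            )
            comp = pd.DataFrame(
                [
                    {"model": "M2a_rel", "lnL": fit_null.lnL,
                     "k": fit_null.n_free_params, "aic": fit_null.aic,
                     "null": "", "p": "", "df": ""},
                    {"model": "CmC", "lnL": fit_cmc.lnL,
                     "k": fit_cmc.n_free_params, "aic": fit_cmc.aic,
                     "null": "M2a_rel", "p": p, "df": df},
                ]
            )
            comp.to_csv(out / "model_comparison.csv", index=False)
            cmc_df.to_csv(out / "cmc_site_posteriors.csv", index=False)
            _record("cmc", out / "cmc_site_posteriors.csv")
        else:
            fit_cmc = None
            cmc_df = None
    except Exception as exc:
        raise PipelineStageError("cmc", exc) from exc

    # ------------------------------------------------------ MI stage
    try:
        mi_cfg = cfg["mi"]
        mi_df = mi_scan(
            aln, focal,
            identity_threshold=mi_cfg["identity_threshold"],
            pseudocount=mi_cfg["pseudocount"],
            n_column_shuffles=mi_cfg["n_shuffles"],
            n_random=mi_cfg["n_random"],
            seed=cfg["seed"],
        )
        mi_df.to_csv(out / "mi_scan.csv", index=False)
        _record("mi", out / "mi_scan.csv")
    except Exception as exc:
        raise PipelineStageError("mi", exc) from exc

    # --------------------------------------------------- Pagel stage
    try:
        pg = cfg["pagel"]
        focal_trait = encode_binary_trait(aln, focal)
        rows = []
        for s in scan_sites:
            trait = encode_binary_trait(aln, s)
            try:
                res = pagel_mc_test(
                    tree, trait, focal_trait,
                    n_sim=pg["n_sim"], seed=cfg["seed"] + s,
                    n_starts=pg["n_starts"], maxiter=pg["maxiter"],
                    optimizer=pg["optimizer"],
                )
                rows.append(
                    {"site": s, "lnL_indep": res.lnL_indep,
                     "lnL_dep": res.lnL_dep, "lrt": res.lrt_stat,
                     "p_mc": res.p_mc, "n_sim": res.n_sim,
                     "testable": True}
                )
            except UntestableTraitError:
                rows.append(
                    {"site": s, "lnL_indep": np.nan, "lnL_dep": np.nan,
                     "lrt": np.nan, "p_mc": np.nan, "n_sim": 0,
                     "testable": False}
                )
        pagel_df = pd.DataFrame(rows)
        testable = pagel_df[pagel_df["testable"]]
        if len(testable):
            thr, calls = bonferroni(testable["p_mc"], alpha=pg["alpha"])
            pagel_df["bonferroni_threshold"] = thr
            pagel_df["m_tests"] = len(testable)
            sig = dict(zip(testable["site"], calls))
            pagel_df["significant"] = pagel_df["site"].map(sig)
        else:
            pagel_df["bonferroni_threshold"] = np.nan
            pagel_df["m_tests"] = 0
            pagel_df["significant"] = np.nan
        pagel_df.to_csv(out / "pagel.csv", index=False)
        _record("pagel", out / "pagel.csv")
    except Exception as exc:
        raise PipelineStageError("pagel", exc) from exc

    # ----------------------------------------------------------- join
    try:
        ev = pd.DataFrame({"site": scan_sites})
        if len(dist_df):
            ev = ev.merge(
                dist_df[["site", "distance_A", "sequence_neighbor"]],
                on="site", how="left",
            )
        else:
            ev["distance_A"] = np.nan
            ev["sequence_neighbor"] = False
        ev = ev.merge(m8_df, on="site", how="left")
        if cmc_df is not None:
            ev = ev.merge(cmc_df, on="site", how="left")
        ev = ev.merge(
            mi_df[["site", "z", "cutoff", "significant"]].rename(
                columns={"z": "mi_z", "cutoff": "mi_cutoff",
                         "significant": "mi_significant"}
            ),
            on="site", how="left",
        )
        ev = ev.merge(
            pagel_df[["site", "p_mc", "significant", "testable"]].rename(
                columns={"p_mc": "pagel_p_mc",
                         "significant": "pagel_significant",
                         "testable": "pagel_testable"}
            ),
            on="site", how="left",
        )
        ev.to_csv(out / "evidence.csv", index=False)
        _record("evidence", out / "evidence.csv")
    except Exception as exc:
        raise PipelineStageError("join", exc) from exc
    return ev


def report_table(evidence: pd.DataFrame) -> pd.DataFrame:
    """Deterministic column order and rounding for the evidence report.

    Distances to 0.1 Å, ω to 3 decimals, z to 1 decimal; untestable
    correlated-evolution entries print N/A.
    """
    if evidence.empty:
        cols = ["site", "distance_A", "m8_mean_omega", "p_divergent",
                "mi_z", "pagel_significant"]
        return pd.DataFrame(columns=cols)
    out = evidence.copy()
    if "distance_A" in out:
        out["distance_A"] = out["distance_A"].map(
            lambda v: round(float(v), 1) if pd.notna(v) else "N/A"
        )
    for col in ("m8_mean_omega", "p_divergent"):
        if col in out:
            out[col] = out[col].map(
                lambda v: round(float(v), 3) if pd.notna(v) else "N/A"
            )
    if "mi_z" in out:
        out["mi_z"] = out["mi_z"].map(
            lambda v: round(float(v), 1) if pd.notna(v) else "N/A"
        )
    if "pagel_testable" in out:
        out["pagel_significant"] = [
            ("Yes" if sig else "No") if testable else "N/A"
            for sig, testable in zip(
                out.get("pagel_significant", [False] * len(out)),
                out["pagel_testable"],
            )
        ]
    ordered = [
        c for c in (
            "site", "distance_A", "m8_mean_omega", "p_divergent",
            "mi_z", "mi_cutoff", "mi_significant",
            "pagel_p_mc", "pagel_significant",
        )
        if c in out.columns
    ]
    rest = [c for c in out.columns if c not in ordered]
    return out[ordered + rest]


def ancestral_stage(
    aln: CodonAlignment,
    tree: CladeTree,
    fit,
    sites=(119, 122, 123, 124),
    out_dir: str | Path | None = None,
):
    """Ancestral reconstruction at all internal nodes for the motif sites."""
    posts = marginal_reconstruct(aln, tree, fit, sites=list(sites))
    table = reconstruction_table(posts)
    motifs = motif_report(posts, sites=list(sites))
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "ancestral_codons.csv", index=False)
        motifs.to_csv(out / "ancestral_motifs.csv", index=False)
    return table, motifs
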