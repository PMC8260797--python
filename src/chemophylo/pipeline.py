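"""Config-driven end-to-end runs.

A run executes: (optional) simulate -> chemoprofile -> phylosignal ->
comparative -> olfnet -> refselect (when mapping summaries are given),
writing versioned TSV/JSON outputs plus a run log carrying the seed, the
parameters, the config hash and the package version, so reruns with the
same config are reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .chemoprofile import (
    call_sex_specific,
    call_transferred,
    pca_scores,
    profile_correlation,
    read_peak_table,
    standardize_profiles,
)
from .comparative import pgls_fit, select_model_bic
from .olfnet import (
    build_network,
    coefficient_table,
    compare_coefficients,
    self_loop_summary,
)
from .phylosignal import compare_lambda_distributions, fit_lambda_table
from .refselect import MappingSummary, rank_references
from .synthetic import SimulationConfig, simulate_peak_table, simulate_response_matrix
from .trees import Phylogeny

logger = logging.getLogger("chemophylo")


@dataclass
class RunConfig:
    """Paths and thresholds of a pipeline run."""

    out_dir: str = "chemophylo_out"
    tree: str | None = None
    peak_table: str | None = None
    response_matrix: str | None = None
    mapping_summaries: str | None = None
    simulate: bool = False
    seed: int = 0
    n_species: int = 30
    presence_frac: float = 0.5
    response_threshold: float = 10.0
    min_replicates: int = 5
    n_boot: int = 2000
    sim_overrides: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not 0.0 <= self.presence_frac <= 1.0:
            raise ValueError("presence_frac must be in [0, 1]")
        if self.response_threshold < 0:
            raise ValueError("response_threshold must be >= 0")
        for name in ("tree", "peak_table", "response_matrix",
                     "mapping_summaries"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{name} file not found: {path}")
        if not self.simulate and (self.tree is None or self.peak_table is None):
            raise ValueError(
                "without --simulate, tree and peak_table paths are required"
            )

    def content_hash(self) -> str:
        payload = json.dumps(
            {k: v for k, v in self.__dict__.items()}, sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _write_tsv(df: pd.DataFrame, path: Path, cfg_hash: str,
               index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(f"# chemophylo {__version__} config={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=index)


def run_all(cfg: RunConfig) -> dict:
    """Execute the full pipeline; returns a report dict of key results."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = cfg.content_hash()
    report: dict = {"config_hash": cfg_hash, "version": __version__,
                    "seed": cfg.seed}
    t0 = time.time()

    stage_name = "inputs"

    def stage(name):
        logger.info("stage %-10s %6.1fs", name, time.time() - t0)

    try:
        # -- inputs -----------------------------------------------------
        if cfg.simulate:
            sim = SimulationConfig(seed=cfg.seed, n_species=cfg.n_species,
                                   **cfg.sim_overrides)
            pt, truth = simulate_peak_table(sim)
            tree = truth["tree"]
            rm, _ = simulate_response_matrix(truth, sim)
            tree.write(out / "tree.nwk")
            pt.to_csv(out / "peak_table.tsv", sep="\t", index=False)
            rm.to_csv(out / "response_matrix.tsv", sep="\t", index=False)
        else:
            tree = Phylogeny.from_file(cfg.tree)
            pt = read_peak_table(cfg.peak_table)
            rm = (pd.read_csv(cfg.response_matrix, sep="\t")
                  if cfg.response_matrix else None)
        stage("inputs")
        stage_name = "profiles"

        # -- chemoprofile ------------------------------------------------
        catalog = call_sex_specific(pt, presence_frac=cfg.presence_frac)
        if (pt["mating"] == "mated").any():
            catalog = call_transferred(pt, catalog,
                                       presence_frac=cfg.presence_frac)
        tms = {}
        for sex in ("male", "female"):
            sub = pt[(pt["sex"] == sex) & (pt["mating"] == "virgin")]
            tm = standardize_profiles(sub, level="species_mean")
            tms[sex] = tm
            _write_tsv(tm, out / f"traits_{sex}.tsv", cfg_hash)
            _write_tsv(profile_correlation(tm),
                       out / f"correlation_{sex}.tsv", cfg_hash)
            k = min(2, min(tm.shape) - 1)
            if k >= 1:
                scores, evr = pca_scores(tm, k)
                scores["explained_var"] = [
                    ";".join(f"{v:.4f}" for v in evr)
                ] * len(scores)
                _write_tsv(scores, out / f"pca_{sex}.tsv", cfg_hash)
        spec_summary = catalog.specificity.value_counts().to_dict()
        report["compound_calls"] = {str(k): int(v)
                                    for k, v in spec_summary.items()}
        report["n_dimorphic"] = len(catalog.dimorphic_species)
        report["n_monomorphic"] = len(catalog.monomorphic_species)
        if catalog.transferred is not None:
            report["n_transferred"] = int(catalog.transferred.sum())
        stage("profiles")
        stage_name = "signal"

        # -- phylosignal -------------------------------------------------
        lam_tables = {}
        for sex, tm in tms.items():
            lt = fit_lambda_table(tm, tree)
            lam_tables[sex] = lt
            _write_tsv(lt, out / f"lambda_{sex}.tsv", cfg_hash, index=False)
        comparison = compare_lambda_distributions(
            lam_tables["male"]["lambda_hat"],
            lam_tables["female"]["lambda_hat"],
        )
        report["lambda_sex_comparison"] = {
            "statistic": comparison.statistic, "p_value": comparison.p_value,
            "method": comparison.method,
            "mean_lambda_male": float(lam_tables["male"]["lambda_hat"].mean()),
            "mean_lambda_female": float(
                lam_tables["female"]["lambda_hat"].mean()),
        }
        stage("signal")
        stage_name = "regress"

        # -- comparative: production vs detection ------------------------
        if rm is not None and catalog.male_specific:
            male_tm = tms["male"]
            resp = (rm.groupby("detector", observed=True)["mean_response"]
                    .mean().rename("mean_response"))
            common = [s for s in male_tm.index if s in resp.index]
            covers_tree = set(common) == set(tree.tip_labels)
            if not covers_tree:
                logger.info("PGLS skipped: response matrix does not cover "
                            "all tree tips")
            if len(male_tm.columns) and covers_tree and len(common) > 2:
                y = male_tm.loc[common].mean(axis=1)
                X = resp.loc[common].to_frame()
                X = (X - X.mean()) / X.std(ddof=0)
                fits = [pgls_fit(y, X, tree, model=m)
                        for m in ("OLS_star", "BM", "lambda_ML")]
                best = select_model_bic(fits)
                report["pgls"] = {
                    "selected_model": best.model,
                    "coef": dict(zip(best.coef_names_,
                                     map(float, best.coef_))),
                    "bic": {f.model: float(f.bic_) for f in fits},
                    "p_values": dict(zip(best.coef_names_,
                                         map(float, best.pvalues_))),
                }
        stage("regress")
        stage_name = "network"

        # -- olfnet ------------------------------------------------------
        if rm is not None:
            net = build_network(catalog, rm,
                                threshold=cfg.response_threshold)
            _write_tsv(net.edge_list(), out / "network_edges.tsv", cfg_hash,
                       index=False)
            _write_tsv(coefficient_table(net),
                       out / "clustering_coefficients.tsv", cfg_hash)
            loops = self_loop_summary(net)
            _write_tsv(loops, out / "self_loops.tsv", cfg_hash)
            comp = compare_coefficients(net)
            report["network"] = {
                "n_edges": int(net.graph.number_of_edges()),
                "self_loop_totals": loops.attrs["totals"],
                "at1_vs_at4": {"statistic": comp.statistic,
                               "p_value": comp.p_value},
            }
        stage("network")
        stage_name = "refselect"

        # -- refselect ---------------------------------------------------
        if cfg.mapping_summaries:
            ms = pd.read_csv(cfg.mapping_summaries, sep="\t")
            summaries = [
                MappingSummary(str(r["reference"]), float(r["completeness"]),
                               float(r["p_proper"]), float(r["mean_mapq"]))
                for _, r in ms.iterrows()
            ]
            ranking = rank_references(summaries)
            _write_tsv(ranking, out / "reference_ranking.tsv", cfg_hash,
                       index=False)
            report["chosen_reference"] = str(ranking["reference"].iloc[0])
        stage("refselect")
    except Exception as exc:
        raise RuntimeError(
            f"pipeline failed at stage {stage_name!r}: {exc}"
        ) from exc

    with open(out / "run_log.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report
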