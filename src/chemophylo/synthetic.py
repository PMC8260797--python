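"""Seeded generators for every input the pipeline consumes.

The generators emulate the structure of a comparative chemo-ecology study
of drosophilid cuticular chemistry: a species phylogeny, replicate-level
GC-MS peak tables for both sexes (with sex-specific and mating-transferred
compounds), single-sensillum response matrices for two trichoid sensillum
classes, two-choice behavioral counts, and per-reference mapping
summaries.  Ground truth is returned alongside each dataset so recovery
can be tested end to end.

Default study conditions follow the emulated design: 99 species, ~250
chemical features per sex, 6 replicates per species-sex (the study used
more than five), male-specific compounds at roughly the observed fraction
(43 of 248 features), a smaller female-specific fraction (9 of 256),
supra-threshold neuronal responses uniform on 25–125 spikes/s and
sub-threshold noise on [0, 10] spikes/s so the exclusion rule is exercised
at its boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trees import (
    Phylogeny,
    _leaf_label,
    lambda_transform_matrix,
    parse_newick,
)

__all__ = [
    "SimulationConfig",
    "simulate_tree",
    "simulate_bm_traits",
    "simulate_mk_presence",
    "simulate_peak_table",
    "simulate_response_matrix",
]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the emulated conditions."""

    seed: int = 0
    n_species: int = 99
    birth_rate: float = 1.0
    # phylogenetic signal of (log) chemical abundances per trait class:
    # male profiles carry strong signal, female profiles weak
    lambda_true: dict = field(
        default_factory=lambda: {"male": 0.8, "female": 0.2}
    )
    sigma2_true: float = 1.0
    n_features: dict = field(
        default_factory=lambda: {"male": 248, "female": 256}
    )
    frac_sex_specific: dict = field(
        default_factory=lambda: {"male": 43 / 248, "female": 9 / 256}
    )
    transfer_prob: float = 0.5
    n_replicates: int = 6
    peak_noise_cv: float = 0.3
    detect_intra_prob: float = 0.75
    detect_inter_prob: float = 0.15
    response_range: tuple = (25.0, 125.0)
    response_threshold: float = 10.0
    mk_gain_rate: float = 0.5
    mk_loss_rate: float = 1.5

    def validate(self) -> None:
        probs = [self.transfer_prob, self.detect_intra_prob,
                 self.detect_inter_prob] + list(self.frac_sex_specific.values())
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if any(not 0.0 <= l <= 1.0 for l in self.lambda_true.values()):
            raise ValueError("lambda_true values must lie in [0, 1]")
        if self.n_replicates < 5:
            raise ValueError("need >= 5 replicates per species-sex")
        if self.birth_rate <= 0:
            raise ValueError("birth_rate must be > 0")
        if self.n_species < 2:
            raise ValueError("need >= 2 species")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(seed)


def simulate_tree(n_tips: int, birth_rate: float = 1.0, seed=None) -> Phylogeny:
    """Yule (pure-birth) tree with exponential waiting times.

    Starting from two lineages, the waiting time to the next split with k
    extant lineages is Exponential(k·birth_rate) and the splitting lineage
    is uniform.  Branch lengths are in expected time units (1/birth_rate).
    """
    if n_tips < 2:
        raise ValueError("a tree needs >= 2 tips")
    rng = _rng(seed)
    next_id = [0]

    def leaf():
        next_id[0] += 1
        return {"name": f"sp{next_id[0]:03d}", "children": [], "age": 0.0}

    root = {"name": None, "children": [leaf(), leaf()], "age": 0.0}
    active = list(root["children"])
    elapsed = 0.0
    pending = {id(n): 0.0 for n in active}  # birth time of each active tip
    while len(active) < n_tips:
        k = len(active)
        elapsed += rng.exponential(1.0 / (k * birth_rate))
        i = rng.integers(k)
        node = active[i]
        node["children"] = [leaf(), leaf()]
        node["name"] = None
        node["length"] = elapsed - pending.pop(id(node))
        for c in node["children"]:
            pending[id(c)] = elapsed
        active[i] = node["children"][0]
        active.append(node["children"][1])
    elapsed += rng.exponential(1.0 / (len(active) * birth_rate))
    for tip in active:
        tip["length"] = elapsed - pending[id(tip)]

    def newick(node):
        if not node["children"]:
            return f"{node['name']}:{node.get('length', 0.0):.10f}"
        inner = ",".join(newick(c) for c in node["children"])
        return f"({inner}):{node.get('length', 0.0):.10f}"

    text = "(" + ",".join(newick(c) for c in root["children"]) + ");"
    return parse_newick(text)


def simulate_bm_traits(
    tree, lam: float, sigma2: float = 1.0, mu: float = 0.0,
    n_traits: int = 1, seed=None,
) -> pd.DataFrame:
    """Traits from N(μ·1, σ²·C(λ)) on the tree; species × trait frame."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    rng = _rng(seed)
    cov = tree.covariance() if isinstance(tree, Phylogeny) else tree
    V = sigma2 * lambda_transform_matrix(cov.matrix, lam)
    n = cov.n
    if sigma2 == 0:
        draws = np.full((n, n_traits), mu)
    else:
        L = np.linalg.cholesky(V + 1e-12 * np.trace(V) / n * np.eye(n))
        draws = mu + L @ rng.standard_normal((n, n_traits))
    return pd.DataFrame(
        draws, index=list(cov.labels),
        columns=[f"trait{j + 1}" for j in range(n_traits)],
    )


def simulate_mk_presence(
    tree, gain_rate: float, loss_rate: float,
    root_state: int = 0, n_compounds: int = 1, seed=None,
) -> pd.DataFrame:
    """Binary presence via a two-state Markov chain along branches.

    Transition probabilities over a branch of length t follow the closed
    form of the 2-state chain with rates (gain, loss): with total rate
    q = gain + loss and stationary presence π = gain/q,

        P(1 | start 0) = π (1 − e^{−qt}),
        P(1 | start 1) = π + (1 − π) e^{−qt}.

    Returns a species × compound 0/1 DataFrame.
    """
    if gain_rate < 0 or loss_rate < 0:
        raise ValueError("rates must be >= 0")
    rng = _rng(seed)
    q = gain_rate + loss_rate
    pi1 = gain_rate / q if q > 0 else float(root_state)

    dtree = tree._tree
    labels = tree.tip_labels
    out = {}
    state: dict[int, np.ndarray] = {}
    for node in dtree.preorder_node_iter():
        if node.parent_node is None:
            state[id(node)] = np.full(n_compounds, root_state, dtype=int)
            continue
        parent = state[id(node.parent_node)]
        t = node.edge.length or 0.0
        decay = np.exp(-q * t) if q > 0 else 1.0
        p1 = np.where(parent == 1, pi1 + (1 - pi1) * decay, pi1 * (1 - decay))
        state[id(node)] = (rng.random(n_compounds) < p1).astype(int)
        if node.is_leaf():
            out[_leaf_label(node)] = state[id(node)]
    return pd.DataFrame(
        out, index=[f"c{j + 1}" for j in range(n_compounds)]
    ).T.reindex(list(labels))


def simulate_peak_table(cfg: SimulationConfig, tree=None):
    """Replicate-level peak table plus ground truth.

    Species-level (log-scale) abundances of shared features evolve under
    λ-Brownian motion per sex (strong male, weak female signal by
    default).  Sex-specific compounds get patchy producing-species sets
    from the Mk model; transferred male-specific compounds also appear on
    mated females of producing species.  Replicate areas are log-normal
    around the species mean with coefficient of variation
    ``peak_noise_cv``.

    Returns
    -------
    (PeakTable DataFrame, truth dict) — truth holds per-compound
    specificity, producing species, transfer flags, and the simulated λ.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    if tree is None:
        tree = simulate_tree(cfg.n_species, cfg.birth_rate, rng)
    labels = list(tree.tip_labels)
    cov = tree.covariance()
    n_sp, n_rep = len(labels), cfg.n_replicates
    sigma_log = np.sqrt(np.log1p(cfg.peak_noise_cv**2))

    def noisy(means, shape):
        """Log-normal multiplicative noise with mean 1 around `means`."""
        if sigma_log == 0:
            return np.broadcast_to(means, shape).copy()
        return means * np.exp(
            rng.normal(-0.5 * sigma_log**2, sigma_log, size=shape)
        )

    def melt(areas, features, sex, mating, rep_tag, mask=None):
        """Turn a (n_rep, n_sp, n_feat) area array into long records.

        `mask` (n_sp, n_feat) marks which species carry which feature."""
        n_feat = len(features)
        if n_feat == 0:
            return pd.DataFrame(
                columns=["species", "sex", "mating", "replicate", "feature",
                         "area"]
            )
        reps, sp, ft = np.meshgrid(
            np.arange(n_rep), np.arange(n_sp), np.arange(n_feat),
            indexing="ij",
        )
        keep = np.ones_like(areas, dtype=bool) if mask is None \
            else np.broadcast_to(mask[None, :, :], areas.shape)
        sp_f, rep_f, ft_f = sp[keep], reps[keep], ft[keep]
        lab = np.asarray(labels)
        feat = np.asarray(features)
        return pd.DataFrame({
            "species": lab[sp_f],
            "sex": sex,
            "mating": mating,
            "replicate": [f"{lab[s]}_{rep_tag}{r + 1}"
                          for s, r in zip(sp_f, rep_f)],
            "feature": feat[ft_f],
            "area": areas[keep],
        })

    truth = {"lambda_true": dict(cfg.lambda_true), "specificity": {},
             "producing_species": {}, "transferred": {}}
    blocks = []
    sex_data = {}

    # one common pool of shared compounds, present in both sexes; its size
    # is set so each sex's total feature count stays near the configured one
    n_spec_by_sex = {
        s: int(round(cfg.frac_sex_specific[s] * cfg.n_features[s]))
        for s in ("male", "female")
    }
    n_shared = min(cfg.n_features[s] - n_spec_by_sex[s]
                   for s in ("male", "female"))
    feat_shared = [f"shared{j + 1}" for j in range(n_shared)]

    for sex in ("male", "female"):
        n_spec = n_spec_by_sex[sex]
        feat_spec = [f"{sex[0]}_spec{j + 1}" for j in range(n_spec)]

        # per-sex abundance of the common compounds evolves with the sex's
        # own phylogenetic signal (strong in males, weak in females)
        base = simulate_bm_traits(
            cov, cfg.lambda_true[sex], cfg.sigma2_true, mu=3.0,
            n_traits=n_shared, seed=rng,
        )
        mean_shared = np.exp(np.asarray(base))  # log-scale BM -> areas

        if n_spec:
            presence = simulate_mk_presence(
                tree, cfg.mk_gain_rate, cfg.mk_loss_rate, root_state=0,
                n_compounds=n_spec, seed=rng,
            )
            presence.columns = feat_spec
            for f in feat_spec:  # every compound needs >= 1 producer
                if presence[f].sum() == 0:
                    presence.loc[labels[rng.integers(n_sp)], f] = 1
            pres = np.asarray(presence.reindex(labels), dtype=bool)
        else:
            pres = np.zeros((n_sp, 0), dtype=bool)
        mean_spec = np.exp(rng.normal(3.0, 1.0, size=(n_sp, n_spec)))

        for j, f in enumerate(feat_spec):
            producers = frozenset(np.asarray(labels)[pres[:, j]])
            truth["specificity"][f] = f"{sex}_specific"
            truth["producing_species"][f] = producers
            if sex == "male":
                truth["transferred"][f] = bool(
                    rng.random() < cfg.transfer_prob
                )

        tag = "mv" if sex == "male" else "fv"
        shape_shared = (n_rep, n_sp, n_shared)
        shape_spec = (n_rep, n_sp, n_spec)
        blocks.append(melt(noisy(mean_shared[None], shape_shared),
                           feat_shared, sex, "virgin", tag))
        blocks.append(melt(noisy(mean_spec[None], shape_spec),
                           feat_spec, sex, "virgin", tag, mask=pres))
        sex_data[sex] = (mean_shared, feat_spec, mean_spec, pres)

    # mated females: their own profile plus transferred male compounds
    mean_shared_f, feat_spec_f, mean_spec_f, pres_f = sex_data["female"]
    blocks.append(melt(noisy(mean_shared_f[None], (n_rep, n_sp, n_shared)),
                       feat_shared, "female", "mated", "fm"))
    blocks.append(melt(noisy(mean_spec_f[None], (n_rep, n_sp,
                                                 len(feat_spec_f))),
                       feat_spec_f, "female", "mated", "fm", mask=pres_f))
    _, feat_spec_m, mean_spec_m, pres_m = sex_data["male"]
    transferred_mask = np.array(
        [truth["transferred"].get(f, False) for f in feat_spec_m], dtype=bool
    )
    transfer_pres = pres_m & transferred_mask[None, :]
    blocks.append(melt(
        noisy(mean_spec_m[None], (n_rep, n_sp, len(feat_spec_m))),
        feat_spec_m, "female", "mated", "fm", mask=transfer_pres,
    ))

    pt = pd.concat([b for b in blocks if not b.empty], ignore_index=True)
    truth["dimorphic_species"] = sorted(
        {s for producers in truth["producing_species"].values()
         for s in producers}
    )
    truth["monomorphic_species"] = sorted(
        set(labels) - set(truth["dimorphic_species"])
    )
    truth["tree"] = tree
    return pt, truth


def simulate_response_matrix(catalog_or_truth, cfg: SimulationConfig, seed=None):
    """Single-sensillum response matrix plus the ground-truth edge set.

    For every (detector species, male-specific compound, sensillum) a true
    detection occurs with probability ``detect_intra_prob`` when the
    detector produces the compound and ``detect_inter_prob`` otherwise.
    Detections draw mean responses uniform on ``response_range``;
    non-detections draw sub-threshold noise uniform on
    [0, response_threshold] so the exclusion rule is exercised at its
    boundary.  Recording counts are uniform on 3–10.

    `catalog_or_truth` may be a CompoundCatalog or the truth dict from
    :func:`simulate_peak_table`.

    Returns (ResponseMatrix DataFrame, truth edge DataFrame with columns
    detector, producer, sensillum).
    """
    cfg.validate()
    rng = _rng(cfg.seed if seed is None else seed)
    if isinstance(catalog_or_truth, dict):
        producing = {
            f: catalog_or_truth["producing_species"][f]
            for f, s in catalog_or_truth["specificity"].items()
            if s == "male_specific"
        }
        species = sorted(
            set(catalog_or_truth["dimorphic_species"])
            | set(catalog_or_truth["monomorphic_species"])
        )
    else:
        producing = {
            f: catalog_or_truth.producing_species[f]
            for f in catalog_or_truth.male_specific
        }
        species = sorted(
            set(catalog_or_truth.dimorphic_species)
            | set(catalog_or_truth.monomorphic_species)
        )

    lo, hi = cfg.response_range
    rows, edges = [], set()
    for detector in species:
        for compound, producers in sorted(producing.items()):
            intra = detector in producers
            p = cfg.detect_intra_prob if intra else cfg.detect_inter_prob
            for sensillum in ("at1", "at4"):
                detected = rng.random() < p
                if detected:
                    resp = float(rng.uniform(lo, hi))
                    for producer in producers:
                        edges.add((detector, producer, sensillum))
                else:
                    resp = float(rng.uniform(0.0, cfg.response_threshold))
                rows.append(
                    (detector, compound, sensillum, resp,
                     int(rng.integers(3, 11)))
                )
    rm = pd.DataFrame(
        rows,
        columns=["detector", "compound", "sensillum", "mean_response", "n"],
    )
    truth_edges = pd.DataFrame(
        sorted(edges), columns=["detector", "producer", "sensillum"]
    )
    return rm, truth_edges
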