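"""Synthetic trees, traits and yawn events with the statistical structure
the analysis assumes.

The generator produces (i) a pure-birth (Yule) tree rescaled to unit
root-to-tip height; (ii) correlated log body / log brain mass evolving by
Brownian motion on that tree; (iii) log neuron counts allometrically tied
to log brain mass with i.i.d. noise; and (iv) per-individual yawn
durations that are Gamma-distributed around a species mean whose log is a
linear function of a standardized brain measure plus a phylogenetically
correlated intercept (MVN with covariance sigma_phylo^2 * C_lambda) and an
i.i.d. species intercept.

Because the per-yawn Gamma shares the species-level mean, the species
average of m yawns is again Gamma with shape ``m * alpha`` and the same
mean, so the species-mean model fitted downstream is exactly the
generative model for aggregated data.

Default parameter values are the reference conditions the recovery
suites exercise: 50 species, slope 0.35 per SD of log brain mass, intercept
log(3.4) log-seconds, sigma_phylo = 0.2, sigma_species = 0.1, Gamma shape
20, lambda = 1.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .exceptions import DomainError, InputError
from .io_data import YawnEvent, write_events
from .phylo_core import chol_with_jitter, lambda_transform, phylo_cov

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_tree",
    "simulate_bm_traits",
    "simulate_neurons",
    "simulate_yawns",
    "assign_orders",
    "generate_dataset",
    "write_dataset",
]


def default_evo_cov(var_body: float = 4.0, var_brain: float = 2.0, corr: float = 0.95):
    """2x2 evolutionary covariance for (log body, log brain) per unit branch."""
    off = corr * math.sqrt(var_body * var_brain)
    return np.array([[var_body, off], [off, var_brain]])


@dataclass
class SimulationConfig:
    """Generative parameters for a synthetic clade.

    ``beta0``/``beta`` are the log-seconds intercept and the slope per SD
    of the standardized predictor; ``sigma_phylo``/``sigma_species`` are
    random-effect SDs on the link scale; ``shape`` is the per-yawn Gamma
    shape; ``lambda_sim`` scales the off-diagonal of the unit-height
    phylogenetic correlation matrix exactly as in estimation.
    """

    n_species: int = 50
    birth_rate: float = 1.0
    trait_root: tuple = (8.0, 3.0)  # log body mass (g), log brain mass (g)
    evo_cov: np.ndarray = field(default_factory=default_evo_cov)
    neuron_slope: float = 0.75
    neuron_intercept: float = 17.75
    neuron_noise_sd: float = 0.3
    beta0: float = math.log(3.4)
    beta: float = 0.35
    sigma_phylo: float = 0.2
    sigma_species: float = 0.1
    shape: float = 20.0
    lambda_sim: float = 1.0
    individuals_per_species: int = 6
    yawns_per_individual: int = 2
    n_orders: int = 5
    sigma_slope: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self.evo_cov = np.asarray(self.evo_cov, dtype=float)
        if not (self.shape > 0):
            raise DomainError("Gamma shape must be positive")
        if not (0.0 <= self.lambda_sim <= 1.0):
            raise DomainError("lambda_sim must lie in [0, 1]")
        w = np.linalg.eigvalsh(0.5 * (self.evo_cov + self.evo_cov.T))
        if w.min() < -1e-10 or not np.allclose(self.evo_cov, self.evo_cov.T):
            raise DomainError("evo_cov must be symmetric positive semi-definite")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["evo_cov"] = np.asarray(self.evo_cov).tolist()
        d["trait_root"] = list(self.trait_root)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f for f in cls.__dataclass_fields__}
        bad = set(d) - known
        if bad:
            raise InputError(f"unknown simulation config fields: {sorted(bad)}")
        d = dict(d)
        if "evo_cov" in d:
            d["evo_cov"] = np.asarray(d["evo_cov"], dtype=float)
        if "trait_root" in d:
            d["trait_root"] = tuple(d["trait_root"])
        return cls(**d)


def simulate_tree(n_species: int, birth_rate: float = 1.0, seed: int = 0) -> dendropy.Tree:
    """Pure-birth (Yule) tree with ``n_species`` tips, rescaled to unit
    root-to-tip height.  Tips are labeled sp001, sp002, ... in leaf order.
    Deterministic given ``seed``."""
    if n_species < 4:
        raise InputError("at least 4 species are required")
    rng = random.Random(int(seed))
    tree = treesim.birth_death_tree(
        birth_rate=float(birth_rate),
        death_rate=0.0,
        num_extant_tips=int(n_species),
        rng=rng,
        repeat_until_success=True,
    )
    # the simulator stops exactly at the n-th birth, leaving the newest
    # tip pair with zero-length branches (a singular covariance); extend
    # every tip by the waiting time to the next unrealized speciation,
    # which is the proper Yule snapshot between the n-th and (n+1)-th
    # birth events
    extra = rng.expovariate(n_species * float(birth_rate))
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    height = max(lf.root_distance for lf in tree.leaf_node_iter())
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length / height
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"sp{i + 1:03d}"
    return tree


def _psd_factor(M: np.ndarray) -> np.ndarray:
    """A factor F with F @ F.T = M for symmetric PSD M (eigen-based, so
    exactly-singular matrices such as the zero matrix are handled)."""
    w, V = np.linalg.eigh(0.5 * (M + M.T))
    if w.min() < -1e-10:
        raise DomainError("matrix is not positive semi-definite")
    return V * np.sqrt(np.clip(w, 0.0, None))


def simulate_bm_traits(
    tree: dendropy.Tree,
    trait_root,
    evo_cov,
    seed: int = 0,
    columns: tuple = ("log_body", "log_brain"),
) -> pd.DataFrame:
    """Correlated Brownian-motion traits on a tree.

    Tip values are drawn from a matrix normal with row covariance equal to
    the tree's phylogenetic covariance and column covariance ``evo_cov``
    (per unit branch length), centred at ``trait_root``.
    """
    cov = phylo_cov(tree)
    evo_cov = np.asarray(evo_cov, dtype=float)
    root = np.asarray(trait_root, dtype=float)
    k = len(root)
    if evo_cov.shape != (k, k):
        raise InputError("evo_cov shape must match trait_root length")
    Fc = _psd_factor(cov.matrix)
    Ft = _psd_factor(evo_cov)
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((cov.n, k))
    vals = root + Fc @ Z @ Ft.T
    return pd.DataFrame(vals, index=cov.tip_order, columns=list(columns)[:k])


def simulate_neurons(
    log_brain, slope: float, intercept: float, noise_sd: float, seed: int = 0
) -> np.ndarray:
    """Allometric log neuron counts: intercept + slope * log_brain + noise."""
    if noise_sd < 0:
        raise DomainError("noise_sd must be non-negative")
    log_brain = np.asarray(log_brain, dtype=float)
    rng = np.random.default_rng(seed)
    return intercept + slope * log_brain + noise_sd * rng.standard_normal(log_brain.shape)


def assign_orders(tree: dendropy.Tree, n_orders: int) -> pd.Series:
    """Partition tips into ``n_orders`` monophyletic groups.

    Repeatedly splits the largest current group at its root node, so the
    groups are the clades below the earliest splits of the tree; labels
    are ord1, ord2, ... by leaf order.
    """
    groups = [tree.seed_node]
    def nleaves(nd):
        return sum(1 for _ in nd.leaf_iter())
    while len(groups) < n_orders:
        cand = [g for g in groups if g.child_nodes()]
        if not cand:
            break
        big = max(cand, key=nleaves)
        groups.remove(big)
        groups.extend(big.child_nodes())
    tips = [lf.taxon.label for lf in tree.leaf_node_iter()]
    pos = {t: i for i, t in enumerate(tips)}
    label_of = {}
    ordered = sorted(
        groups, key=lambda g: min(pos[lf.taxon.label] for lf in g.leaf_iter())
    )
    for k, g in enumerate(ordered):
        for lf in g.leaf_iter():
            label_of[lf.taxon.label] = f"ord{k + 1}"
    return pd.Series([label_of[t] for t in tips], index=tips, name="order")


def simulate_yawns(
    tree: dendropy.Tree,
    z_predictor,
    config: SimulationConfig,
    return_latent: bool = False,
):
    """Per-individual yawn events from the generative multilevel model.

    Species latent: eta_i = beta0 + beta_i * z_i + b_i + u_i with
    b ~ MVN(0, sigma_phylo^2 * C_lambda) on the unit-height tree and
    u_i ~ N(0, sigma_species^2) i.i.d.  When ``sigma_slope`` > 0, species
    in taxonomic order k share a slope deviation so that
    beta_i = beta + sigma_slope * delta_k, delta_k ~ N(0, 1).  Each yawn
    is Gamma with mean exp(eta_i) and shape ``config.shape``.
    """
    cov = phylo_cov(tree, scale_to_unit_height=True)
    z = np.asarray(z_predictor, dtype=float)
    if len(z) != cov.n:
        raise InputError(
            f"z_predictor length {len(z)} does not match tree tip count {cov.n}"
        )
    rng = np.random.default_rng(config.seed)
    Cl = lambda_transform(cov.matrix, config.lambda_sim)
    L = chol_with_jitter(Cl + 1e-12 * np.eye(cov.n))
    b = config.sigma_phylo * (L @ rng.standard_normal(cov.n))
    u = config.sigma_species * rng.standard_normal(cov.n)

    beta_i = np.full(cov.n, config.beta)
    orders = assign_orders(tree, config.n_orders)
    if config.sigma_slope > 0:
        uniq = sorted(orders.unique())
        delta = {o: config.sigma_slope * rng.standard_normal() for o in uniq}
        beta_i = beta_i + np.array([delta[orders[t]] for t in cov.tip_order])

    eta = config.beta0 + beta_i * z + b + u
    mu = np.exp(eta)

    events: list[YawnEvent] = []
    for i, sp in enumerate(cov.tip_order):
        for ind in range(config.individuals_per_species):
            durs = rng.gamma(
                shape=config.shape,
                scale=mu[i] / config.shape,
                size=config.yawns_per_individual,
            )
            for d in durs:
                events.append(
                    YawnEvent(sp, f"{sp}_ind{ind + 1}", float(d), "synthetic")
                )
    if return_latent:
        latent = pd.DataFrame(
            {"eta": eta, "b": b, "u": u, "beta_i": beta_i, "order": orders.values,
             "z": z},
            index=cov.tip_order,
        )
        return events, latent
    return events


@dataclass
class SyntheticDataset:
    """A complete synthetic clade: tree, trait records, events and truth."""

    tree: dendropy.Tree
    records: pd.DataFrame
    events: list
    truth: dict
    latent: pd.DataFrame


def generate_dataset(
    config: SimulationConfig, clade: str = "mammal"
) -> SyntheticDataset:
    """Simulate a full clade dataset driven by standardized log brain mass.

    Stages (each with a seed spawned from ``config.seed``): Yule tree ->
    bivariate Brownian body/brain mass -> allometric neuron counts ->
    Gamma yawn events around the species latent mean.
    """
    ss = np.random.SeedSequence(config.seed)
    s_tree, s_bm, s_neu, s_cx, s_yawn = [
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(5)
    ]
    tree = simulate_tree(config.n_species, config.birth_rate, seed=s_tree)
    traits = simulate_bm_traits(tree, config.trait_root, config.evo_cov, seed=s_bm)
    log_neu = simulate_neurons(
        traits["log_brain"].values, config.neuron_slope, config.neuron_intercept,
        config.neuron_noise_sd, seed=s_neu,
    )
    # cortical/pallial counts: a fixed fraction of total with its own noise
    rng_cx = np.random.default_rng(s_cx)
    log_cx = log_neu + math.log(0.4) + 0.1 * rng_cx.standard_normal(len(log_neu))

    lb = traits["log_brain"].values
    z = (lb - lb.mean()) / lb.std(ddof=1)
    cfg_yawn = SimulationConfig(**{**config.to_dict(), "seed": s_yawn})
    events, latent = simulate_yawns(tree, z, cfg_yawn, return_latent=True)

    orders = assign_orders(tree, config.n_orders)
    records = pd.DataFrame(
        {
            "species": traits.index,
            "clade": clade,
            "order": orders.values,
            "body_mass": np.exp(traits["log_body"].values),
            "brain_mass": np.exp(traits["log_brain"].values),
            "ecv": np.nan,
            "total_neurons": np.round(np.exp(log_neu)),
            "cortex_pallium_neurons": np.round(np.exp(log_cx)),
        }
    )
    truth = {"config": config.to_dict(), "clade": clade, "stage_seeds": {
        "tree": s_tree, "bm": s_bm, "neurons": s_neu, "cortex": s_cx, "yawns": s_yawn}}
    return SyntheticDataset(tree=tree, records=records, events=events, truth=truth,
                            latent=latent)


def write_dataset(ds: SyntheticDataset, outdir) -> dict:
    """Write events CSV, traits CSV, tree Newick and truth JSON; returns paths."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "events": out / "events.csv",
        "traits": out / "traits.csv",
        "tree": out / "tree.nwk",
        "truth": out / "truth.json",
    }
    write_events(ds.events, paths["events"])
    ds.records.to_csv(paths["traits"], index=False)
    ds.tree.write(path=str(paths["tree"]), schema="newick")
    with open(paths["truth"], "w") as fh:
        json.dump(ds.truth, fh, indent=2)
    return {k: str(v) for k, v in paths.items()}
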