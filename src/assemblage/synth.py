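"""Synthetic communities with known assembly processes.

Generates birth-death trees, Brownian niche traits, a stations-by-layers
sampling design, and OTU count tables assembled under tunable mixtures of
environmental selection, dispersal limitation, homogenizing dispersal and
drift — so that every downstream inference can be checked against ground
truth.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from dendropy.simulate import treesim
from skbio import TreeNode

from .errors import ConsistencyError
from .io import (DEPTH_LAYERS, EARTH_RADIUS_KM, OtuTable, SampleMetadata)

LAYER_DEPTHS_M = {"surface": 5.0, "DCM": 35.0, "bottom": 75.0}


@dataclass
class SyntheticDesign:
    """Sampling design: stations x depth layers x replicates."""

    n_stations: int = 4
    n_layers: int = 3
    n_replicates_per_cell: int = 7
    station_coords: list[tuple[float, float]] = field(default_factory=lambda: [
        (22.0, 114.5), (21.4, 115.0), (20.5, 115.6), (18.0, 116.0)])
    env_gradient: np.ndarray | None = None  # (n_stations, n_layers)
    env_noise_sd: float = 0.1
    read_depth: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_stations < 1 or self.n_layers < 1 or self.n_replicates_per_cell < 1:
            raise ValueError("design dimensions must be positive")
        if not 1 <= self.n_layers <= len(DEPTH_LAYERS):
            raise ValueError(f"n_layers must be in [1, {len(DEPTH_LAYERS)}]")
        if len(self.station_coords) < self.n_stations:
            raise ValueError("need coordinates for every station")
        if self.read_depth <= 0:
            raise ValueError("read_depth must be positive")
        if self.env_gradient is None:
            # temperature-like: warms offshore at surface, cools with depth
            base = np.linspace(24.0, 29.0, self.n_stations)
            self.env_gradient = np.stack(
                [base - 3.0 * k for k in range(self.n_layers)], axis=1)
        self.env_gradient = np.asarray(self.env_gradient, dtype=float)
        if self.env_gradient.shape != (self.n_stations, self.n_layers):
            raise ValueError("env_gradient must be (n_stations, n_layers)")

    @property
    def n_samples(self) -> int:
        return self.n_stations * self.n_layers * self.n_replicates_per_cell


@dataclass
class AssemblyScenario:
    """Knobs realizing the four assembly processes.

    selection_strength   inverse squared width of the Gaussian trait filter
    dispersal_kernel_scale  e-folding distance (km) of between-station mixing
    migration_rate_m     per-sample immigration rate in (0, 1]
    drift_only           ignore everything else: pure multinomial resampling
    pool_concentration   Dirichlet concentration of station pools around the
                         metacommunity; small values -> divergent pools
    """

    selection_strength: float = 0.0
    dispersal_kernel_scale: float = 1e9
    migration_rate_m: float = 1.0
    drift_only: bool = False
    pool_concentration: float = 1e6

    def __post_init__(self) -> None:
        if not np.isfinite(self.selection_strength) or self.selection_strength < 0:
            raise ValueError("selection_strength must be finite and >= 0")
        if not self.dispersal_kernel_scale > 0:
            raise ValueError("dispersal_kernel_scale must be > 0")
        if not 0 < self.migration_rate_m <= 1:
            raise ValueError("migration_rate_m must be in (0, 1]")
        if not self.pool_concentration > 0:
            raise ValueError("pool_concentration must be > 0")


@dataclass
class SyntheticDataset:
    otu_table: OtuTable
    tree: TreeNode
    traits: pd.Series
    metadata: SampleMetadata
    truth: AssemblyScenario

    def __post_init__(self) -> None:
        tips = {t.name for t in self.tree.tips()}
        if not set(self.otu_table.otu_ids) <= tips:
            raise ConsistencyError("tree tips must cover all table OTUs")
        if not set(self.otu_table.otu_ids) <= set(self.traits.index):
            raise ConsistencyError("traits must cover all table OTUs")

    def write(self, outdir, prefix: str = "synthetic") -> None:
        import os
        os.makedirs(outdir, exist_ok=True)
        self.otu_table.to_tsv(os.path.join(outdir, f"{prefix}_otu_table.tsv"))
        self.otu_table.to_biom(os.path.join(outdir, f"{prefix}_otu_table.biom"))
        self.tree.write(os.path.join(outdir, f"{prefix}_tree.nwk"))
        self.metadata.to_tsv(os.path.join(outdir, f"{prefix}_metadata.tsv"))
        self.traits.rename("trait").to_csv(
            os.path.join(outdir, f"{prefix}_traits.tsv"), sep="\t",
            index_label="otu_id")
        with open(os.path.join(outdir, f"{prefix}_truth.json"), "w") as fh:
            json.dump(asdict(self.truth), fh, indent=2)


def simulate_tree(n_taxa: int, seed: int, birth_rate: float = 1.0,
                  death_rate: float = 0.0) -> TreeNode:
    """Simulate a rooted birth-death (default Yule) tree with ``n_taxa`` tips.

    Tips are relabelled ``t1..tN`` in a deterministic traversal order so the
    newick string is reproducible for a fixed seed.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    rng = random.Random(seed)
    dtree = treesim.birth_death_tree(
        birth_rate=birth_rate, death_rate=death_rate,
        num_extant_tips=n_taxa, rng=rng)
    dtree.suppress_unifurcations()
    newick = dtree.as_string(schema="newick", suppress_rooting=True)
    tree = TreeNode.read([newick])
    for i, tip in enumerate(tree.tips(), start=1):
        tip.name = f"t{i}"
    for node in tree.traverse():
        if node.length is None:
            node.length = 0.0
    return tree


def patristic_distances(tree: TreeNode) -> pd.DataFrame:
    """Tip-to-tip path-length distance matrix as a labelled DataFrame."""
    dm = tree.tip_tip_distances()
    return pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))


def evolve_traits(tree: TreeNode, sigma2: float, seed: int,
                  root_value: float = 0.0) -> pd.Series:
    """Evolve a single continuous trait along the tree by Brownian motion.

    Each branch adds a Normal(0, sigma2 * branch_length) increment; tip
    values therefore have covariance sigma2 x shared branch length.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    rng = np.random.default_rng(seed)
    values: dict[int, float] = {id(tree): root_value}
    tips = {}
    for node in tree.preorder(include_self=False):
        parent_val = values[id(node.parent)]
        bl = node.length or 0.0
        step = rng.normal(0.0, np.sqrt(sigma2 * bl)) if sigma2 * bl > 0 else 0.0
        values[id(node)] = parent_val + step
        if node.is_tip():
            tips[node.name] = values[id(node)]
    return pd.Series(tips, name="trait")


def simulate_metadata(design: SyntheticDesign) -> SampleMetadata:
    """One metadata row per sample of the design.

    Temperature follows the design's env gradient plus Gaussian noise;
    salinity / dissolved oxygen / bacterial abundance are noisy affine
    transforms of it, giving realistically collinear covariates.
    """
    rng = np.random.default_rng(design.seed)
    rows = []
    half = design.n_stations / 2.0
    for s in range(design.n_stations):
        lat, lon = design.station_coords[s]
        habitat = "nearshore" if s < half else "offshore"
        for k in range(design.n_layers):
            layer = DEPTH_LAYERS[k]
            env = design.env_gradient[s, k]
            for r in range(design.n_replicates_per_cell):
                temp = env + rng.normal(0.0, design.env_noise_sd)
                rows.append({
                    "sample_id": f"S{s + 1}_{layer}_r{r + 1}",
                    "station": f"ST{s + 1}",
                    "habitat_class": habitat,
                    "layer": layer,
                    "latitude": lat,
                    "longitude": lon,
                    "depth": LAYER_DEPTHS_M[layer],
                    "temperature": temp,
                    "salinity": 34.0 - 0.1 * (temp - 25.0)
                                + rng.normal(0.0, 0.05),
                    "dissolved_oxygen": 7.5 - 0.12 * (temp - 25.0)
                                        + rng.normal(0.0, 0.05),
                    "bacterial_abundance": 1e6 * np.exp(
                        0.08 * (temp - 25.0) + rng.normal(0.0, 0.1)),
                })
    df = pd.DataFrame(rows).set_index("sample_id")
    return SampleMetadata(df)


def metacommunity_proportions(n_otus: int, seed: int,
                              sigma: float = 1.5) -> np.ndarray:
    """Log-normal (mu=0) regional relative abundances, normalised to 1."""
    rng = np.random.default_rng(seed)
    w = rng.lognormal(0.0, sigma, size=n_otus)
    return w / w.sum()


def _station_distance_km(design: SyntheticDesign) -> np.ndarray:
    coords = np.asarray(design.station_coords[:design.n_stations], dtype=float)
    phi = np.radians(coords[:, 0])
    lam = np.radians(coords[:, 1])
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    a = (np.sin(dphi / 2) ** 2
         + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2) ** 2)
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def assemble_communities(tree: TreeNode, traits: pd.Series,
                         metadata: SampleMetadata,
                         scenario: AssemblyScenario, seed: int,
                         read_depth: int = 2000,
                         design: SyntheticDesign | None = None,
                         metacommunity: np.ndarray | None = None) -> OtuTable:
    """Draw one multinomial community per metadata row.

    Sampling weights per sample are
    ``station-pool mixture x exp(-selection_strength * (trait - env)^2)``,
    where station pools are Dirichlet draws around the metacommunity
    (divergent when ``pool_concentration`` is small) and pools are mixed
    across stations within a depth layer with kernel
    ``exp(-distance / dispersal_kernel_scale)``. ``drift_only`` bypasses all
    structure and resamples the metacommunity multinomially.
    """
    otu_ids = list(traits.index)
    tips = {t.name for t in tree.tips()}
    if not set(otu_ids) <= tips:
        raise ConsistencyError("traits index must be a subset of tree tips")
    n_otus = len(otu_ids)
    rng = np.random.default_rng(seed)
    if metacommunity is None:
        metacommunity = metacommunity_proportions(n_otus, seed=seed + 1)
    metacommunity = np.asarray(metacommunity, dtype=float)
    if metacommunity.shape != (n_otus,):
        raise ConsistencyError("metacommunity length must match traits")

    meta = metadata.data
    stations = sorted(meta["station"].unique())
    layers = sorted(meta["layer"].unique())
    st_index = {s: i for i, s in enumerate(stations)}

    if scenario.drift_only:
        counts = rng.multinomial(read_depth, metacommunity,
                                 size=len(meta))
        df = pd.DataFrame(counts, index=meta.index, columns=otu_ids)
        return OtuTable(df)

    # per (station, layer) pool around the metacommunity
    pools: dict[tuple[str, str], np.ndarray] = {}
    for st in stations:
        for ly in layers:
            alpha = scenario.pool_concentration * metacommunity
            pool = rng.gamma(np.maximum(alpha, 1e-12))
            pools[(st, ly)] = pool / pool.sum()

    # mix pools across stations within each layer (layers stay stratified)
    if design is not None:
        dist_km = _station_distance_km(design)
    else:
        sub = meta.drop_duplicates("station").set_index("station").loc[stations]
        coords = list(zip(sub["latitude"], sub["longitude"]))
        pseudo = SyntheticDesign(n_stations=len(stations), n_layers=1,
                                 n_replicates_per_cell=1,
                                 station_coords=coords, read_depth=1)
        dist_km = _station_distance_km(pseudo)
    kernel = np.exp(-dist_km / scenario.dispersal_kernel_scale)
    kernel = kernel / kernel.sum(axis=1, keepdims=True)
    mixed: dict[tuple[str, str], np.ndarray] = {}
    for ly in layers:
        pool_mat = np.stack([pools[(st, ly)] for st in stations])
        mix = kernel @ pool_mat
        for st in stations:
            mixed[(st, ly)] = mix[st_index[st]]

    trait_vals = traits.loc[otu_ids].to_numpy(dtype=float)
    env = metadata.numeric("temperature")
    m = scenario.migration_rate_m
    out = np.zeros((len(meta), n_otus), dtype=np.int64)
    for i, (sid, row) in enumerate(meta.iterrows()):
        pool = mixed[(row["station"], row["layer"])]
        # immigration below 1 shrinks the effective pool toward a local
        # stochastic realisation (more drift)
        if m < 1.0:
            local = rng.gamma(np.maximum(m * read_depth * pool, 1e-12))
            pool = local / local.sum()
        w = pool * np.exp(-scenario.selection_strength
                          * (trait_vals - env.loc[sid]) ** 2)
        total = w.sum()
        if total <= 0:
            w = pool
            total = w.sum()
        out[i] = rng.multinomial(read_depth, w / total)
    return OtuTable(pd.DataFrame(out, index=meta.index, columns=otu_ids))


def simulate_neutral_metacommunity(Nm: float, source_proportions,
                                   n_samples: int, read_depth: int,
                                   seed: int) -> OtuTable:
    """Sloan-neutral samples: Dirichlet(Nm * p) composition, multinomial reads.

    This is the exact generative model assumed by the neutral-model fit, so
    it serves as the parameter-recovery oracle.
    """
    if Nm <= 0:
        raise ValueError("Nm must be > 0")
    p = np.asarray(source_proportions, dtype=float)
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("source proportions must sum to 1")
    rng = np.random.default_rng(seed)
    n_otus = len(p)
    counts = np.zeros((n_samples, n_otus), dtype=np.int64)
    alpha = Nm * p
    pos = alpha > 0
    for i in range(n_samples):
        pi = np.zeros(n_otus)
        g = rng.gamma(alpha[pos])
        if g.sum() == 0:
            g = np.ones(pos.sum())
        pi[pos] = g / g.sum()
        counts[i] = rng.multinomial(read_depth, pi)
    sample_ids = [f"N{i + 1}" for i in range(n_samples)]
    otu_ids = [f"t{j + 1}" for j in range(n_otus)]
    return OtuTable(pd.DataFrame(counts, index=sample_ids, columns=otu_ids))


def match_traits_to_env(traits: pd.Series, env_values) -> pd.Series:
    """Affinely rescale traits to the mean/spread of an environmental variable
    so that the Gaussian filter has bite; rank order is preserved."""
    env = np.asarray(env_values, dtype=float)
    t = traits.to_numpy(dtype=float)
    t_sd = t.std()
    if t_sd == 0:
        return pd.Series(np.full_like(t, env.mean()), index=traits.index)
    scaled = (t - t.mean()) / t_sd * max(env.std(), 1e-12) + env.mean()
    return pd.Series(scaled, index=traits.index, name=traits.name)


def simulate_dataset(design: SyntheticDesign, scenario: AssemblyScenario,
                     n_taxa: int = 200, sigma2: float = 1.0, seed: int = 0,
                     meta_sigma: float = 1.5) -> SyntheticDataset:
    """End-to-end generator: tree + traits + metadata + assembled table."""
    tree = simulate_tree(n_taxa, seed=seed)
    traits = evolve_traits(tree, sigma2=sigma2, seed=seed + 17)
    metadata = simulate_metadata(design)
    traits = match_traits_to_env(traits, metadata.numeric("temperature"))
    metacommunity = metacommunity_proportions(n_taxa, seed=seed + 7,
                                              sigma=meta_sigma)
    table = assemble_communities(tree, traits, metadata, scenario,
                                 seed=seed + 31, read_depth=design.read_depth,
                                 design=design, metacommunity=metacommunity)
    return SyntheticDataset(table, tree, traits, metadata, scenario)
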