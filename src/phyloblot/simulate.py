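"""Synthetic data with the statistical structure the analysis assumes.

Two generators are combined to emulate a cross-species blot study:

* correlated Brownian-motion (BM) evolution of log traits on a phylogeny —
  the generative model under which independent contrasts are exact — giving
  each species a true log protein level and log life-history trait values;
* a measurement layer that packs replicate lanes onto gels of fixed
  capacity, inserts a reference-species lane on every gel (the cross-gel
  loading control), and applies multiplicative lognormal lane noise,
  per-gel scale effects and loading-control variation.

The packaged rodent fixture ships the 16-species life-history table
(maximum lifespan in years, adult body mass in grams, per-organ replicate
counts) together with a literature-consistent binary topology for these
taxa. The topology is an approximation assembled from published rodent
phylogenies; it is a test fixture, not a reconstruction of any particular
study's tree.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import dendropy

from .phylo import leaf_labels, parse_newick, set_equal_branch_lengths

__all__ = [
    "BMParameters",
    "NoiseModel",
    "DEFAULT_LEVEL_RATE",
    "DEFAULT_LIFESPAN_RATE",
    "DEFAULT_MASS_RATE",
    "NONREACTIVE_SPECIES",
    "DEFAULT_ANALYSIS_EXCLUSIONS",
    "simulate_bm_traits",
    "simulate_blot_measurements",
    "simulate_rodent_study",
    "rodent_fixture",
    "random_binary_tree",
]

# BM rates (log10-trait-units^2 per unit branch length) chosen to match the
# observed spread of the real study system under unit branch lengths:
# roughly a 10-fold range of brain protein levels across species, lifespans
# spanning 3-31 years, and body masses spanning 20 g - 55 kg.
DEFAULT_LEVEL_RATE = 0.06
DEFAULT_LIFESPAN_RATE = 0.02
DEFAULT_MASS_RATE = 0.25

#: Species whose samples did not react with the target antibody and are
#: excluded from analysis by default.
NONREACTIVE_SPECIES = "Nannospalax_ehrenbergi"

#: 16-taxon fixture minus the non-reactive species and the one species with
#: incomplete organ coverage; the resulting 14-taxon subtree is the default
#: simulation testbed.
DEFAULT_ANALYSIS_EXCLUSIONS = (NONREACTIVE_SPECIES, "Meriones_unguiculatus")


@dataclass(frozen=True)
class BMParameters:
    """Bivariate Brownian-motion parameters for trait evolution.

    ``rate_matrix`` is the 2x2 symmetric positive-semidefinite matrix of
    evolutionary (co)variance accrued per unit branch length, in squared
    log-trait units; ``root_state`` is the ancestral log-trait vector.
    """

    rate_matrix: np.ndarray
    root_state: np.ndarray
    seed: int = 0

    def __post_init__(self):
        R = np.asarray(self.rate_matrix, dtype=float)
        if R.shape != (2, 2):
            raise ValueError(f"rate matrix must be 2x2, got shape {R.shape}")
        if not np.allclose(R, R.T):
            raise ValueError("rate matrix must be symmetric")
        if np.min(np.linalg.eigvalsh(R)) < -1e-12:
            raise ValueError("rate matrix must be positive semidefinite")
        object.__setattr__(self, "rate_matrix", R)
        object.__setattr__(
            self, "root_state", np.asarray(self.root_state, dtype=float)
        )

    @classmethod
    def from_correlation(
        cls,
        correlation: float,
        rate_1: float = DEFAULT_LEVEL_RATE,
        rate_2: float = DEFAULT_LIFESPAN_RATE,
        root_state: Sequence[float] = (0.5, 1.0),
        seed: int = 0,
    ) -> "BMParameters":
        """Build parameters from an evolutionary correlation and two rates."""
        if not -1.0 <= correlation <= 1.0:
            raise ValueError(f"correlation must be in [-1, 1], got {correlation}")
        cov = correlation * np.sqrt(rate_1 * rate_2)
        return cls(
            rate_matrix=np.array([[rate_1, cov], [cov, rate_2]]),
            root_state=np.asarray(root_state, dtype=float),
            seed=seed,
        )


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative measurement noise for simulated blot lanes.

    ``lane_cv``: coefficient of variation of per-lane lognormal noise;
    ``gel_scale_sd``: SD of the per-gel log-scale effect (differences in
    transfer efficiency, exposure, scan brightness); ``actin_cv``: CV of
    the loading-control band. Defaults keep the cross-gel adjustment small,
    as observed in practice. All parameters dimensionless and >= 0.
    """

    lane_cv: float = 0.2
    gel_scale_sd: float = 0.1
    actin_cv: float = 0.1

    def __post_init__(self):
        if min(self.lane_cv, self.gel_scale_sd, self.actin_cv) < 0:
            raise ValueError("noise parameters must be non-negative")


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=size)


def simulate_bm_traits(
    tree: dendropy.Tree,
    params: BMParameters,
    trait_names: tuple[str, str] = ("log_level", "log_lifespan"),
) -> pd.DataFrame:
    """Simulate two correlated traits under Brownian motion on a tree.

    Starting from ``root_state`` at the root, each branch adds a bivariate
    normal increment with covariance ``rate_matrix`` x branch length.
    Returns a DataFrame indexed by species with one column per trait.
    Seeded-deterministic via ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    R = params.rate_matrix
    # Cholesky-like factor; eigendecomposition tolerates the PSD boundary.
    evals, evecs = np.linalg.eigh(R)
    L = evecs @ np.diag(np.sqrt(np.clip(evals, 0, None)))

    states: dict[int, np.ndarray] = {}
    rows = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            states[id(node)] = params.root_state.copy()
        else:
            bl = node.edge.length
            if bl is None or bl < 0:
                raise ValueError("tree branches need non-negative lengths for BM")
            z = rng.standard_normal(2)
            states[id(node)] = states[id(node.parent_node)] + np.sqrt(bl) * (L @ z)
        if node.is_leaf():
            rows[node.taxon.label] = states[id(node)]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(trait_names))
    df.index.name = "species"
    return df


def simulate_blot_measurements(
    true_levels: Mapping[str, float],
    replicate_counts: Mapping[str, int],
    gel_capacity: int = 10,
    reference_species: str = "Mus_musculus",
    organ: str = "brain",
    noise: NoiseModel | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate lane-level gel measurements for known true protein levels.

    Replicate lanes are packed first-fit in species order onto gels of
    ``gel_capacity`` lanes; every gel carries one extra reference-species
    lane (flagged ``is_reference``) in lane 1, emulating the design where a
    control sample is run on every gel. Lane target intensity is
    true level x gel effect x lane noise x control level, with the
    loading-control intensity reported alongside. With all noise terms zero
    the densitometry pipeline recovers ``true_levels`` exactly.
    """
    if gel_capacity < 2:
        raise ValueError("gel capacity must be >= 2 (reference + sample lane)")
    if reference_species not in true_levels:
        raise ValueError(f"no true level for reference species {reference_species!r}")
    for sp, lvl in true_levels.items():
        if not lvl > 0:
            raise ValueError(f"true level for {sp!r} must be positive, got {lvl}")
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)

    sample_lanes = [
        sp
        for sp in true_levels
        for _ in range(int(replicate_counts.get(sp, 0)))
    ]
    per_gel = gel_capacity - 1
    n_gels = max(1, -(-len(sample_lanes) // per_gel))

    records = []
    for g in range(n_gels):
        gel_id = f"gel{g + 1:02d}"
        gel_species = [reference_species] + sample_lanes[g * per_gel : (g + 1) * per_gel]
        k = len(gel_species)
        gel_effect = float(np.exp(rng.normal(0.0, noise.gel_scale_sd)))
        lane_noise = _lognormal_factor(rng, noise.lane_cv, k)
        actin = _lognormal_factor(rng, noise.actin_cv, k)
        for lane_idx, sp in enumerate(gel_species):
            records.append(
                {
                    "gel_id": gel_id,
                    "lane": lane_idx + 1,
                    "species": sp,
                    "organ": organ,
                    "target_intensity": true_levels[sp]
                    * gel_effect
                    * lane_noise[lane_idx]
                    * actin[lane_idx],
                    "control_intensity": actin[lane_idx],
                    "is_reference": lane_idx == 0,
                }
            )
    return pd.DataFrame.from_records(records)


def simulate_rodent_study(
    tree: dendropy.Tree,
    correlation: float,
    seed: int,
    replicate_counts: Mapping[str, int] | None = None,
    noise: NoiseModel | None = None,
    reference_species: str = "Mus_musculus",
    organ: str = "brain",
    level_rate: float = DEFAULT_LEVEL_RATE,
    lifespan_rate: float = DEFAULT_LIFESPAN_RATE,
    mass_rate: float = DEFAULT_MASS_RATE,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One full synthetic study: traits on a tree plus blot measurements.

    Log protein level and log lifespan evolve under correlated BM with the
    given evolutionary ``correlation``; log body mass evolves under an
    independent BM (the mass-lifespan association is left to the tree's
    shared history). Returns ``(measurements, traits)`` in exactly the
    formats the analysis pipeline reads: a lane-level measurement table and
    a species table with ``max_lifespan_yr`` and ``body_mass_g``.
    """
    params = BMParameters.from_correlation(
        correlation, rate_1=level_rate, rate_2=lifespan_rate, seed=seed
    )
    traits2 = simulate_bm_traits(tree, params)
    mass_params = BMParameters(
        rate_matrix=np.array([[mass_rate, 0.0], [0.0, mass_rate]]),
        root_state=np.array([2.7, 2.7]),
        seed=seed + 1_000_003,
    )
    log_mass = simulate_bm_traits(tree, mass_params, ("log_mass", "_unused"))["log_mass"]

    species = list(traits2.index)
    true_levels = {sp: float(10.0 ** traits2.loc[sp, "log_level"]) for sp in species}
    if replicate_counts is None:
        replicate_counts = {sp: 2 for sp in species}
    measurements = simulate_blot_measurements(
        true_levels,
        replicate_counts,
        reference_species=reference_species,
        organ=organ,
        noise=noise,
        seed=seed + 2_000_003,
    )
    traits = pd.DataFrame(
        {
            "species": species,
            "max_lifespan_yr": 10.0 ** traits2["log_lifespan"].to_numpy(),
            "body_mass_g": 10.0 ** log_mass.loc[species].to_numpy(),
        }
    )
    return measurements, traits


def rodent_fixture(
    equal_branch_length: float | None = 1.0,
) -> tuple[pd.DataFrame, dendropy.Tree]:
    """The packaged 16-species rodent table and reference topology.

    The trait table carries maximum lifespan (years), adult body mass (g)
    and per-organ replicate counts; the tree is a literature-consistent
    binary topology for the same 16 taxa with equal branch lengths applied
    by default (pass ``equal_branch_length=None`` to get the bare topology).
    """
    root = importlib.resources.files("phyloblot.data")
    traits = pd.read_csv(str(root / "rodent_traits.csv"))
    tree = parse_newick((root / "rodent_tree.nwk").read_text())
    if equal_branch_length is not None:
        tree = set_equal_branch_lengths(tree, equal_branch_length)
    assert set(traits["species"]) == set(leaf_labels(tree))
    return traits, tree


def random_binary_tree(
    n_leaves: int,
    seed: int | np.random.Generator = 0,
    length_range: tuple[float, float] = (0.1, 2.0),
) -> dendropy.Tree:
    """A random rooted binary tree with uniform random branch lengths.

    Built by repeatedly splitting a random leaf (a Yule-like growth
    process); intended for property tests and oracle comparisons.
    """
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = length_range

    def bl() -> float:
        return float(rng.uniform(lo, hi))

    taxon_namespace = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_namespace)
    labels = [f"t{i + 1}" for i in range(n_leaves)]

    left = dendropy.Node(edge_length=bl())
    right = dendropy.Node(edge_length=bl())
    tree.seed_node.add_child(left)
    tree.seed_node.add_child(right)
    leaves = [left, right]
    for _ in range(n_leaves - 2):
        victim = leaves.pop(int(rng.integers(len(leaves))))
        a = dendropy.Node(edge_length=bl())
        b = dendropy.Node(edge_length=bl())
        victim.add_child(a)
        victim.add_child(b)
        leaves.extend([a, b])
    order = rng.permutation(n_leaves)
    for node, i in zip(leaves, order):
        node.taxon = taxon_namespace.new_taxon(label=labels[int(i)])
    return tree
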