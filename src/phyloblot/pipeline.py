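"""End-to-end study orchestration.

Runs, per organ: lane normalization -> cross-gel rescaling -> species
summaries -> exclusions -> log transform -> normality checks -> raw simple
and multiple regressions of protein level on lifespan and body mass ->
tree pruning and independent-contrast regressions. Emits a report that is
serializable to JSON and reproducible bit-for-bit for a fixed config,
inputs and seed.

Species labels are matched by exact string after trimming and
underscore/space unification; there is no fuzzy matching — a silent misjoin
is worse than a hard error. Species dropped at any stage (excluded,
non-positive level, missing traits, absent from the tree) are listed in the
report with the reason.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import dendropy

from . import densitometry as dens
from . import phylo
from . import stats as st

__all__ = ["StudyConfig", "OrganResult", "StudyReport", "run_study", "run_study_files"]

MIN_SPECIES_FOR_MODELS = 4


def canonical_label(label: str) -> str:
    """Trim and unify spaces to underscores; the only normalization applied."""
    return "_".join(str(label).strip().split())


@dataclass(frozen=True)
class StudyConfig:
    """Analysis-wide settings for one study run."""

    organs: tuple[str, ...] = ("brain", "lung", "heart", "kidney")
    reference_species: str = "Mus_musculus"
    exclude: tuple[str, ...] = ()
    log_base: float = 10.0
    branch_lengths: str = "equal"  # "equal" | "as_given"
    equal_length: float = 1.0
    n_bins: int = 5
    binning: str = "equal_probability"
    seed: int = 0
    strict_tree: bool = False

    def __post_init__(self):
        if self.branch_lengths not in ("equal", "as_given"):
            raise ValueError(f"branch_lengths must be 'equal' or 'as_given'")
        object.__setattr__(self, "organs", tuple(self.organs))
        object.__setattr__(
            self, "exclude", tuple(canonical_label(s) for s in self.exclude)
        )
        object.__setattr__(
            self, "reference_species", canonical_label(self.reference_species)
        )


@dataclass
class OrganResult:
    """All statistics for one organ, or an explicit refusal."""

    organ: str
    species_used: list[str] = field(default_factory=list)
    n_species: int = 0
    species_table: pd.DataFrame | None = None
    normality: dict = field(default_factory=dict)
    regression_lifespan: st.RegressionResult | None = None
    regression_mass: st.RegressionResult | None = None
    multiple_regression: st.MultiRegressionResult | None = None
    pic_lifespan: st.RegressionResult | None = None
    pic_mass: st.RegressionResult | None = None
    pic_species: list[str] = field(default_factory=list)
    dropped: list[dict] = field(default_factory=list)
    refusals: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def maybe(x):
            return x.to_dict() if x is not None else None

        return {
            "organ": self.organ,
            "species_used": self.species_used,
            "n_species": self.n_species,
            "species_table": (
                self.species_table.to_dict(orient="records")
                if self.species_table is not None
                else None
            ),
            "normality": {k: maybe(v) for k, v in self.normality.items()},
            "regression_lifespan": maybe(self.regression_lifespan),
            "regression_mass": maybe(self.regression_mass),
            "multiple_regression": maybe(self.multiple_regression),
            "pic_lifespan": maybe(self.pic_lifespan),
            "pic_mass": maybe(self.pic_mass),
            "pic_species": self.pic_species,
            "dropped": self.dropped,
            "refusals": self.refusals,
        }


@dataclass
class StudyReport:
    """Per-organ results plus a provenance echo of the configuration."""

    config: StudyConfig
    organs: dict[str, OrganResult]
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "config": asdict(self.config),
            "organs": {k: v.to_dict() for k, v in self.organs.items()},
            "notes": self.notes,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)


def _canonicalize_inputs(
    measurements: pd.DataFrame, traits: pd.DataFrame, tree: dendropy.Tree
) -> tuple[pd.DataFrame, pd.DataFrame, dendropy.Tree]:
    m = measurements.copy()
    t = traits.copy()
    m["species"] = m["species"].map(canonical_label)
    t["species"] = t["species"].map(canonical_label)
    tree = tree.clone(depth=1)
    for leaf in tree.leaf_node_iter():
        leaf.taxon.label = canonical_label(leaf.taxon.label)
    return m, t, tree


def run_study(
    measurements: pd.DataFrame,
    traits: pd.DataFrame,
    tree: dendropy.Tree,
    config: StudyConfig | None = None,
) -> StudyReport:
    """Execute the full comparative analysis for every configured organ.

    ``measurements``: lane table with gel_id, lane, species, organ,
    target_intensity, control_intensity. ``traits``: species table with
    max_lifespan_yr and body_mass_g. ``tree``: phylogeny whose leaf labels
    match the species labels (after space/underscore unification).
    """
    config = config or StudyConfig()
    for col in ("species", "max_lifespan_yr", "body_mass_g"):
        if col not in traits.columns:
            raise ValueError(f"trait table lacks column {col!r}")
    measurements, traits, tree = _canonicalize_inputs(measurements, traits, tree)
    traits = traits.set_index("species")
    if config.reference_species not in set(measurements["species"]):
        raise ValueError(
            f"reference species {config.reference_species!r} not in measurement table"
        )

    normalized = dens.actin_normalize(measurements)
    report = StudyReport(
        config=config,
        organs={},
        notes=[
            "No multiple-testing correction is applied across organs; "
            "p-values are reported raw."
        ],
    )
    for organ in config.organs:
        report.organs[organ] = _run_organ(normalized, traits, tree, config, organ)
    return report


def _run_organ(
    normalized: pd.DataFrame,
    traits: pd.DataFrame,
    tree: dendropy.Tree,
    config: StudyConfig,
    organ: str,
) -> OrganResult:
    res = OrganResult(organ=organ)
    lanes = normalized[normalized["organ"] == organ]
    if not len(lanes):
        res.refusals["all"] = f"no measurements for organ {organ!r}"
        return res
    for sp in config.exclude:
        if (lanes["species"] == sp).any():
            res.dropped.append({"species": sp, "reason": "excluded by configuration"})
    lanes = lanes[~lanes["species"].isin(config.exclude)]
    if not len(lanes):
        res.refusals["all"] = "no measurements left after exclusions"
        return res

    rescaled = dens.cross_gel_normalize(lanes, config.reference_species)
    table = dens.summarize_species(rescaled, organ=organ)

    nonpos = table[~(table["mean_level"] > 0)]
    for sp in nonpos["species"]:
        res.dropped.append(
            {"species": sp, "reason": "non-positive mean level (log scale undefined)"}
        )
    table = table[table["mean_level"] > 0]

    missing_traits = [sp for sp in table["species"] if sp not in traits.index]
    for sp in missing_traits:
        res.dropped.append({"species": sp, "reason": "absent from trait table"})
    table = table[table["species"].isin(traits.index)]

    table = table.merge(
        traits[["max_lifespan_yr", "body_mass_g"]],
        left_on="species",
        right_index=True,
    ).sort_values("species", ignore_index=True)
    res.species_table = table
    res.species_used = list(table["species"])
    res.n_species = len(table)

    species = list(table["species"])
    log_level = st.log_transform(table["mean_level"], config.log_base, species)
    log_life = st.log_transform(table["max_lifespan_yr"], config.log_base, species)
    log_mass = st.log_transform(table["body_mass_g"], config.log_base, species)

    for name, vals in (
        ("level", log_level),
        ("lifespan", log_life),
        ("mass", log_mass),
    ):
        try:
            res.normality[name] = st.chi_square_normality(
                vals, n_bins=config.n_bins, binning=config.binning
            )
        except ValueError as exc:
            res.normality[name] = None
            res.refusals[f"normality_{name}"] = str(exc)

    if res.n_species >= 3:
        res.regression_lifespan = st.simple_regression(log_life, log_level)
        res.regression_mass = st.simple_regression(log_mass, log_level)
    else:
        res.refusals["regression"] = (
            f"only {res.n_species} species with data; need >= 3"
        )
    if res.n_species >= MIN_SPECIES_FOR_MODELS:
        res.multiple_regression = st.multiple_regression(
            log_level, log_life, log_mass, names=("log_lifespan", "log_mass")
        )
    else:
        res.refusals["multiple_regression"] = (
            f"only {res.n_species} species with data; need >= {MIN_SPECIES_FOR_MODELS}"
        )

    _run_pic(res, tree, config, species, log_level, log_life, log_mass)
    return res


def _run_pic(
    res: OrganResult,
    tree: dendropy.Tree,
    config: StudyConfig,
    species: list[str],
    log_level: np.ndarray,
    log_life: np.ndarray,
    log_mass: np.ndarray,
) -> None:
    tree_leaves = set(phylo.leaf_labels(tree))
    off_tree = [sp for sp in species if sp not in tree_leaves]
    if off_tree:
        if config.strict_tree:
            raise phylo.TreeError(
                f"species missing from tree: {', '.join(sorted(off_tree))}"
            )
        for sp in off_tree:
            res.dropped.append(
                {"species": sp, "reason": "absent from tree; dropped from contrasts only"}
            )
    keep = [sp for sp in species if sp in tree_leaves]
    if len(keep) < MIN_SPECIES_FOR_MODELS:
        res.refusals["pic"] = (
            f"only {len(keep)} species on the tree; need >= {MIN_SPECIES_FOR_MODELS}"
        )
        return
    sub = phylo.prune_to_taxa(tree, keep)
    if config.branch_lengths == "equal":
        sub = phylo.set_equal_branch_lengths(sub, config.equal_length)
    sub = phylo.resolve_polytomies(sub, seed=config.seed)
    idx = {sp: i for i, sp in enumerate(species)}
    tr_level = {sp: float(log_level[idx[sp]]) for sp in keep}
    tr_life = {sp: float(log_life[idx[sp]]) for sp in keep}
    tr_mass = {sp: float(log_mass[idx[sp]]) for sp in keep}
    c_level = phylo.independent_contrasts(sub, tr_level, "log_level")
    c_life = phylo.independent_contrasts(sub, tr_life, "log_lifespan")
    c_mass = phylo.independent_contrasts(sub, tr_mass, "log_mass")
    res.pic_species = sorted(keep)
    res.pic_lifespan = phylo.contrast_regression(c_life, c_level)
    res.pic_mass = phylo.contrast_regression(c_mass, c_level)


def run_study_files(
    measurements_path,
    traits_path,
    tree_path,
    config: StudyConfig | None = None,
) -> StudyReport:
    """File-based front end to :func:`run_study` (CSV/TSV + Newick)."""
    measurements = dens.read_measurements(measurements_path)
    sep = "\t" if str(traits_path).endswith((".tsv", ".tab")) else ","
    traits = pd.read_csv(traits_path, sep=sep)
    tree = phylo.read_newick(tree_path)
    return run_study(measurements, traits, tree, config)
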