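"""Synthetic case-control cohorts with a known microbiome + phenotype structure.

The generator emulates the kind of cross-sectional cohort used to train
disease-prediction models from gut microbiota: one healthy control group and
several disease groups, a genus-level 16S count table, quantitative
(nutrient-intake / body-composition) variables, categorical lifestyle
variables, and a random phylogeny over the genera.  Effects are *planted* —
the spec used to generate a cohort is carried along as ground truth, so
recovery of the planted signal can be tested end to end.

Counts are Dirichlet-multinomial: each sample's genus composition is drawn
from a Dirichlet whose concentration vector is the cohort baseline with the
sample's group-specific log2 fold-changes applied multiplicatively, then reads
are multinomial at a per-sample library size drawn uniformly from a range.
The total concentration mass controls overdispersion (smaller mass, more
sample-to-sample compositional noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "QuantVar",
    "QualVar",
    "SyntheticSpec",
    "CohortData",
    "default_spec",
    "generate_cohort",
    "generate_tree",
]

CONTROL = "CT"


class SpecValidationError(ValueError):
    """A SyntheticSpec field violates its invariants."""


@dataclass(frozen=True)
class QuantVar:
    """Quantitative phenotype variable: Gaussian, truncated at zero.

    ``shifts`` maps disease-group name -> additive shift of the mean relative
    to the control mean.  Groups absent from ``shifts`` use the control mean.
    """

    name: str
    control_mean: float
    control_sd: float
    shifts: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class QualVar:
    """Categorical phenotype variable with group-dependent level probabilities."""

    name: str
    levels: tuple[str, ...]
    control_probs: tuple[float, ...]
    group_probs: Mapping[str, tuple[float, ...]] = field(default_factory=dict)


@dataclass(frozen=True)
class SyntheticSpec:
    """Full parameterization of a synthetic cohort, including ground truth.

    planted_taxa maps a disease group to a list of (taxon index, log2
    fold-change) pairs applied to the baseline Dirichlet concentrations for
    samples of that group.
    """

    group_sizes: Mapping[str, int]
    n_taxa: int
    planted_taxa: Mapping[str, Sequence[tuple[int, float]]]
    base_concentration: tuple[float, ...]
    library_size_range: tuple[int, int]
    quant_vars: tuple[QuantVar, ...]
    qual_vars: tuple[QualVar, ...]
    seed: int
    control: str = CONTROL

    def validate(self) -> None:
        if self.control not in self.group_sizes:
            raise SpecValidationError(
                f"group_sizes: control group {self.control!r} missing"
            )
        for g, n in self.group_sizes.items():
            if n < 2:
                raise SpecValidationError(f"group_sizes[{g!r}] = {n} < 2")
        if self.n_taxa < 2:
            raise SpecValidationError(f"n_taxa = {self.n_taxa} < 2")
        if len(self.base_concentration) != self.n_taxa:
            raise SpecValidationError(
                "base_concentration length "
                f"{len(self.base_concentration)} != n_taxa {self.n_taxa}"
            )
        if any(c <= 0 for c in self.base_concentration):
            raise SpecValidationError("base_concentration: entries must be > 0")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise SpecValidationError(
                f"library_size_range: need 0 < lo <= hi, got ({lo}, {hi})"
            )
        for disease, effects in self.planted_taxa.items():
            if disease not in self.group_sizes or disease == self.control:
                raise SpecValidationError(
                    f"planted_taxa: unknown disease group {disease!r}"
                )
            for idx, lfc in effects:
                if not 0 <= idx < self.n_taxa:
                    raise SpecValidationError(
                        f"planted_taxa[{disease!r}]: taxon index {idx} out of range"
                    )
                if not np.isfinite(lfc):
                    raise SpecValidationError(
                        f"planted_taxa[{disease!r}]: non-finite log2FC for taxon {idx}"
                    )
        for qv in self.quant_vars:
            if qv.control_sd <= 0:
                raise SpecValidationError(f"quant_vars[{qv.name!r}]: sd must be > 0")
            for g in qv.shifts:
                if g not in self.group_sizes:
                    raise SpecValidationError(
                        f"quant_vars[{qv.name!r}]: unknown group {g!r}"
                    )
        for qv in self.qual_vars:
            for label, probs in [("control", qv.control_probs)] + [
                (g, p) for g, p in qv.group_probs.items()
            ]:
                if len(probs) != len(qv.levels):
                    raise SpecValidationError(
                        f"qual_vars[{qv.name!r}]: {label} probability vector length "
                        f"{len(probs)} != number of levels {len(qv.levels)}"
                    )
                if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
                    raise SpecValidationError(
                        f"qual_vars[{qv.name!r}]: {label} probabilities must be "
                        "nonnegative and sum to 1"
                    )
            for g in qv.group_probs:
                if g not in self.group_sizes:
                    raise SpecValidationError(
                        f"qual_vars[{qv.name!r}]: unknown group {g!r}"
                    )

    @property
    def diseases(self) -> list[str]:
        return [g for g in self.group_sizes if g != self.control]

    @property
    def n_samples(self) -> int:
        return int(sum(self.group_sizes.values()))


@dataclass
class CohortData:
    """A generated cohort: counts, phenotypes, labels, phylogeny, and truth."""

    counts: pd.DataFrame  # samples x taxa, nonnegative integers
    phenotypes: pd.DataFrame  # samples x variables (mixed dtypes)
    labels: pd.Series  # sample -> group name
    tree: TreeNode
    truth: SyntheticSpec

    def validate(self) -> None:
        samples = self.counts.index
        if not (samples.equals(self.phenotypes.index) and samples.equals(self.labels.index)):
            raise ValueError("counts, phenotypes and labels must share sample IDs")
        leaves = {t.name for t in self.tree.tips()}
        if leaves != set(self.counts.columns):
            raise ValueError("tree leaf set must equal the count-table taxon set")


def default_spec(seed: int = 0) -> SyntheticSpec:
    """Default cohort design: 50 controls plus seven disease groups (202 subjects).

    Group sizes mirror a multi-disease case-control design (IBD split into
    Crohn's disease and ulcerative colitis at 20 each, psoriasis, rheumatoid
    arthritis, lupus, type 1 diabetes at 20, type 2 diabetes at 32).  Each
    disease plants moderate fold-changes on a few genera, with some genera
    shared across diseases; quantitative variables emulate age, body
    composition and habitual nutrient intake; categorical variables emulate
    sex, smoking, physical activity and supplement use.
    """
    group_sizes = {
        CONTROL: 50, "CD": 20, "UC": 20, "PP": 20,
        "RA": 20, "SLE": 20, "T1D": 20, "T2D": 32,
    }
    n_taxa = 60
    # Baseline concentrations: power-law ranked abundances, total mass 50
    # (moderate 16S-like overdispersion).
    ranks = np.arange(1, n_taxa + 1, dtype=float)
    conc = ranks ** -1.1
    conc = conc / conc.sum() * 50.0
    planted = {
        "CD": [(3, -1.8), (7, 1.6), (12, -2.0), (25, 1.8)],
        "UC": [(3, -1.4), (9, 1.8), (14, -1.6), (30, 2.0)],
        "PP": [(5, 1.7), (9, -1.5), (18, 1.9), (33, -1.8)],
        "RA": [(2, -1.5), (11, 1.8), (21, -1.7), (36, 2.1)],
        "SLE": [(2, 1.6), (13, -1.9), (24, 1.7), (40, -1.6)],
        "T1D": [(6, -1.7), (15, 2.0), (27, -1.8), (44, 1.9)],
        "T2D": [(4, 1.5), (17, -1.9), (29, 1.8), (48, -2.0)],
    }
    quant = (
        QuantVar("age", 32, 10, {"PP": 20, "RA": 25, "T2D": 18, "CD": 6, "UC": 6}),
        QuantVar("weight_kg", 68, 12, {"T2D": 28}),
        QuantVar("bmi", 24, 2.5, {"T2D": 12, "PP": 3, "RA": 2}),
        QuantVar("fat_mass_pct", 27, 7, {"T2D": 19, "RA": 16, "PP": 11}),
        QuantVar("lean_mass_pct", 73, 8, {"T2D": -19, "RA": -16, "PP": -11}),
        QuantVar("selenium_ug", 55, 15, {"RA": -18, "SLE": -20, "CD": -10}),
        QuantVar("manganese_mg", 2.2, 0.8, {"CD": -0.9, "UC": -0.8, "SLE": -0.9}),
        QuantVar("carbohydrates_g", 230, 60, {"CD": -50}),
        QuantVar("fiber_g", 18, 6, {"CD": -7, "UC": -6}),
        QuantVar("protein_g", 75, 20, {"RA": -18}),
        QuantVar("cholesterol_mg", 250, 80, {"T1D": 90, "T2D": 60}),
        QuantVar("folate_ug", 280, 90, {"RA": -85, "T1D": -100}),
    )
    qual = (
        QualVar(
            "sex", ("female", "male"), (0.46, 0.54),
            {"SLE": (1.0, 0.0), "RA": (0.75, 0.25),
             "CD": (0.6, 0.4), "UC": (0.6, 0.4), "PP": (0.6, 0.4)},
        ),
        QualVar(
            "smoking", ("never", "former", "current"), (0.7, 0.2, 0.1),
            {"PP": (0.4, 0.3, 0.3), "RA": (0.45, 0.35, 0.2)},
        ),
        QualVar(
            "physical_activity", ("low", "moderate", "high"), (0.3, 0.45, 0.25),
            {"T2D": (0.65, 0.25, 0.1), "RA": (0.6, 0.3, 0.1)},
        ),
        QualVar(
            "vitamin_supplement", ("no", "yes"), (0.75, 0.25),
            {"SLE": (0.25, 0.75), "RA": (0.45, 0.55)},
        ),
    )
    return SyntheticSpec(
        group_sizes=group_sizes,
        n_taxa=n_taxa,
        planted_taxa=planted,
        base_concentration=tuple(conc),
        library_size_range=(5000, 20000),
        quant_vars=quant,
        qual_vars=qual,
        seed=seed,
    )


def _taxon_names(n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"taxon_{i:0{width}d}" for i in range(n)]


def _component_rng(seed: int, component: int) -> np.random.Generator:
    # Independent stream per component so switching one component off does not
    # perturb the draws of the others.
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(component,)))


def generate_cohort(spec: SyntheticSpec) -> CohortData:
    """Draw a full cohort (counts, phenotypes, labels, tree) from a spec.

    Deterministic given ``spec.seed``; each component (counts, quantitative,
    qualitative, tree) consumes its own RNG stream derived from the seed.
    """
    spec.validate()
    groups: list[str] = []
    for g, n in spec.group_sizes.items():
        groups.extend([g] * n)
    width = max(3, len(str(spec.n_samples)))
    sample_ids = []
    per_group_counter: dict[str, int] = {}
    for g in groups:
        per_group_counter[g] = per_group_counter.get(g, 0) + 1
        sample_ids.append(f"{g}_{per_group_counter[g]:0{width}d}")
    labels = pd.Series(groups, index=sample_ids, name="group")

    taxa = _taxon_names(spec.n_taxa)
    base = np.asarray(spec.base_concentration, dtype=float)

    # Per-group concentration vectors: baseline with planted log2FC applied.
    conc_by_group: dict[str, np.ndarray] = {}
    for g in spec.group_sizes:
        conc = base.copy()
        for idx, lfc in spec.planted_taxa.get(g, ()):  # control never planted
            conc[idx] *= 2.0 ** lfc
        conc_by_group[g] = conc

    rng_counts = _component_rng(spec.seed, 0)
    lo, hi = spec.library_size_range
    count_rows = np.empty((spec.n_samples, spec.n_taxa), dtype=np.int64)
    for i, g in enumerate(groups):
        p = rng_counts.dirichlet(conc_by_group[g])
        depth = int(rng_counts.integers(lo, hi + 1))
        count_rows[i] = rng_counts.multinomial(depth, p)
    counts = pd.DataFrame(count_rows, index=sample_ids, columns=taxa)

    rng_quant = _component_rng(spec.seed, 1)
    quant_cols: dict[str, np.ndarray] = {}
    for qv in spec.quant_vars:
        means = np.array(
            [qv.control_mean + qv.shifts.get(g, 0.0) for g in groups], dtype=float
        )
        draws = rng_quant.normal(means, qv.control_sd)
        # Truncate at zero by redrawing (intakes and body composition are
        # nonnegative); planted shifts keep means well above 0 so redraws are rare.
        bad = draws < 0
        while bad.any():
            draws[bad] = rng_quant.normal(means[bad], qv.control_sd)
            bad = draws < 0
        quant_cols[qv.name] = draws

    rng_qual = _component_rng(spec.seed, 2)
    qual_cols: dict[str, np.ndarray] = {}
    for qv in spec.qual_vars:
        vals = np.empty(spec.n_samples, dtype=object)
        levels = np.asarray(qv.levels, dtype=object)
        for i, g in enumerate(groups):
            probs = qv.group_probs.get(g, qv.control_probs)
            vals[i] = levels[rng_qual.choice(len(levels), p=np.asarray(probs))]
        qual_cols[qv.name] = vals

    phenotypes = pd.DataFrame({**quant_cols, **qual_cols}, index=sample_ids)

    tree_seed = int(
        np.random.SeedSequence(spec.seed, spawn_key=(3,)).generate_state(1)[0]
        % (2**31)
    )
    tree = generate_tree(taxa, seed=tree_seed)

    cohort = CohortData(counts=counts, phenotypes=phenotypes, labels=labels,
                        tree=tree, truth=spec)
    cohort.validate()
    return cohort


def generate_tree(taxa: Sequence[str], seed: int) -> TreeNode:
    """Random rooted bifurcating phylogeny by successive random coalescence.

    Each coalescence event joins two uniformly chosen lineages under a new
    internal node; pendant branch lengths are exponential(1) draws.  The
    result has exactly ``len(taxa) - 1`` internal nodes.
    """
    if len(taxa) < 2:
        raise ValueError("generate_tree requires at least 2 taxa")
    if len(set(taxa)) != len(taxa):
        raise ValueError("taxon names must be unique")
    rng = np.random.default_rng(seed)
    lineages = [TreeNode(name=str(t)) for t in taxa]
    for node in lineages:
        node.length = float(rng.exponential(1.0))
    while len(lineages) > 1:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        b = lineages.pop(j)
        a = lineages.pop(i)
        parent = TreeNode(children=[a, b])
        parent.length = float(rng.exponential(1.0))
        lineages.append(parent)
    root = lineages[0]
    root.length = None
    return root
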