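"""Synthetic recipe corpora with planted ingredient modules.

The generator emulates the statistical shape of a historical remedy
collection — a few hundred recipes of a handful to a couple of dozen
ingredients each, drawn from a vocabulary of a few hundred names that is
organized into overlapping thematic groups — while providing ground-truth
module labels so community recovery can be scored (adjusted Rand index
against the planted partition).

Each recipe picks a *home module* uniformly at random and then draws its
ingredients from that module with probability ``1 - p_noise``, otherwise
uniformly from the rest of the vocabulary.  With ``hierarchy_depth=2`` every
module is split into submodules and the within-module draw prefers the
recipe's home submodule, planting nested block structure: submodule pairs
co-occur most often, same-module/different-submodule pairs less often, and
cross-module pairs rarely.  That weight gradient is what lets a threshold
sweep split a parent community into its subcommunities.

All randomness flows from a single :class:`numpy.random.Generator` seeded
from the design; identical designs give byte-identical corpora.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .corpus import Recipe, RecipeCorpus
from .errors import ValidationError

#: Within-module preference for the home submodule at hierarchy_depth=2.
SUBMODULE_PREFERENCE = 0.75


@dataclass(frozen=True)
class PlantedDesign:
    """Parameters of a planted-module corpus.

    Defaults emulate a manuscript-scale corpus: ~400 recipes of 2-16
    ingredients over a 300-name vocabulary in 10 thematic modules, with 10%
    of draws leaking outside the home module.

    Parameters
    ----------
    n_modules : int
        Number of planted ingredient modules.
    ingredients_per_module : int
        Vocabulary size of each module.
    n_recipes : int
        Number of recipes to generate.
    recipe_len : (int, int)
        Inclusive range of recipe lengths; minimum >= 2.
    p_noise : float
        Probability that an ingredient draw falls outside the home module.
    hierarchy_depth : int
        1 for flat modules; 2 splits each module into two submodules with
        within-module preference :data:`SUBMODULE_PREFERENCE` for the home
        submodule.
    n_ubiquitous : int
        Optional count of module-free, high-frequency ingredients (think
        water or sugar in a remedy book: frequent but structurally
        uninformative) appended to recipes with probability
        ``p_ubiquitous``.  Off by default.
    seed : int
        RNG seed; the corpus is a pure function of the design.
    """

    n_modules: int = 10
    ingredients_per_module: int = 30
    n_recipes: int = 400
    recipe_len: tuple = (2, 16)
    p_noise: float = 0.1
    hierarchy_depth: int = 1
    n_ubiquitous: int = 0
    p_ubiquitous: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.p_noise <= 1.0:
            raise ValidationError("p_noise must be in [0, 1]")
        lo, hi = self.recipe_len
        if lo < 2 or hi < lo:
            raise ValidationError("recipe_len must satisfy 2 <= min <= max")
        if self.hierarchy_depth not in (1, 2):
            raise ValidationError("hierarchy_depth must be 1 or 2")
        if self.n_modules < 1 or self.ingredients_per_module < 1:
            raise ValidationError("need at least one module and ingredient")
        vocab = self.n_modules * self.ingredients_per_module
        if hi > vocab + self.n_ubiquitous:
            raise ValidationError(
                f"max recipe length {hi} exceeds vocabulary size {vocab}"
            )
        if self.p_noise == 0.0 and hi > self.ingredients_per_module:
            raise ValidationError(
                "with p_noise=0 recipes draw only from their home module; "
                f"max length {hi} exceeds module size "
                f"{self.ingredients_per_module}"
            )


@dataclass
class PlantedLabels:
    """Ground-truth (module, submodule) label for every generated ingredient."""

    module: dict = field(default_factory=dict)
    submodule: dict = field(default_factory=dict)

    def module_vector(self, nodes) -> np.ndarray:
        """Integer module labels aligned to ``nodes`` (for ARI scoring)."""
        return np.array([self.module[n] for n in nodes], dtype=int)

    def submodule_vector(self, nodes) -> np.ndarray:
        return np.array(
            [
                self.module[n] * 1000 + (self.submodule[n] or 0)
                for n in nodes
            ],
            dtype=int,
        )


def _token(module: int, index: int) -> str:
    return f"m{module}_i{index:02d}"


def generate_planted_corpus(design: PlantedDesign):
    """Generate a corpus with planted modules plus its ground-truth labels.

    Returns
    -------
    (RecipeCorpus, PlantedLabels)
    """
    rng = np.random.default_rng(design.seed)
    n_sub = 2 if design.hierarchy_depth == 2 else 1

    modules = []  # module -> list of token lists per submodule
    labels = PlantedLabels()
    for m in range(design.n_modules):
        tokens = [
            _token(m, i) for i in range(design.ingredients_per_module)
        ]
        subs = [tokens[s::n_sub] for s in range(n_sub)]
        modules.append(subs)
        for s, sub in enumerate(subs):
            for t in sub:
                labels.module[t] = m
                labels.submodule[t] = s if n_sub > 1 else None

    ubiquitous = [f"ubiq_i{i:02d}" for i in range(design.n_ubiquitous)]
    for t in ubiquitous:
        labels.module[t] = -1
        labels.submodule[t] = None

    module_tokens = [
        [t for sub in subs for t in sub] for subs in modules
    ]
    all_tokens = [t for toks in module_tokens for t in toks]
    # noise draws come from *other* modules only
    other_tokens = [
        [t for t in all_tokens if labels.module[t] != m]
        for m in range(design.n_modules)
    ]
    lo, hi = design.recipe_len
    recipes = []
    for r in range(design.n_recipes):
        home = int(rng.integers(design.n_modules))
        home_sub = int(rng.integers(n_sub))
        length = int(rng.integers(lo, hi + 1))
        chosen: set = set()
        # rejection sampling over sources; stalls are impossible because
        # length is pre-validated against the reachable vocabulary
        guard = 0
        while len(chosen) < length:
            guard += 1
            if guard > 10000 * length:
                raise ValidationError(
                    "could not fill recipe; module too small for its length"
                )
            if other_tokens[home] and rng.random() < design.p_noise:
                pool = other_tokens[home]
            elif n_sub > 1 and rng.random() >= SUBMODULE_PREFERENCE:
                pool = modules[home][1 - home_sub]
            else:
                pool = modules[home][home_sub]
            tok = pool[int(rng.integers(len(pool)))]
            chosen.add(tok)
        for t in ubiquitous:
            if rng.random() < design.p_ubiquitous:
                chosen.add(t)
        recipes.append(
            Recipe(
                recipe_id=f"r{r:04d}",
                condition=f"cond{home}",
                ingredients=frozenset(chosen),
            )
        )
    corpus = RecipeCorpus(
        recipes=recipes,
        provenance=f"planted(seed={design.seed})",
    )
    return corpus, labels


def two_recipe_fixture() -> RecipeCorpus:
    """The two-recipe worked example: an eye ointment and a mouthwash.

    Recipe R1 treats *fistula in lacrimali* with five ingredients; recipe R2
    treats *pascionibus oris* with six.  Four ingredients (hony, galle,
    pomegarnettes, sumac) are shared, so their six pairwise links appear in
    both recipes.
    """
    return RecipeCorpus(
        recipes=[
            Recipe(
                recipe_id="R1",
                condition="fistula in lacrimali",
                ingredients=frozenset(
                    ["galle", "hony", "pomegarnettes", "ruta", "sumac"]
                ),
            ),
            Recipe(
                recipe_id="R2",
                condition="pascionibus oris",
                ingredients=frozenset(
                    [
                        "galle",
                        "hony",
                        "olibanum",
                        "sumac",
                        "vinegre",
                        "pomegarnettes",
                    ]
                ),
            ),
        ],
        provenance="two-recipe worked example",
    )


def hierarchical_fixture(seed: int = 0):
    """Depth-2 planted corpus whose communities split under thresholding.

    Two modules, each divided into two submodules.  At threshold 0 the dense
    within-module links merge each submodule pair into one community; raising
    the threshold cuts the weaker cross-submodule links, so the parent
    communities split and the count of detected communities increases.
    """
    design = PlantedDesign(
        n_modules=2,
        ingredients_per_module=14,
        n_recipes=240,
        recipe_len=(3, 5),
        p_noise=0.02,
        hierarchy_depth=2,
        seed=seed,
    )
    return generate_planted_corpus(design)


def write_labels(labels: PlantedLabels, path) -> None:
    """Write labels as TSV: ``ingredient``, ``module``, ``submodule``."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("ingredient\tmodule\tsubmodule\n")
        for tok in sorted(labels.module):
            sub = labels.submodule.get(tok)
            fh.write(
                f"{tok}\t{labels.module[tok]}\t{'' if sub is None else sub}\n"
            )
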