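"""Candidate recipe selection by core-ingredient content.

A recipe's score is the number of core items it contains: each core pair
counts only when *both* members are present; each core single counts as
one.  Recipes at or above a minimum score are grouped by score (descending)
with alphabetical order inside each group.

Exclusions the original study applied by hand (alchemical metals, opiates,
unwieldy ingredient lists) are exposed as optional parameters — an
ingredient deny-list and a maximum ingredient count — both off by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional

from .consensus import CoreSet
from .corpus import Recipe, RecipeCorpus


@dataclass
class RecipeRanking:
    """Recipes grouped by core-content score, descending."""

    groups: Dict[int, List[str]] = field(default_factory=dict)
    scores: Dict[str, int] = field(default_factory=dict)
    conditions: Dict[str, str] = field(default_factory=dict)

    @property
    def n_recipes(self) -> int:
        return sum(len(v) for v in self.groups.values())

    def to_json(self) -> str:
        return json.dumps(
            {
                "groups": {str(s): ids for s, ids in self.groups.items()},
                "scores": self.scores,
            },
            indent=2,
            sort_keys=True,
        )

    def write_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("recipe_id\tcondition\tscore\tgroup\n")
            for rank, score in enumerate(sorted(self.groups, reverse=True), 1):
                for rid in self.groups[score]:
                    fh.write(
                        f"{rid}\t{self.conditions.get(rid, '')}\t"
                        f"{score}\t{rank}\n"
                    )


def score_recipe(recipe: Recipe, core: CoreSet) -> int:
    """Count core pairs fully present plus core singles present."""
    ing = recipe.ingredients
    pair_hits = sum(1 for a, b in core.core_pairs if a in ing and b in ing)
    single_hits = sum(1 for s in core.core_singles if s in ing)
    return pair_hits + single_hits


def rank_recipes(
    corpus: RecipeCorpus,
    core: CoreSet,
    min_score: int = 1,
    exclude_ingredients: Optional[Iterable[str]] = None,
    max_ingredients: Optional[int] = None,
) -> RecipeRanking:
    """Group recipes scoring at least ``min_score`` by descending score.

    ``exclude_ingredients`` drops any recipe containing a denied token;
    ``max_ingredients`` drops recipes with overly long ingredient lists.
    """
    deny = set(exclude_ingredients or ())
    ranking = RecipeRanking()
    for recipe in corpus:
        if deny and recipe.ingredients & deny:
            continue
        if max_ingredients is not None and len(recipe.ingredients) > max_ingredients:
            continue
        score = score_recipe(recipe, core)
        if score >= min_score:
            ranking.groups.setdefault(score, []).append(recipe.recipe_id)
            ranking.scores[recipe.recipe_id] = score
            ranking.conditions[recipe.recipe_id] = recipe.condition
    for ids in ranking.groups.values():
        ids.sort()
    ranking.groups = {
        s: ranking.groups[s] for s in sorted(ranking.groups, reverse=True)
    }
    return ranking
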