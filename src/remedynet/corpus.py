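"""Recipe corpus data model and I/O.

A corpus is an ordered list of recipes; each recipe carries a unique
identifier, a condition label (the disease or chapter the remedy targets)
and a *set* of canonical ingredient tokens.  Ingredient multiplicity within
a recipe is deliberately discarded: downstream network construction counts
ingredient *pairs per recipe*, for which duplicates carry no information.

Tokens are canonicalized on ingestion by trimming surrounding whitespace and
lower-casing.  Spelling variants beyond that (a pervasive feature of
historical texts, where the same ingredient may appear under many forms)
are handled through an explicit, user-supplied synonym table rather than any
fuzzy matching.

File dialect: delimited text (default tab) with columns ``recipe_id``,
``condition``, ``ingredients``; the ingredients cell is itself delimited
(default ``;``).  Extra columns (e.g. a marker flag distinguishing formally
notated recipes) are preserved as per-recipe metadata but never used by any
computation.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import FormatError, ValidationError

REQUIRED_COLUMNS = ("recipe_id", "condition", "ingredients")


def canonical_token(token: str) -> str:
    """Trim surrounding whitespace and lower-case a token."""
    return token.strip().lower()


@dataclass(frozen=True)
class Recipe:
    """One condition-labelled ingredient list.

    Parameters
    ----------
    recipe_id : str
        Unique, non-empty identifier.
    condition : str
        Disease / chapter label.
    ingredients : frozenset of str
        Canonical ingredient tokens; non-empty, set semantics.
    metadata : tuple of (str, str)
        Extra columns from the source file, unused by computation.
    """

    recipe_id: str
    condition: str
    ingredients: frozenset
    metadata: tuple = ()

    def __post_init__(self):
        if not self.recipe_id:
            raise ValidationError("recipe_id must be non-empty")
        if not self.ingredients:
            raise ValidationError(
                f"recipe {self.recipe_id!r} has no ingredients"
            )


@dataclass
class RecipeCorpus:
    """Ordered collection of recipes with unique identifiers."""

    recipes: list = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self):
        ids = [r.recipe_id for r in self.recipes]
        if len(ids) != len(set(ids)):
            seen, dup = set(), None
            for i in ids:
                if i in seen:
                    dup = i
                    break
                seen.add(i)
            raise ValidationError(f"duplicate recipe_id {dup!r}")

    def __len__(self) -> int:
        return len(self.recipes)

    def __iter__(self):
        return iter(self.recipes)

    @property
    def conditions(self) -> list:
        return [r.condition for r in self.recipes]

    def vocabulary(self) -> list:
        """Sorted list of distinct ingredient tokens in the corpus."""
        vocab = set()
        for r in self.recipes:
            vocab.update(r.ingredients)
        return sorted(vocab)


@dataclass(frozen=True)
class CorpusSummary:
    """Headline counts for a corpus."""

    n_recipes: int
    n_ingredient_mentions: int
    n_unique_ingredients: int
    n_unique_conditions: int

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


class SynonymMap:
    """Token -> canonical-token mapping, validated to be idempotent.

    Idempotence means applying the map twice equals applying it once: a
    canonical form either maps to itself or is absent from the table, so no
    chain ``a -> b -> c`` is possible.
    """

    def __init__(self, mapping: Mapping[str, str]):
        clean = {
            canonical_token(k): canonical_token(v) for k, v in mapping.items()
        }
        for variant, canon in clean.items():
            if canon in clean and clean[canon] != canon:
                raise ValidationError(
                    f"synonym map not idempotent: {variant!r} -> {canon!r} "
                    f"-> {clean[canon]!r}"
                )
        self._mapping = clean

    def __getitem__(self, token: str) -> str:
        return self._mapping.get(token, token)

    def __len__(self) -> int:
        return len(self._mapping)

    def items(self):
        return self._mapping.items()


def read_corpus(
    path,
    delimiter: str = "\t",
    ingredient_sep: str = ";",
) -> RecipeCorpus:
    """Read a recipe corpus from a delimited text file.

    Raises
    ------
    FormatError
        Empty file or missing required columns.
    ValidationError
        Duplicate recipe identifiers or a row with zero ingredients.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        header = [h.strip() for h in header]
        missing = [c for c in REQUIRED_COLUMNS if c not in header]
        if missing:
            raise FormatError(f"{path}: missing columns {missing}")
        idx = {c: header.index(c) for c in REQUIRED_COLUMNS}
        extra_cols = [
            (j, name)
            for j, name in enumerate(header)
            if name not in REQUIRED_COLUMNS
        ]
        recipes = []
        for rownum, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue
            if len(row) < len(header):
                raise FormatError(
                    f"{path}: row {rownum} has {len(row)} fields, "
                    f"expected {len(header)}"
                )
            rid = row[idx["recipe_id"]].strip()
            condition = row[idx["condition"]].strip()
            tokens = [
                canonical_token(t)
                for t in row[idx["ingredients"]].split(ingredient_sep)
            ]
            ingredients = frozenset(t for t in tokens if t)
            if not ingredients:
                raise ValidationError(
                    f"{path}: row {rownum} (recipe_id={rid!r}) "
                    "lists no ingredients"
                )
            meta = tuple(
                (name, row[j].strip()) for j, name in extra_cols
            )
            recipes.append(
                Recipe(
                    recipe_id=rid,
                    condition=condition,
                    ingredients=ingredients,
                    metadata=meta,
                )
            )
    return RecipeCorpus(recipes=recipes, provenance=str(path))


def write_corpus(
    corpus: RecipeCorpus,
    path,
    delimiter: str = "\t",
    ingredient_sep: str = ";",
) -> None:
    """Write a corpus in the dialect :func:`read_corpus` reads."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(REQUIRED_COLUMNS)
        for r in corpus:
            writer.writerow(
                [
                    r.recipe_id,
                    r.condition,
                    ingredient_sep.join(sorted(r.ingredients)),
                ]
            )


def read_synonyms(path, delimiter: str = "\t") -> SynonymMap:
    """Read a two-column ``variant``, ``canonical`` synonym table."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        try:
            header = [h.strip() for h in next(reader)]
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        if header[:2] != ["variant", "canonical"]:
            raise FormatError(
                f"{path}: expected columns 'variant', 'canonical', "
                f"got {header[:2]}"
            )
        mapping = {}
        for row in reader:
            if len(row) >= 2 and row[0].strip():
                mapping[row[0]] = row[1]
    return SynonymMap(mapping)


def apply_synonyms(corpus: RecipeCorpus, synonyms: SynonymMap) -> RecipeCorpus:
    """Replace every token by its canonical form.

    Tokens that collapse to the same canonical form within one recipe are
    merged (set semantics), so a recipe can shrink.
    """
    recipes = [
        Recipe(
            recipe_id=r.recipe_id,
            condition=r.condition,
            ingredients=frozenset(synonyms[t] for t in r.ingredients),
            metadata=r.metadata,
        )
        for r in corpus
    ]
    return RecipeCorpus(recipes=recipes, provenance=corpus.provenance)


def filter_conditions(
    corpus: RecipeCorpus, allowed: Iterable[str]
) -> RecipeCorpus:
    """Keep recipes whose condition label is in ``allowed``, order preserved."""
    allowed = set(allowed)
    return RecipeCorpus(
        recipes=[r for r in corpus if r.condition in allowed],
        provenance=corpus.provenance,
    )


def summarize(corpus: RecipeCorpus) -> CorpusSummary:
    """Compute headline counts (mentions = sum of per-recipe set sizes)."""
    vocab = set()
    conditions = set()
    mentions = 0
    for r in corpus:
        vocab.update(r.ingredients)
        conditions.add(r.condition)
        mentions += len(r.ingredients)
    return CorpusSummary(
        n_recipes=len(corpus),
        n_ingredient_mentions=mentions,
        n_unique_ingredients=len(vocab),
        n_unique_conditions=len(conditions),
    )
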