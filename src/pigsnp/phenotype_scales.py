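"""Conversions between field 5-grade scales and classification scales.

Eye and hair darkness are phenotyped on 5-grade ordinal scales (0 lightest,
4 darkest; for hair, grade 0 is red and grade 1 blond).  Classification uses
coarser scales: three eye classes (blue / intermediate / brown), four hair
classes (red / blond / brown / dark) and a merged three-class hair scale in
which blond and brown are pooled because they are hard to separate.
A population grade-diversity filter removes populations whose samples do not
span at least 4 distinct grades for the analyzed trait.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MERGED_LABEL = "blond+brown"

#: Populations must show at least this many distinct grades to be kept.
MIN_DISTINCT_GRADES = 4


@dataclass(frozen=True)
class ClassScale:
    """Ordered class labels with a total mapping from 5-grade values.

    ``centers`` gives each class a numeric position on the grade axis (the
    mean of the grades mapped to it), used for nearest-class assignment of
    continuous predictions.
    """

    name: str
    classes: tuple[str, ...]
    grade_map: dict[int, str]

    def __post_init__(self) -> None:
        if sorted(self.grade_map) != [0, 1, 2, 3, 4]:
            raise ValueError(f"{self.name}: mapping must cover grades 0-4")
        if len(set(self.classes)) != len(self.classes):
            raise ValueError(f"{self.name}: duplicate class labels")
        extra = set(self.grade_map.values()) - set(self.classes)
        if extra:
            raise ValueError(f"{self.name}: mapped labels not in classes: {extra}")

    def convert(self, grade: int) -> str:
        try:
            return self.grade_map[int(grade)]
        except (KeyError, ValueError):
            raise ValueError(f"grade {grade!r} outside the 0-4 scale") from None

    def convert_series(self, grades: pd.Series) -> pd.Series:
        bad = ~grades.isin(list(self.grade_map))
        if bad.any():
            raise ValueError(
                f"grades outside 0-4 at rows {list(grades.index[bad][:5])}"
            )
        return grades.map(self.grade_map)

    @property
    def centers(self) -> dict[str, float]:
        out: dict[str, list[int]] = {c: [] for c in self.classes}
        for g, c in self.grade_map.items():
            out[c].append(g)
        return {c: float(np.mean(gs)) for c, gs in out.items() if gs}


#: Eye: grades {0,1} -> blue, {2} -> intermediate, {3,4} -> brown
#: (symmetric split; the scale is configurable).
EYE_SCALE_3 = ClassScale(
    name="eye3",
    classes=("blue", "intermediate", "brown"),
    grade_map={0: "blue", 1: "blue", 2: "intermediate", 3: "brown", 4: "brown"},
)

#: Hair: 0 red, 1 blond, {2,3} brown, 4 dark.
HAIR_SCALE_4 = ClassScale(
    name="hair4",
    classes=("red", "blond", "brown", "dark"),
    grade_map={0: "red", 1: "blond", 2: "brown", 3: "brown", 4: "dark"},
)

#: Merged hair scale: blond and brown pooled into one class.
HAIR_SCALE_3 = ClassScale(
    name="hair3",
    classes=("red", MERGED_LABEL, "dark"),
    grade_map={0: "red", 1: MERGED_LABEL, 2: MERGED_LABEL,
               3: MERGED_LABEL, 4: "dark"},
)


def eye_grade_to_class(grade: int, scale: ClassScale = EYE_SCALE_3) -> str:
    """Map a 5-grade eye darkness value to the 3-class scale."""
    return scale.convert(grade)


def hair_grade_to_class4(grade: int, scale: ClassScale = HAIR_SCALE_4) -> str:
    """Map a 5-grade hair value to the 4-class scale (red/blond/brown/dark)."""
    return scale.convert(grade)


def merge_blond_brown(labels):
    """Merge the blond and brown hair classes into one combined class.

    Accepts a single 4-class label or an iterable/Series of labels.
    """
    mapping = {"red": "red", "blond": MERGED_LABEL, "brown": MERGED_LABEL,
               "dark": "dark"}

    def one(label: str) -> str:
        try:
            return mapping[label]
        except KeyError:
            raise ValueError(f"unknown hair class {label!r}") from None

    if isinstance(labels, str):
        return one(labels)
    if isinstance(labels, pd.Series):
        return labels.map(one)
    return [one(x) for x in labels]


def filter_populations_by_grade_diversity(
    phenotypes: pd.DataFrame,
    trait: str = "eye",
    min_distinct_grades: int = MIN_DISTINCT_GRADES,
) -> tuple[pd.DataFrame, list[str]]:
    """Drop populations that show fewer than ``min_distinct_grades`` distinct
    grades of the analyzed trait.

    Applied per trait: a population polymorphic for hair but monomorphic for
    eye color is removed from the eye analysis only.  Returns the filtered
    table and the removed population labels.
    """
    col = f"{trait}_grade"
    if col not in phenotypes.columns:
        raise ValueError(f"no column {col!r} in phenotype table")
    diversity = phenotypes.groupby("population")[col].nunique()
    removed = sorted(diversity.index[diversity < min_distinct_grades])
    kept = phenotypes[~phenotypes["population"].isin(removed)].copy()
    if kept.empty:
        raise ValueError(
            f"grade-diversity filter (>= {min_distinct_grades} grades) "
            f"removed every population for trait {trait!r}"
        )
    if removed:
        logger.info("grade-diversity filter removed %d populations for %s: %s",
                    len(removed), trait, ", ".join(removed[:10]))
    return kept, removed
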