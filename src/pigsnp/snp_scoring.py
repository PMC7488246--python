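"""Rule-based 0-3 SNP scoring, ledger merging, ranking and set selection.

Each dataset (the pooled cohort and each region) assigns every SNP an integer
score from declarative rules over its feature-selection provenance: top-k
ranks by F or MI, non-zero Lasso coefficients at given alphas, and absolute
coefficient thresholds.  Score 3 exists only for pooled rule sets (regional
results are less robust, so regional scores top out at 2).  A SNP satisfying
several rules gets the maximum matching score.  Per-dataset scores are summed
into a total score used to rank candidate predictive SNPs, from which a
minimal (highest-tier) and an optimal (all pooled-supported) SNP set are cut.

Rule sets are data, not code: the defaults below encode the eye (pooled and
regional) and hair rule sets, including their asymmetries (>= 0.1 vs > 0.05
coefficient thresholds, F-or-MI vs F-and-MI top ranks).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .feature_selection import FeatureScoreTable

logger = logging.getLogger(__name__)

POOLED = "pooled"


class EmptySnpSetError(ValueError):
    """Raised when a requested SNP set comes out empty."""


# ---------------------------------------------------------------------------
# Declarative rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Rule:
    """One score level: the score applies if ANY condition matches.

    Conditions are dicts with a single key:

    * ``{"top": {"metric": "f"|"mi", "k": int}}`` - rank <= k for the metric;
    * ``{"top_all": {"metrics": [...], "k": int}}`` - rank <= k for EVERY metric;
    * ``{"nonzero": {"alphas": [...]}}`` - non-zero coefficient at EVERY alpha;
    * ``{"abs_coef": {"alpha": a, "min": t, "strict": bool}}`` - |coef| >= t
      (or > t when strict) at alpha a;
    * ``{"member": true}`` - SNP belongs to the externally supplied member
      list (used for the hair best-list residual rule).
    """

    score: int
    any_of: tuple[dict, ...]


@dataclass(frozen=True)
class ScoringRuleSet:
    """Named rule list for one dataset kind and trait; max score wins."""

    name: str
    kind: str            # "pooled" | "regional"
    trait: str           # "eye" | "hair"
    rules: tuple[Rule, ...]

    def __post_init__(self) -> None:
        for rule in self.rules:
            if rule.score not in (1, 2, 3):
                raise ValueError(f"{self.name}: rule score {rule.score} not in 1-3")
            if rule.score == 3 and self.kind != POOLED:
                raise ValueError(
                    f"{self.name}: score 3 is reserved for pooled rule sets"
                )


POOLED_EYE_RULES = ScoringRuleSet(
    name="pooled_eye",
    kind="pooled",
    trait="eye",
    rules=(
        Rule(3, (
            {"top": {"metric": "f", "k": 5}},
            {"abs_coef": {"alpha": 0.2, "min": 0.1, "strict": False}},
            {"nonzero": {"alphas": [0.5]}},
        )),
        Rule(2, (
            {"top": {"metric": "f", "k": 10}},
            {"top": {"metric": "mi", "k": 10}},
            {"nonzero": {"alphas": [0.2]}},
        )),
        Rule(1, (
            {"abs_coef": {"alpha": 0.005, "min": 0.1, "strict": False}},
        )),
    ),
)

REGIONAL_EYE_RULES = ScoringRuleSet(
    name="regional_eye",
    kind="regional",
    trait="eye",
    rules=(
        Rule(2, (
            {"top_all": {"metrics": ["f", "mi"], "k": 5}},
            {"abs_coef": {"alpha": 0.5, "min": 0.1, "strict": False}},
            {"nonzero": {"alphas": [0.7]}},
        )),
        Rule(1, (
            {"top_all": {"metrics": ["f", "mi"], "k": 6}},
            {"nonzero": {"alphas": [0.7, 0.5]}},
        )),
    ),
)

#: Hair uses > 0.05 (strict) at alpha 0.2 and lets F *or* MI reach score 3;
#: every remaining member of the best list scores 1.
POOLED_HAIR_RULES = ScoringRuleSet(
    name="pooled_hair",
    kind="pooled",
    trait="hair",
    rules=(
        Rule(3, (
            {"top": {"metric": "f", "k": 5}},
            {"top": {"metric": "mi", "k": 5}},
            {"abs_coef": {"alpha": 0.2, "min": 0.05, "strict": True}},
            {"nonzero": {"alphas": [0.5]}},
        )),
        Rule(2, (
            {"top": {"metric": "f", "k": 10}},
            {"top": {"metric": "mi", "k": 10}},
        )),
        Rule(1, (
            {"member": True},
        )),
    ),
)


def _condition_mask(
    cond: dict,
    scores: FeatureScoreTable,
    members: set[str] | None,
) -> pd.Series:
    """Boolean series over all SNPs in the score table for one condition."""
    index = scores.table.index
    if len(cond) != 1:
        raise ValueError(f"condition must have exactly one key: {cond}")
    (kind, params), = cond.items()
    if kind == "top":
        ranks = scores.table[f"rank_{params['metric']}"]
        return ranks <= params["k"]
    if kind == "top_all":
        mask = pd.Series(True, index=index)
        for metric in params["metrics"]:
            mask &= scores.table[f"rank_{metric}"] <= params["k"]
        return mask
    if kind == "nonzero":
        mask = pd.Series(True, index=index)
        for a in params["alphas"]:
            mask &= pd.Series(index.isin(scores.nonzero_ids(a)), index=index)
        return mask
    if kind == "abs_coef":
        ids = scores.abs_coef_ids(
            params["alpha"], params["min"], strict=params.get("strict", False)
        )
        return pd.Series(index.isin(ids), index=index)
    if kind == "member":
        if members is None:
            raise ValueError("rule refers to a member list but none was given")
        return pd.Series(index.isin(sorted(members)), index=index)
    raise ValueError(f"unknown condition kind {kind!r}")


def assign_scores(
    scores: FeatureScoreTable,
    ruleset: ScoringRuleSet,
    members: list[str] | None = None,
) -> pd.Series:
    """Score every SNP of one dataset: max over matching rules, default 0."""
    member_set = set(members) if members is not None else None
    out = pd.Series(0, index=scores.table.index, dtype=int)
    for rule in ruleset.rules:
        mask = pd.Series(False, index=out.index)
        for cond in rule.any_of:
            mask |= _condition_mask(cond, scores, member_set)
        out = out.where(~mask | (out >= rule.score), rule.score)
    return out


def assign_pooled_eye_scores(scores: FeatureScoreTable) -> pd.Series:
    """Pooled eye rules: 3 for top-5 F / |coef| >= 0.1 at alpha 0.2 / non-zero
    at alpha 0.5; 2 for top-10 F or MI / non-zero at alpha 0.2; 1 for
    |coef| >= 0.1 at alpha 0.005."""
    return assign_scores(scores, POOLED_EYE_RULES)


def assign_regional_eye_scores(scores: FeatureScoreTable) -> pd.Series:
    """Regional eye rules (max 2): 2 for top-5 by both F and MI / |coef| >=
    0.1 at alpha 0.5 / non-zero at alpha 0.7; 1 for top-6 by both F and MI /
    non-zero at both alpha 0.7 and 0.5."""
    return assign_scores(scores, REGIONAL_EYE_RULES)


def assign_hair_scores(
    scores: FeatureScoreTable, best_members: list[str]
) -> pd.Series:
    """Pooled hair rules: 3 for top-5 F or MI / |coef| > 0.05 at alpha 0.2 /
    non-zero at alpha 0.5; 2 for top-10 F or MI; the rest of the best list
    scores 1."""
    return assign_scores(scores, POOLED_HAIR_RULES, members=best_members)


# ---------------------------------------------------------------------------
# Ledger
# ---------------------------------------------------------------------------

def merge_and_rank(ledgers: dict[str, pd.Series]) -> pd.DataFrame:
    """Merge per-dataset scores into one ledger ranked by total score.

    A SNP missing from a dataset contributes 0 there.  SNPs whose scores are
    zero everywhere are excluded.  Ties in total break by the number of
    datasets with a non-zero score (more support first), then by snp_id.
    """
    frame = pd.DataFrame(ledgers).fillna(0).astype(int)
    frame.index.name = "snp_id"
    frame["total"] = frame.sum(axis=1)
    frame["n_datasets"] = (frame.drop(columns="total") > 0).sum(axis=1)
    frame = frame[frame["total"] > 0]
    frame = frame.sort_values(
        ["total", "n_datasets", "snp_id"], ascending=[False, False, True]
    )
    return frame


def select_snp_sets(
    ledger: pd.DataFrame,
    trait: str,
    pooled_label: str = POOLED,
    min_total: int = 3,
    require_multi_dataset: bool = False,
) -> dict[str, list[str]]:
    """Cut the minimal and optimal SNP sets from a ranked ledger.

    The optimal set is every SNP with a non-zero pooled score.  The minimal
    set takes the top scoring tier: for eyes, total score >= ``min_total``
    (optionally additionally requiring support from more than one dataset);
    for hair, the maximal pooled score 3.
    """
    if pooled_label not in ledger.columns:
        raise ValueError(f"ledger has no {pooled_label!r} column")
    optimal = list(ledger.index[ledger[pooled_label] > 0])
    if trait == "eye":
        mask = ledger["total"] >= min_total
        if require_multi_dataset and "n_datasets" in ledger.columns:
            mask &= ledger["n_datasets"] >= 2
        minimal = list(ledger.index[mask])
    elif trait == "hair":
        minimal = list(ledger.index[ledger[pooled_label] >= 3])
    else:
        raise ValueError(f"unknown trait {trait!r}")
    if not optimal:
        raise EmptySnpSetError(f"optimal {trait} SNP set is empty")
    if not minimal:
        raise EmptySnpSetError(f"minimal {trait} SNP set is empty")
    return {"minimal": minimal, "optimal": optimal}


def reference_eye_score_ledger() -> pd.DataFrame:
    """Published per-dataset score matrix for 36 North Eurasian eye-color
    candidate SNPs (three regional scores plus the pooled score), shipped as
    package data.  Serves as the worked example for ranking and set
    selection: it contains exactly five SNPs with pooled score 3 and seven
    SNPs reaching total score >= 3."""
    with resources.files("pigsnp.data").joinpath(
        "eye_reference_score_ledger.tsv"
    ).open() as fh:
        raw = pd.read_csv(fh, sep="\t", dtype={"hirisplex": str})
    return raw.set_index("snp_id")


def write_ledger(ledger: pd.DataFrame, path, annotations: pd.DataFrame | None = None,
                 reference_panel: list[str] | None = None) -> None:
    """Serialize a ledger as TSV, optionally joining gene annotations and a
    flag for membership in a user-supplied reference panel of known SNPs."""
    out = ledger.copy()
    if annotations is not None:
        out = out.join(annotations, how="left")
    if reference_panel is not None:
        out["in_reference_panel"] = out.index.isin(set(reference_panel))
    out.to_csv(path, sep="\t")
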