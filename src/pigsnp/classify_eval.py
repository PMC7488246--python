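"""Stratified splitting, the linear SNP classifier, metrics, and the pipeline.

Each dataset is split 60:40 into training and test samples, stratified by
phenotype class crossed with geographic region so that every region is
represented in the same proportion inside the pooled dataset.  The classifier
is an ordinary linear regression of the 5-grade ordinal target on the 0/1/2
genotype codes of a selected SNP set; its continuous prediction is mapped to
the nearest class on the trait's class scale (ties go to the darker class).
Evaluation reports per-class one-vs-rest AUC (from the continuous score),
precision and recall (from hard classes), overall accuracy and the r^2 of the
continuous prediction, with classes below a minimum test count reported N/A.

``run_full_pipeline`` orchestrates QC, scale conversion, the population
grade-diversity filter, the split, per-dataset feature selection (regions +
pooled), rule-based scoring, SNP-set selection, classifier fitting on the
training split and evaluation on the held-out split.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import (
    accuracy_score,
    precision_score,
    r2_score,
    recall_score,
    roc_auc_score,
)

from . import data_io, feature_selection as fs, phenotype_scales as scales
from . import snp_scoring
from .phenotype_scales import ClassScale, EYE_SCALE_3, HAIR_SCALE_3, HAIR_SCALE_4
from .snp_scoring import POOLED, EmptySnpSetError

logger = logging.getLogger(__name__)

TRAIN_RATIO = 0.6
#: Classes with fewer test samples than this report N/A metrics.
MIN_CLASS_N = 10
#: Ridge penalty used when the design is rank-deficient or underdetermined.
RIDGE_FALLBACK = 1e-6

#: Regional datasets analyzed per trait; the North Asian region shows no
#: eye-color variation and enters the hair analysis only.
DEFAULT_EYE_REGIONS = ("Caucasus", "EuropeanRussia", "WestSiberia")
DEFAULT_HAIR_REGIONS = ("Caucasus", "EuropeanRussia", "WestSiberia", "NorthAsia")

#: Alpha union whose non-zero Lasso sets feed the hair best list together
#: with top-10 F/MI and the |coef| >= 0.1 rule at alpha 0.005.
BEST_LIST_ALPHAS = (0.5, 0.2)


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def stratified_split(
    phenotypes: pd.DataFrame,
    class_col: str,
    ratio: float = TRAIN_RATIO,
    seed: int = 0,
) -> pd.DataFrame:
    """Assign samples to train/test per (class x region) stratum.

    Within each stratum the train count is ``round(ratio * n)``, so every
    stratum's train fraction is within one sample of the ratio.  Strata of
    size 1 go to training with a warning.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    out = phenotypes[["sample_id", "region", class_col]].copy()
    out["stratum"] = out[class_col].astype(str) + "|" + out["region"].astype(str)
    out["is_train"] = False
    for stratum, group in out.groupby("stratum", sort=True):
        n = len(group)
        if n == 1:
            logger.warning("stratum %s has a single sample; assigned to train",
                           stratum)
            out.loc[group.index, "is_train"] = True
            continue
        n_train = int(round(ratio * n))
        n_train = min(max(n_train, 1), n - 1)
        order = rng.permutation(group.index.to_numpy())
        out.loc[order[:n_train], "is_train"] = True
    return out[["sample_id", "stratum", "is_train"]]


# ---------------------------------------------------------------------------
# Classifier
# ---------------------------------------------------------------------------

@dataclass
class ClassifierModel:
    """A linear regression of the ordinal grade on additive genotype codes."""

    snp_ids: list[str]
    coef: np.ndarray
    intercept: float
    trait: str
    ridge_fallback: bool = False

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coef + self.intercept


def fit_linear_classifier(
    X: np.ndarray, grades: np.ndarray, snp_ids: list[str], trait: str = "eye"
) -> ClassifierModel:
    """Least-squares fit of the grade on the selected SNP codes.

    When the design is underdetermined or rank-deficient (collinear SNP sets,
    e.g. variants in strong LD), a tiny ridge penalty stabilizes the solution
    and the model is flagged.
    """
    if not snp_ids:
        raise ValueError("snp_set must be non-empty")
    X = np.asarray(X, dtype=float)
    y = np.asarray(grades, dtype=float)
    n, p = X.shape
    design = np.column_stack([np.ones(n), X])
    fallback = n < p + 1
    if not fallback:
        sol, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
        fallback = rank < p + 1
    if fallback:
        logger.warning("rank-deficient or underdetermined design for %d SNPs, "
                       "n=%d: using ridge fallback", p, n)
        xm = X.mean(axis=0)
        xc = X - xm
        gram = xc.T @ xc + RIDGE_FALLBACK * np.eye(p)
        coef = np.linalg.solve(gram, xc.T @ (y - y.mean()))
        intercept = float(y.mean() - xm @ coef)
    else:
        intercept, coef = float(sol[0]), sol[1:]
    return ClassifierModel(snp_ids=list(snp_ids), coef=np.asarray(coef),
                           intercept=intercept, trait=trait,
                           ridge_fallback=bool(fallback))


def calibrate_class_centers(
    train_scores: np.ndarray,
    train_classes: np.ndarray,
    scale: ClassScale,
    min_n: int = 3,
) -> dict[str, float]:
    """Class centers as mean training prediction per true class.

    Least-squares predictions of an ordinal grade are shrunk toward the
    cohort mean, so grade-scale midpoints over-assign middle classes;
    centering each class at its mean training score corrects this without
    touching held-out data.  Classes with fewer than ``min_n`` training
    samples keep their grade-scale center.
    """
    centers = dict(scale.centers)
    train_classes = np.asarray(train_classes, dtype=object)
    for cls in scale.classes:
        mask = train_classes == cls
        if mask.sum() >= min_n:
            centers[cls] = float(np.mean(train_scores[mask]))
    return centers


def predict_and_classify(
    model: ClassifierModel,
    X: np.ndarray,
    scale: ClassScale,
    centers: dict[str, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Continuous linear score plus the nearest class on the grade axis.

    By default class centers are the mean grades mapped to each class
    (``centers`` may supply calibrated values, see
    :func:`calibrate_class_centers`); boundaries are the midpoints between
    adjacent centers, with scores exactly on a boundary assigned to the
    darker class.
    """
    score = model.predict(X)
    if centers is None:
        centers = scale.centers
    ordered = sorted(scale.classes, key=lambda c: centers[c])
    cuts = np.array([
        (centers[a] + centers[b]) / 2.0 for a, b in zip(ordered, ordered[1:])
    ])
    idx = np.searchsorted(cuts, score, side="right")
    classes = np.asarray(ordered, dtype=object)[idx]
    return score, classes


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Per-class AUC/precision/recall plus overall accuracy and r^2."""

    per_class: pd.DataFrame
    accuracy: float
    r2: float
    sample_ids: list[str]
    scale: ClassScale

    def summary(self) -> pd.DataFrame:
        out = self.per_class.copy()
        out.loc["overall", "n"] = int(out["n"].sum())
        out.loc["overall", "accuracy"] = self.accuracy
        out.loc["overall", "r2"] = self.r2
        return out


def _oriented_score(scores: np.ndarray, scale: ClassScale, cls: str,
                    centers: dict[str, float] | None = None) -> np.ndarray:
    """Orient the continuous score toward one class for one-vs-rest AUC.

    The lightest class uses the negated score, the darkest the raw score, and
    middle classes the negated absolute distance to the class center.
    """
    if centers is None:
        centers = scale.centers
    ordered = sorted(scale.classes, key=lambda c: centers[c])
    if cls == ordered[0]:
        return -scores
    if cls == ordered[-1]:
        return scores
    return -np.abs(scores - centers[cls])


def evaluate(
    scores,
    hard_classes: np.ndarray,
    true_classes: np.ndarray,
    scale: ClassScale,
    min_class_n: int = MIN_CLASS_N,
    true_grades: np.ndarray | None = None,
    sample_ids: list[str] | None = None,
    centers: dict[str, float] | None = None,
) -> EvaluationReport:
    """Per-class one-vs-rest metrics on a test set.

    ``scores`` may be a 1-D continuous prediction (oriented per class as
    documented in :func:`_oriented_score`) or a DataFrame of per-class
    probabilities (columns = class labels), in which case each class's own
    probability is used directly.  Classes with fewer than ``min_class_n``
    test samples are reported N/A; AUC is also N/A when a class is absent or
    fills the whole test set.  ``r2`` compares the continuous prediction with
    ``true_grades`` when given (ordinal 5-grade truth), else with the class
    centers of the true classes; it is NaN for probability-table input.
    """
    true_classes = np.asarray(true_classes, dtype=object)
    hard_classes = np.asarray(hard_classes, dtype=object)
    n = true_classes.size
    if n == 0:
        raise ValueError("test set is empty")
    prob_input = isinstance(scores, pd.DataFrame)

    rows = []
    for cls in scale.classes:
        positives = true_classes == cls
        n_cls = int(positives.sum())
        row = {"class": cls, "n": n_cls, "auc": np.nan,
               "precision": np.nan, "recall": np.nan}
        if n_cls >= min_class_n:
            if 0 < n_cls < n:
                oriented = (
                    scores[cls].to_numpy()
                    if prob_input
                    else _oriented_score(np.asarray(scores, dtype=float),
                                         scale, cls, centers)
                )
                if not np.isnan(oriented).any():
                    row["auc"] = roc_auc_score(positives, oriented)
            row["precision"] = precision_score(
                positives, hard_classes == cls, zero_division=0.0
            )
            row["recall"] = recall_score(
                positives, hard_classes == cls, zero_division=0.0
            )
        rows.append(row)
    per_class = pd.DataFrame(rows).set_index("class")

    accuracy = accuracy_score(true_classes, hard_classes)
    if prob_input:
        r2 = np.nan
    else:
        centers = scale.centers
        target = (np.asarray(true_grades, dtype=float)
                  if true_grades is not None
                  else np.array([centers[c] for c in true_classes]))
        r2 = r2_score(target, np.asarray(scores, dtype=float))
    return EvaluationReport(
        per_class=per_class,
        accuracy=float(accuracy),
        r2=float(r2),
        sample_ids=list(sample_ids) if sample_ids is not None else [],
        scale=scale,
    )


def read_external_predictions(path: str) -> pd.DataFrame:
    """Read an external panel's predictions: sample_id, predicted_class and
    optional per-class probability columns named ``prob_<class>``."""
    table = pd.read_csv(path, dtype={"sample_id": str})
    for col in ("sample_id", "predicted_class"):
        if col not in table.columns:
            raise ValueError(f"external prediction table missing column {col!r}")
    return table


def evaluate_external(
    predictions: pd.DataFrame,
    truth: pd.DataFrame,
    class_col: str,
    scale: ClassScale,
    min_class_n: int = MIN_CLASS_N,
) -> EvaluationReport:
    """Run externally produced predictions through the same evaluation path.

    ``truth`` must carry sample_id and the true class column; every truth
    sample must be present in the predictions (mismatches raise, listing the
    discrepancies).
    """
    missing = sorted(set(truth["sample_id"]) - set(predictions["sample_id"]))
    if missing:
        raise ValueError(f"external predictions missing samples: {missing[:10]}")
    pred = predictions.set_index("sample_id").loc[list(truth["sample_id"])]
    prob_cols = {c: f"prob_{c}" for c in scale.classes}
    have_probs = all(col in pred.columns for col in prob_cols.values())
    scores = (
        pred[[prob_cols[c] for c in scale.classes]]
        .rename(columns={v: k for k, v in prob_cols.items()})
        if have_probs
        else pd.DataFrame(
            {c: np.full(len(pred), np.nan) for c in scale.classes},
            index=pred.index,
        )
    )
    return evaluate(
        scores,
        pred["predicted_class"].to_numpy(),
        truth[class_col].to_numpy(),
        scale,
        min_class_n=min_class_n,
        sample_ids=list(truth["sample_id"]),
    )


def compare_panels(
    report_a: EvaluationReport, report_b: EvaluationReport
) -> pd.DataFrame:
    """Side-by-side per-class metrics of two panels on the same test set.

    Requires identical test samples and class scale; deltas are b - a.
    """
    if report_a.scale.classes != report_b.scale.classes:
        raise ValueError("reports use different class scales")
    if report_a.sample_ids != report_b.sample_ids:
        only_a = set(report_a.sample_ids) - set(report_b.sample_ids)
        only_b = set(report_b.sample_ids) - set(report_a.sample_ids)
        raise ValueError(
            f"test samples differ: {sorted(only_a)[:5]} only in a, "
            f"{sorted(only_b)[:5]} only in b"
        )
    a, b = report_a.per_class, report_b.per_class
    out = pd.DataFrame(index=a.index)
    for metric in ("auc", "precision", "recall"):
        out[f"{metric}_a"] = a[metric]
        out[f"{metric}_b"] = b[metric]
        out[f"{metric}_delta"] = b[metric] - a[metric]
    out.loc["overall", "accuracy_a"] = report_a.accuracy
    out.loc["overall", "accuracy_b"] = report_b.accuracy
    out.loc["overall", "accuracy_delta"] = report_b.accuracy - report_a.accuracy
    return out


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """End-to-end run configuration (paths, QC, selection and scoring knobs)."""

    vcf: str
    phenotypes: str
    trait: str = "eye"
    regions: tuple[str, ...] | None = None   # None -> trait default, then all
    qual_min: float = data_io.QUAL_MIN
    dp_min: float = data_io.DP_MIN
    min_call_rate: float = data_io.MIN_CALL_RATE
    min_distinct_grades: int = scales.MIN_DISTINCT_GRADES
    train_ratio: float = TRAIN_RATIO
    alphas: tuple[float, ...] = fs.ALPHA_GRID
    top_k: int = fs.TOP_K
    k_neighbors: int = fs.K_NEIGHBORS
    p_threshold: float = fs.P_THRESHOLD
    min_class_n: int = MIN_CLASS_N
    score_regional: bool | None = None       # None -> eye True, hair False

    def __post_init__(self) -> None:
        if self.trait not in ("eye", "hair"):
            raise ValueError(f"trait must be 'eye' or 'hair', got {self.trait!r}")
        if self.score_regional is None:
            self.score_regional = self.trait == "eye"

    def config_hash(self) -> str:
        payload = {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(self).items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def _trait_regions(config: PipelineConfig, present: list[str]) -> list[str]:
    if config.regions is not None:
        wanted = [r for r in config.regions if r in present]
    else:
        default = (DEFAULT_EYE_REGIONS if config.trait == "eye"
                   else DEFAULT_HAIR_REGIONS)
        wanted = [r for r in default if r in present]
        if not wanted:
            wanted = sorted(present)
    if not wanted:
        raise ValueError(f"none of the configured regions present: {present}")
    return wanted


def build_best_snp_list(scores: fs.FeatureScoreTable) -> list[str]:
    """Narrow a pooled top list to the best SNPs: top-10 F, top-10 MI,
    non-zero at alphas 0.5 and 0.2, and |coef| >= 0.1 at alpha 0.005."""
    best: set[str] = set(scores.top_ids("f", 10)) | set(scores.top_ids("mi", 10))
    for a in BEST_LIST_ALPHAS:
        best |= set(scores.nonzero_ids(a))
    best |= set(scores.abs_coef_ids(0.005, 0.1, strict=False))
    return sorted(best)


def run_full_pipeline(
    config: PipelineConfig,
    seed: int = 0,
    out_dir: str | None = None,
    split: pd.DataFrame | None = None,
) -> dict:
    """Run QC -> scales -> diversity filter -> split -> selection -> scoring
    -> set selection -> classification -> evaluation; returns all artifacts.

    ``split`` may supply a precomputed train/test assignment (e.g. to keep a
    split paired across panels being compared); by default the seeded
    stratified split is drawn here.
    """
    trait = config.trait
    grade_col = f"{trait}_grade"

    # --- QC and alignment
    callset = data_io.read_vcf(config.vcf)
    callset = data_io.filter_variants(callset, config.qual_min, config.dp_min)
    if not callset.records:
        raise data_io.EmptyCohortError("variant QC removed every SNP")
    matrix = data_io.encode_genotypes(callset)
    matrix, dropped_samples = data_io.filter_samples_by_call_rate(
        matrix, config.min_call_rate
    )
    pheno = data_io.read_phenotypes(config.phenotypes, matrix.sample_ids)
    matrix, pheno = data_io.align_samples(matrix, pheno)

    # --- regions and grade diversity
    regions = _trait_regions(config, sorted(pheno["region"].unique()))
    pheno = pheno[pheno["region"].isin(regions)].reset_index(drop=True)
    pheno, removed_populations = scales.filter_populations_by_grade_diversity(
        pheno, trait=trait, min_distinct_grades=config.min_distinct_grades
    )
    pheno = pheno.reset_index(drop=True)
    matrix = matrix.subset_samples(list(pheno["sample_id"]))

    # --- class labels and split
    class_scale = EYE_SCALE_3 if trait == "eye" else HAIR_SCALE_4
    pheno = pheno.copy()
    pheno["class"] = class_scale.convert_series(pheno[grade_col])
    if split is None:
        split = stratified_split(pheno, "class", config.train_ratio, seed)
    split = split.set_index("sample_id").loc[pheno["sample_id"]].reset_index()
    train_ids = list(split.loc[split["is_train"], "sample_id"])
    test_ids = list(split.loc[~split["is_train"], "sample_id"])

    imputed = data_io.impute_missing(matrix, train_ids)
    train_pheno = pheno.set_index("sample_id").loc[train_ids]
    test_pheno = pheno.set_index("sample_id").loc[test_ids]
    X_train_full = imputed.subset_samples(train_ids)
    y_train = train_pheno[grade_col].to_numpy(dtype=float)

    # --- per-dataset feature selection
    dataset_labels = [POOLED] + (regions if config.score_regional else [])
    score_tables: dict[str, fs.FeatureScoreTable] = {}
    top_lists: dict[str, fs.TopSnpList] = {}
    for i, label in enumerate(dataset_labels):
        if label == POOLED:
            rows = list(train_pheno.index)
        else:
            rows = list(train_pheno.index[train_pheno["region"] == label])
        sub = X_train_full.subset_samples(rows)
        y = train_pheno.loc[rows, grade_col].to_numpy(dtype=float)
        scores = fs.compute_feature_scores(
            sub.codes, y, sub.snp_ids,
            alphas=config.alphas,
            k_neighbors=config.k_neighbors,
            p_threshold=config.p_threshold,
            seed=(seed + 1000 * (i + 1)) % (2**31 - 1),
        )
        score_tables[label] = scores
        top_lists[label] = fs.build_top_snp_list(scores, label, top_k=config.top_k)

    # --- scoring and set selection
    ledgers: dict[str, pd.Series] = {}
    if trait == "eye":
        ledgers[POOLED] = snp_scoring.assign_pooled_eye_scores(score_tables[POOLED])
        for label in dataset_labels[1:]:
            ledgers[label] = snp_scoring.assign_regional_eye_scores(
                score_tables[label]
            )
    else:
        best = build_best_snp_list(score_tables[POOLED])
        ledgers[POOLED] = snp_scoring.assign_hair_scores(score_tables[POOLED], best)
        for label in dataset_labels[1:]:
            ledgers[label] = snp_scoring.assign_regional_eye_scores(
                score_tables[label]
            )
    ledger = snp_scoring.merge_and_rank(ledgers)

    empty_sets_warning = None
    try:
        snp_sets = snp_scoring.select_snp_sets(ledger, trait)
    except EmptySnpSetError as err:
        empty_sets_warning = str(err)
        logger.warning("SNP set selection failed: %s", empty_sets_warning)
        snp_sets = {"minimal": [], "optimal": []}

    # --- classification and evaluation
    models: dict[str, ClassifierModel] = {}
    reports: dict[str, EvaluationReport] = {}
    X_test_full = imputed.subset_samples(test_ids)
    y_test = test_pheno[grade_col].to_numpy(dtype=float)
    eval_scales = ([EYE_SCALE_3] if trait == "eye"
                   else [HAIR_SCALE_4, HAIR_SCALE_3])
    for set_name, snp_ids in snp_sets.items():
        if not snp_ids:
            continue
        X_tr = X_train_full.subset_snps(snp_ids).codes
        X_te = X_test_full.subset_snps(snp_ids).codes
        model = fit_linear_classifier(X_tr, y_train, snp_ids, trait=trait)
        models[set_name] = model
        train_scores = model.predict(X_tr)
        for scale in eval_scales:
            train_classes = scale.convert_series(train_pheno[grade_col]).to_numpy()
            centers = calibrate_class_centers(train_scores, train_classes, scale)
            score, hard = predict_and_classify(model, X_te, scale, centers=centers)
            truth = scale.convert_series(test_pheno[grade_col]).to_numpy()
            reports[f"{set_name}_{scale.name}"] = evaluate(
                score, hard, truth, scale,
                min_class_n=config.min_class_n,
                true_grades=y_test,
                sample_ids=test_ids,
                centers=centers,
            )

    manifest = {
        "seed": seed,
        "trait": trait,
        "config_hash": config.config_hash(),
        "n_samples": matrix.n_samples,
        "n_snps": matrix.n_snps,
        "n_train": len(train_ids),
        "n_test": len(test_ids),
        "regions": regions,
        "dropped_samples": dropped_samples,
        "removed_populations": removed_populations,
        "empty_sets_warning": empty_sets_warning,
        "snp_set_sizes": {k: len(v) for k, v in snp_sets.items()},
    }
    result = {
        "split": split,
        "phenotypes": pheno,
        "score_tables": score_tables,
        "top_lists": top_lists,
        "ledger": ledger,
        "snp_sets": snp_sets,
        "models": models,
        "reports": reports,
        "manifest": manifest,
    }
    if out_dir is not None:
        _write_artifacts(result, out_dir)
    return result


def _write_artifacts(result: dict, out_dir: str) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    snp_scoring.write_ledger(result["ledger"], out / "score_ledger.tsv")
    for name, ids in result["snp_sets"].items():
        (out / f"snp_set_{name}.txt").write_text("\n".join(ids) + "\n")
    for name, report in result["reports"].items():
        report.summary().to_csv(out / f"metrics_{name}.tsv", sep="\t")
    for label, scores in result["score_tables"].items():
        scores.to_frame().to_csv(out / f"feature_scores_{label}.tsv", sep="\t")
    result["split"].to_csv(out / "split.tsv", sep="\t", index=False)
    with open(out / "provenance.json", "w") as fh:
        json.dump(result["manifest"], fh, indent=1, sort_keys=True)
        fh.write("\n")
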