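"""Per-class signature gene set identification from a labeled reference.

The model behind the selection: each gene's log expression decomposes into
an ambient level, a class-specific additive effect, and zero-mean Gaussian
noise. A per-gene one-way fixed-effects ANOVA tests whether any class
effect is nonzero; Benjamini-Hochberg adjustment controls the false
discovery rate over the ~10^4 genes tested. Each significant gene becomes
a *candidate* for exactly one class — the class where its absolute mean
(centered log) expression is largest — and three expression filters then
prune candidates:

1. the candidate's class must have the largest absolute average expression
   for that gene (guaranteed by the candidate assignment);
2. the gap between the class mean and the mean over all remaining samples
   must be at least ``t1``;
3. the absolute class mean must be at least ``t2``.

``t1``/``t2`` are in log-expression units. A grid search scores each
threshold pair by self-classification: the resulting gene sets are used to
re-label the reference with the unsupervised predictor and compared with
the known labels.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dataio import LabeledDataset


def _default_grid() -> list[tuple[float, float]]:
    axis = [round(0.1 * i, 1) for i in range(1, 11)]
    return list(product(axis, axis))


@dataclass
class SelectionConfig:
    """Tunable knobs of the selection step.

    fdr_level : BH-adjusted significance level for the per-gene ANOVA.
    t1 : lower limit on |class mean - rest mean| (log-expression units).
    t2 : lower limit on the absolute class mean (log-expression units).
    grid : (t1, t2) pairs searched by :func:`grid_search_thresholds`;
        defaults to {0.1, ..., 1.0}^2 in steps of 0.1.
    rest_mean : "pooled" (mean over all non-class samples) or "macro"
        (unweighted mean of the other class means).
    """

    fdr_level: float = 0.05
    t1: float = 0.1
    t2: float = 0.8
    grid: list[tuple[float, float]] = field(default_factory=_default_grid)
    rest_mean: str = "pooled"

    def __post_init__(self):
        if not 0.0 < self.fdr_level < 1.0:
            raise ValueError("fdr_level must lie in (0, 1)")
        if self.t1 < 0 or self.t2 < 0:
            raise ValueError("thresholds must be non-negative")
        if not self.grid:
            raise ValueError("threshold grid must be non-empty")
        if self.rest_mean not in ("pooled", "macro"):
            raise ValueError("rest_mean must be 'pooled' or 'macro'")


@dataclass
class AnovaResult:
    """Per-gene one-way ANOVA over the reference classes.

    ``stats`` holds one row per gene with columns F, p, q (BH-adjusted)
    and ``degenerate`` (True where the gene shows no variation at all, in
    which case p is set to 1: no evidence either way).
    """

    stats: pd.DataFrame
    class_means: pd.DataFrame  # genes x classes
    grand_mean: pd.Series
    class_sizes: pd.Series

    @property
    def genes(self) -> pd.Index:
        return self.stats.index

    @property
    def class_names(self) -> list[str]:
        return list(self.class_means.columns)


def anova_per_gene(dataset: LabeledDataset) -> AnovaResult:
    """One-way fixed-effects ANOVA F test, gene by gene.

    Genes with zero between-class and zero within-class variance carry no
    information; they get F = 0, p = 1 and are flagged ``degenerate``.
    """
    X = dataset.matrix
    groups = [X[dataset.samples_of(c)].to_numpy() for c in dataset.class_names]
    with warnings.catch_warnings():
        # constant rows make scipy warn; they are repaired just below
        warnings.simplefilter("ignore")
        F, p = stats.f_oneway(*groups, axis=1)
    F = np.asarray(F, dtype=float)
    p = np.asarray(p, dtype=float)

    values = X.to_numpy()
    no_variation = np.ptp(values, axis=1) == 0
    repair = no_variation | ~np.isfinite(p)
    F[repair & ~np.isfinite(F)] = 0.0
    F[no_variation] = 0.0
    p[repair] = 1.0

    q = bh_fdr(p)
    table = pd.DataFrame(
        {"F": F, "p": p, "q": q, "degenerate": no_variation}, index=X.index
    )
    class_means = pd.DataFrame(
        {c: g.mean(axis=1) for c, g in zip(dataset.class_names, groups)}, index=X.index
    )
    class_sizes = pd.Series(
        {c: g.shape[1] for c, g in zip(dataset.class_names, groups)}, name="n"
    )
    return AnovaResult(table, class_means, X.mean(axis=1), class_sizes)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, order-aligned with input."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-d sequence")
    if not np.all(np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def assign_candidate_class(anova: AnovaResult, fdr_level: float) -> pd.Series:
    """Map each significant gene (q < fdr_level) to its candidate class.

    The candidate class is the one with the largest absolute class mean;
    exact ties go to the lowest class index and are reported in a warning.
    """
    sig = anova.stats.index[anova.stats["q"] < fdr_level]
    if len(sig) == 0:
        return pd.Series(dtype=object, name="candidate_class")
    absmeans = anova.class_means.loc[sig].abs()
    best = absmeans.idxmax(axis=1)  # first (lowest-index) class wins ties
    n_ties = int((absmeans.eq(absmeans.max(axis=1), axis=0).sum(axis=1) > 1).sum())
    if n_ties:
        warnings.warn(f"{n_ties} gene(s) had tied absolute class means; lowest class index kept")
    return best.rename("candidate_class")


def _rest_means(anova: AnovaResult, genes: pd.Index, class_name: str, how: str) -> pd.Series:
    if how == "pooled":
        n_total = int(anova.class_sizes.sum())
        n_k = int(anova.class_sizes[class_name])
        total = anova.grand_mean.loc[genes] * n_total
        return (total - anova.class_means.loc[genes, class_name] * n_k) / (n_total - n_k)
    return anova.class_means.loc[genes].drop(columns=class_name).mean(axis=1)


def filter_candidates(
    candidates: pd.Series,
    anova: AnovaResult,
    t1: float,
    t2: float,
    rest_mean: str = "pooled",
) -> dict[str, list[str]]:
    """Apply the two threshold filters; returns per-class gene lists.

    A candidate for class k survives iff |mean_k - mean_rest| >= t1 and
    |mean_k| >= t2 (condition 1, largest absolute class mean, already
    holds by construction of the candidate assignment). Gene lists stay
    disjoint across classes and keep the input gene order.
    """
    gene_sets: dict[str, list[str]] = {c: [] for c in anova.class_names}
    for c in anova.class_names:
        genes = candidates.index[candidates == c]
        if len(genes) == 0:
            continue
        mk = anova.class_means.loc[genes, c]
        rest = _rest_means(anova, genes, c, rest_mean)
        keep = ((mk - rest).abs() >= t1) & (mk.abs() >= t2)
        gene_sets[c] = list(genes[keep])
    empty = [c for c, g in gene_sets.items() if not g]
    if empty:
        warnings.warn(f"empty signature gene set for class(es): {empty}")
    return gene_sets


@dataclass
class SignatureModel:
    """Per-class signature gene sets plus the metadata needed to reuse them."""

    class_names: list[str]
    gene_sets: dict[str, list[str]]
    class_means: dict[str, dict[str, float]]  # class -> gene -> reference mean
    fdr_level: float
    t1: float
    t2: float
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        seen: set[str] = set()
        for c in self.class_names:
            genes = self.gene_sets.get(c, [])
            overlap = seen & set(genes)
            if overlap:
                raise ValueError(f"gene(s) assigned to multiple classes: {sorted(overlap)[:5]}")
            seen |= set(genes)

    @property
    def all_genes(self) -> list[str]:
        return [g for c in self.class_names for g in self.gene_sets[c]]

    @property
    def n_genes(self) -> int:
        return len(self.all_genes)

    @property
    def empty_classes(self) -> list[str]:
        return [c for c in self.class_names if not self.gene_sets[c]]

    def to_dict(self) -> dict:
        return {
            "class_names": list(self.class_names),
            "fdr_level": self.fdr_level,
            "T1": self.t1,
            "T2": self.t2,
            "classes": {
                c: {
                    "genes": list(self.gene_sets[c]),
                    "reference_class_means": dict(self.class_means[c]),
                }
                for c in self.class_names
            },
            "diagnostics": dict(self.diagnostics),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SignatureModel":
        classes = d["classes"]
        return cls(
            class_names=list(d["class_names"]),
            gene_sets={c: list(classes[c]["genes"]) for c in d["class_names"]},
            class_means={c: dict(classes[c]["reference_class_means"]) for c in d["class_names"]},
            fdr_level=float(d["fdr_level"]),
            t1=float(d["T1"]),
            t2=float(d["T2"]),
            diagnostics=dict(d.get("diagnostics", {})),
        )


def _model_from_gene_sets(
    gene_sets: dict[str, list[str]],
    anova: AnovaResult,
    config: SelectionConfig,
    t1: float,
    t2: float,
    n_candidates: int,
) -> SignatureModel:
    class_means = {
        c: {g: float(anova.class_means.loc[g, c]) for g in gene_sets[c]}
        for c in anova.class_names
    }
    selected = [g for c in anova.class_names for g in gene_sets[c]]
    smallest = (
        float(min(abs(class_means[c][g]) for c in anova.class_names for g in gene_sets[c]))
        if selected
        else float("nan")
    )
    return SignatureModel(
        class_names=anova.class_names,
        gene_sets=gene_sets,
        class_means=class_means,
        fdr_level=config.fdr_level,
        t1=t1,
        t2=t2,
        diagnostics={
            "n_candidates": n_candidates,
            "n_selected": len(selected),
            "smallest_abs_class_mean": smallest,
            "empty_classes": [c for c in anova.class_names if not gene_sets[c]],
        },
    )


def grid_search_thresholds(
    dataset: LabeledDataset,
    config: SelectionConfig,
    seed: int = 17,
    anova: AnovaResult | None = None,
) -> tuple[float, float, pd.DataFrame]:
    """Score every (t1, t2) pair by reference self-classification accuracy.

    For each pair the gene sets are rebuilt and the unsupervised predictor
    is applied back to the reference dataset; accuracy against the known
    labels is the objective. Ties favour the pair selecting more genes,
    then the lexicographically smaller (t1, t2). Returns the winning pair
    and the full table (t1, t2, n_genes, smallest absolute class mean,
    accuracy).
    """
    from .class_prediction import predict  # deferred: predictor uses SignatureModel

    if anova is None:
        anova = anova_per_gene(dataset)
    candidates = assign_candidate_class(anova, config.fdr_level)
    rows = []
    for t1, t2 in config.grid:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # empty-class warnings are expected mid-search
            gene_sets = filter_candidates(candidates, anova, t1, t2, config.rest_mean)
            n_genes = sum(len(g) for g in gene_sets.values())
            if n_genes == 0:
                acc, smallest = 0.0, float("nan")
            else:
                model = _model_from_gene_sets(gene_sets, anova, config, t1, t2, len(candidates))
                result = predict(dataset.matrix, model, seed=seed)
                acc = float((result.labels == dataset.labels).mean())
                smallest = model.diagnostics["smallest_abs_class_mean"]
        rows.append({"t1": t1, "t2": t2, "n_genes": n_genes,
                     "smallest_abs_class_mean": smallest, "accuracy": acc})
    table = pd.DataFrame(rows)
    order = table.sort_values(
        by=["accuracy", "n_genes", "t1", "t2"], ascending=[False, False, True, True]
    )
    best = order.iloc[0]
    return float(best["t1"]), float(best["t2"]), table


def build_signature_model(
    dataset: LabeledDataset,
    config: SelectionConfig | None = None,
    seed: int = 17,
    grid_search: bool = False,
) -> SignatureModel:
    """Full selection pipeline: ANOVA -> BH FDR -> candidate assignment -> filters.

    With ``grid_search=True`` the (t1, t2) pair is chosen by
    :func:`grid_search_thresholds` over ``config.grid``; otherwise
    ``config.t1``/``config.t2`` are used as given. One signature gene set
    is returned per class (possibly empty, with a warning).
    """
    config = config or SelectionConfig()
    anova = anova_per_gene(dataset)
    if grid_search:
        t1, t2, table = grid_search_thresholds(dataset, config, seed=seed, anova=anova)
    else:
        t1, t2, table = config.t1, config.t2, None
    candidates = assign_candidate_class(anova, config.fdr_level)
    gene_sets = filter_candidates(candidates, anova, t1, t2, config.rest_mean)
    model = _model_from_gene_sets(gene_sets, anova, config, t1, t2, len(candidates))
    if table is not None:
        model.diagnostics["grid_search"] = table.to_dict(orient="list")
    return model
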