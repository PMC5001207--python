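"""Unsupervised label transfer via per-class 2-means clustering.

For each class, the samples of the prediction dataset are clustered into
two groups (k-means, k=2, Euclidean) in the subspace spanned by that
class's signature genes. The cluster with the higher absolute average
signature expression is the *target* cluster — presumed to hold that
class's samples — because the signature is, by construction, uniquely
shifted in its own class under any condition; the other cluster is the
*non-target*. A per-gene additive condition bias translates every sample
by the same vector and therefore leaves the partition untouched, which is
what makes the transfer robust across conditions.

Each sample is reduced, per class, to a scalar *summary*: the mean of its
expression over the class's signature genes, each gene first aligned to
the direction of its reference class mean (a gene depressed in its class
counts its depression positively). Without alignment, a signature mixing
up- and down-regulated genes averages toward zero in exactly the samples
that express it, and the target call degenerates to chance; with it, the
summary is high precisely in the signature's own class under any additive
condition bias.

A sample claimed by several target clusters is adjudicated by the
confidence score S = p1 * p2, where, writing x for the sample's summary:

* p1 = -log N(x; mu_nt, sigma_nt) — how implausible the sample is under
  the non-target cluster's normal model (a distance from its center);
* p2 = -log p_t — the two-sided pooled-variance two-sample t-test p-value
  for the separation of the two cluster means (df = n1 + n2 - 2), a
  cluster-level quantity shared by all samples of that class.

Both factors are floored so that S >= 0 and finite: densities and
p-values at 1e-300, p1 at 0.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .dataio import DataError
from .signature_selection import SignatureModel

EPS_SIGMA = 1e-6  # stand-in spread for singleton / zero-variance clusters
PROB_FLOOR = 1e-300


@dataclass
class ClusterSplit:
    """A per-class 2-means split with normal summaries of both clusters."""

    class_name: str
    is_target: pd.Series  # bool per sample
    mu_t: float
    sigma_t: float
    n_t: int
    mu_nt: float
    sigma_nt: float
    n_nt: int
    s_p: float  # pooled standard deviation
    df: int
    flags: list[str] = field(default_factory=list)


@dataclass
class PredictionResult:
    """Per-sample candidate calls, confidence scores and final labels."""

    labels: pd.Series
    status: pd.Series  # unique-call | multi-call-resolved | fallback | unassigned
    candidates: pd.DataFrame  # bool, samples x classes
    p1: pd.DataFrame  # samples x classes
    p2: pd.Series  # per class (cluster-level)
    scores: pd.DataFrame  # S = p1 * p2, samples x classes
    splits: dict[str, ClusterSplit]
    flags: list[str] = field(default_factory=list)

    def scores_long(self) -> pd.DataFrame:
        """Long-format score table: sample, class, p1, p2, S, is_candidate."""
        rows = []
        for s in self.scores.index:
            for c in self.scores.columns:
                rows.append({
                    "sample_id": s, "class": c,
                    "p1": self.p1.loc[s, c], "p2": self.p2[c],
                    "S": self.scores.loc[s, c],
                    "is_candidate": bool(self.candidates.loc[s, c]),
                })
        return pd.DataFrame(rows)


def _intersect_genes(prediction: pd.DataFrame, gene_set) -> list[str]:
    present = set(prediction.index)
    genes = [g for g in gene_set if g in present]
    if len(genes) < len(gene_set):
        warnings.warn(
            f"{len(gene_set) - len(genes)} signature gene(s) absent from the "
            "prediction matrix; using the intersection"
        )
    return genes


def signature_summaries(
    prediction: pd.DataFrame, genes: list[str], gene_signs: pd.Series | None = None
) -> pd.Series:
    """Per-sample scalar summary: mean expression over the signature genes.

    ``gene_signs`` (+1/-1 per gene, from the sign of the reference class
    mean) aligns each gene's direction first; without it the plain mean is
    used.
    """
    block = prediction.loc[genes]
    if gene_signs is not None:
        block = block.mul(gene_signs.reindex(genes).fillna(1.0), axis=0)
    return block.mean(axis=0)


def reference_gene_signs(model: SignatureModel, class_name: str) -> pd.Series:
    """Direction of each signature gene in its class (+1 for mean >= 0)."""
    means = model.class_means[class_name]
    return pd.Series({g: (1.0 if m >= 0 else -1.0) for g, m in means.items()})


def cluster_by_signature(
    prediction: pd.DataFrame, gene_set, seed: int = 17
) -> pd.Series:
    """2-means partition of the samples in the signature-gene subspace.

    Euclidean distance, k-means++ initialisation, 10 restarts, best
    inertia kept; fully deterministic given ``seed``. Returns a 0/1
    cluster id per sample.
    """
    if prediction.shape[1] < 2:
        raise DataError("unsupervised prediction needs multiple samples")
    genes = _intersect_genes(prediction, gene_set)
    if not genes:
        raise DataError("no common genes between the signature set and the prediction matrix")
    X = prediction.loc[genes].T.to_numpy()
    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(X)
    return pd.Series(km.labels_, index=prediction.columns, name="cluster")


def _summary_stats(values: np.ndarray, flags: list[str], side: str) -> tuple[float, float]:
    mu = float(values.mean())
    if values.size < 2:
        flags.append(f"singleton-{side}-cluster")
        return mu, EPS_SIGMA
    sigma = float(values.std(ddof=1))
    if sigma == 0.0:
        flags.append(f"zero-variance-{side}-cluster")
        sigma = EPS_SIGMA
    return mu, sigma


def call_target_cluster(
    assignment: pd.Series,
    prediction: pd.DataFrame,
    gene_set,
    class_name: str = "",
    gene_signs: pd.Series | None = None,
) -> ClusterSplit:
    """Pick the target cluster and fill both clusters' normal summaries.

    Each sample is reduced to its summary (see
    :func:`signature_summaries`) and the cluster whose member summaries
    have the higher absolute mean is the target. Exact ties go to
    cluster 0 and are flagged.
    """
    genes = _intersect_genes(prediction, gene_set)
    summaries = signature_summaries(prediction, genes, gene_signs)
    flags: list[str] = []
    member = {cid: summaries[assignment == cid].to_numpy() for cid in (0, 1)}
    score = {cid: abs(v.mean()) for cid, v in member.items()}
    if score[0] == score[1]:
        flags.append("target-call-tie")
        target = 0
    else:
        target = 0 if score[0] > score[1] else 1
    non_target = 1 - target

    mu_t, sigma_t = _summary_stats(member[target], flags, "target")
    mu_nt, sigma_nt = _summary_stats(member[non_target], flags, "non-target")
    n_t, n_nt = member[target].size, member[non_target].size
    df = n_t + n_nt - 2
    if df > 0:
        s_p = float(
            np.sqrt(((n_t - 1) * sigma_t**2 + (n_nt - 1) * sigma_nt**2) / df)
        )
    else:
        flags.append("no-degrees-of-freedom")
        s_p = EPS_SIGMA
    return ClusterSplit(
        class_name=class_name,
        is_target=(assignment == target).rename("is_target"),
        mu_t=mu_t, sigma_t=sigma_t, n_t=n_t,
        mu_nt=mu_nt, sigma_nt=sigma_nt, n_nt=n_nt,
        s_p=s_p, df=df, flags=flags,
    )


def separation_log_score(split: ClusterSplit) -> float:
    """p2: -log of the two-sided pooled-variance two-sample t-test p-value.

    Measures how far apart the target and non-target cluster means are;
    identical means give p = 1, hence p2 = 0 and no confidence. This is a
    cluster-level quantity: every sample of the class shares it.
    """
    if split.df <= 0:
        return 0.0
    sp = max(split.s_p, EPS_SIGMA)
    t = (split.mu_t - split.mu_nt) / (sp * np.sqrt(1.0 / split.n_t + 1.0 / split.n_nt))
    pval = 2.0 * stats.t.sf(abs(t), split.df)
    pval = min(max(pval, PROB_FLOOR), 1.0)
    return float(-np.log(pval))


def confidence_score(sample_summary: float, split: ClusterSplit) -> tuple[float, float, float]:
    """(p1, p2, S) for one sample against one class split.

    p1 is -log of the non-target normal density at the sample's summary,
    floored at 0 so that very high densities (sigma << 1) cannot flip the
    sign of S; p2 comes from :func:`separation_log_score`.
    """
    if not np.isfinite(sample_summary):
        raise ValueError("sample summary must be finite")
    sigma_nt = max(split.sigma_nt, EPS_SIGMA)
    dens = stats.norm.pdf(sample_summary, loc=split.mu_nt, scale=sigma_nt)
    p1 = max(0.0, float(-np.log(max(dens, PROB_FLOOR))))
    p2 = separation_log_score(split)
    return p1, p2, p1 * p2


def resolve_labels(
    candidates: pd.DataFrame,
    scores: pd.DataFrame,
    fallback: str = "argmax",
) -> tuple[pd.Series, pd.Series]:
    """Adjudicate multi-call and zero-call samples.

    One candidate -> that label. Several -> the candidate with the highest
    confidence score (ties: lowest class index). None -> the overall score
    argmax when ``fallback='argmax'`` (status "fallback"), or the literal
    label "unassigned" when ``fallback='unassigned'``.
    """
    if fallback not in ("argmax", "unassigned"):
        raise ValueError("fallback must be 'argmax' or 'unassigned'")
    class_order = list(scores.columns)
    labels, status = {}, {}
    for s in candidates.index:
        cand = [c for c in class_order if candidates.loc[s, c]]
        if len(cand) == 1:
            labels[s], status[s] = cand[0], "unique-call"
        elif len(cand) > 1:
            row = scores.loc[s, cand]
            labels[s] = cand[int(np.argmax(row.to_numpy()))]  # first max = lowest index
            status[s] = "multi-call-resolved"
        elif fallback == "argmax":
            row = scores.loc[s, class_order]
            labels[s] = class_order[int(np.argmax(row.to_numpy()))]
            status[s] = "fallback"
        else:
            labels[s], status[s] = "unassigned", "unassigned"
    idx = candidates.index
    return (
        pd.Series(labels, name="label").reindex(idx),
        pd.Series(status, name="status").reindex(idx),
    )


def predict(
    prediction: pd.DataFrame,
    model: SignatureModel,
    seed: int = 17,
    fallback: str = "argmax",
) -> PredictionResult:
    """Label every prediction sample using only the signature gene sets.

    Runs the 2-means split and target call once per class, scores every
    sample against every usable class, and resolves the labels. Classes
    whose gene set is empty or entirely absent from the prediction matrix
    are skipped with a warning (they can never be called); a model with no
    usable class at all is an error.
    """
    usable: dict[str, list[str]] = {}
    present = set(prediction.index)
    for c in model.class_names:
        genes = [g for g in model.gene_sets[c] if g in present]
        if genes:
            usable[c] = genes
        else:
            warnings.warn(f"class {c!r}: no usable signature genes; class cannot be called")
    if not usable:
        raise DataError("no common genes: model signature sets are empty or absent "
                        "from the prediction matrix")
    if prediction.shape[1] < 2:
        raise DataError("unsupervised prediction needs multiple samples")

    samples = prediction.columns
    classes = [c for c in model.class_names if c in usable]
    candidates = pd.DataFrame(False, index=samples, columns=classes)
    p1 = pd.DataFrame(0.0, index=samples, columns=classes)
    p2 = pd.Series(0.0, index=classes, name="p2")
    splits: dict[str, ClusterSplit] = {}

    for c in classes:
        genes = usable[c]
        signs = reference_gene_signs(model, c)
        assignment = cluster_by_signature(prediction, genes, seed=seed)
        split = call_target_cluster(assignment, prediction, genes, class_name=c,
                                    gene_signs=signs)
        splits[c] = split
        candidates[c] = split.is_target
        summaries = signature_summaries(prediction, genes, signs)
        p2[c] = separation_log_score(split)
        sigma_nt = max(split.sigma_nt, EPS_SIGMA)
        dens = stats.norm.pdf(summaries.to_numpy(), loc=split.mu_nt, scale=sigma_nt)
        p1[c] = np.maximum(0.0, -np.log(np.maximum(dens, PROB_FLOOR)))

    scores = p1.mul(p2, axis=1)
    labels, status = resolve_labels(candidates, scores, fallback=fallback)

    flags = []
    # a genuine signature split separates the cluster means by the class
    # effect, several pooled SDs; when NO class achieves that, the sample
    # set likely holds a single class and every split is a noise split
    max_sep = max(
        abs(s.mu_t - s.mu_nt) / max(s.s_p, EPS_SIGMA) for s in splits.values()
    )
    if max_sep < 2.0:
        flags.append(
            "degenerate-splits: no class separated its clusters by more than "
            "2 pooled standard deviations; the prediction set may contain "
            "samples from a single class, where unsupervised transfer fails"
        )
        warnings.warn(flags[-1])
    return PredictionResult(
        labels=labels, status=status, candidates=candidates,
        p1=p1, p2=p2, scores=scores, splits=splits, flags=flags,
    )
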